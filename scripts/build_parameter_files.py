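"""Regenerate the bundled standard parameter files and reference grid.

Run from the repository root:

    python scripts/build_parameter_files.py

Writes the six growth-standard JSON files and the synthetic birthweight
reference CSV under src/epwscreen/data/. The build is deterministic, so a
rerun reproduces the shipped files byte-for-byte.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from epwscreen.calibration import build_birthweight_reference, build_default_standards

ROOT = Path(__file__).resolve().parents[1] / "src" / "epwscreen" / "data"


def main() -> None:
    standards = build_default_standards()
    for sid, spec in standards.items():
        path = ROOT / "standards" / f"{sid}.json"
        path.write_text(json.dumps(spec, indent=1) + "\n")
        print(f"wrote {path}")
    ref = build_birthweight_reference()
    path = ROOT / "reference" / "synthetic_birthweight_reference.csv"
    ref.to_csv(path, index=False)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
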