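ga_days,sex,level,weight_g
259,male,10,2539.9
266,male,10,2660.9
273,male,10,2777.3
280,male,10,2889.0
287,male,10,2996.1
294,male,10,3098.5
259,female,10,2450.1
266,female,10,2566.8
273,female,10,2679.1
280,female,10,2786.9
287,female,10,2890.1
294,female,10,2988.9
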