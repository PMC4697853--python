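id,sex,age,weight,height
1,male,39,98,191
2,male,26,78,179
3,male,30,120,198
4,female,26,81,178
5,male,37,78,177
6,male,27,95,183
7,female,42,68,165
8,male,36,89,176
9,female,35,74,169
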