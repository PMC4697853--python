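id,object_time,syringe_drop_time,number_time,command_time
1,180,283,435,475
2,90,357,639,649
3,90,421,792,802
4,30,454,,650
5,120,289,360,380
6,180,433,,588
7,90,202,,545
8,30,401,822,832
9,90,355,560,570
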