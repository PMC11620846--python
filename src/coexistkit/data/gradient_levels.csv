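variable,level,lo,hi
pH,1,,4.3
pH,2,4.3,4.4
pH,3,4.4,4.5
pH,4,4.5,4.6
pH,5,4.6,4.7
pH,6,4.8,4.9
pH,7,4.9,5.0
pH,8,5.0,5.1
pH,9,5.1,5.3
pH,10,5.3,5.4
pH,11,5.4,
t_k,1,,1.0
t_k,2,1.0,2.0
t_k,3,2.0,2.5
t_k,4,2.5,3.0
t_k,5,3.0,3.5
t_k,6,3.5,4.0
t_k,7,4.4,5.1
t_k,8,6.5,7.0
t_k,9,7.1,7.6
t_k,10,8.2,8.9
t_k,11,9.0,
a_k,1,,30
a_k,2,30,40
a_k,3,40,50
a_k,4,50,60
a_k,5,60,70
a_k,6,70,80
a_k,7,80,90
a_k,8,90,100
a_k,9,102,113
a_k,10,118,127
a_k,11,130,
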