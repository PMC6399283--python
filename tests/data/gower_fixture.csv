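sex,age,bmi,htn,fhdm
0,57.0,18.1,0,1
1,49.9,25.3,0,0
0,54.5,24.2,0,0
0,66.0,19.2,1,1
1,65.4,26.8,1,0
1,44.8,20.7,0,1
1,57.8,32.1,0,0
0,46.1,20.9,1,0
0,58.1,25.4,0,1
0,56.0,25.0,0,1
1,46.4,27.4,0,0
0,40.1,26.4,1,1
1,66.0,21.5,0,0
0,66.1,28.6,0,0
0,63.4,24.2,1,1
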