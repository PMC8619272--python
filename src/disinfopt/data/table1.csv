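naocl,h2o2,time,mean,se
0,0,0,100.0,0.00
0,10,5,86.7,6.67
0,10,10,86.7,6.67
0,10,20,86.7,6.67
0,20,5,86.7,6.67
0,20,10,86.7,6.67
0,20,20,73.3,6.67
0,30,5,86.7,6.67
0,30,10,80.0,11.55
0,30,20,73.3,6.67
5,0,5,53.3,17.64
5,0,10,26.7,6.67
5,0,15,0.0,0.00
10,0,5,6.7,6.67
10,0,10,0.0,0.00
10,0,15,0.0,0.00
15,0,5,6.7,6.67
15,0,10,0.0,0.00
15,0,15,0.0,0.00
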