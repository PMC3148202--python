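image,OP1,OP2,OP3,OP4,TE1,TE2,TE3,TE4,AD3RI
1,1.8,2.2,2.0,2.2,1.3,1.3,1.6,2.0,3.0
2,3.2,4.4,3.3,4.2,2.9,3.4,2.7,6.2,1.8
3,8.3,4.4,5.8,7.8,6.9,4.3,6.1,7.1,7.4
4,2.7,1.3,0.9,1.2,1.2,1.5,1.5,0.6,1.7
5,4.9,3.7,4.3,5.0,2.0,3.5,5.0,5.7,5.8
6,10.7,5.8,7.6,10.7,10.2,9.1,10.0,18.3,11.9
7,13.0,9.5,9.7,18.1,10.3,14.4,12.3,22.8,14.0
8,10.1,3.3,0.1,4.5,3.6,3.0,2.2,9.5,5.2
9,13.8,13.8,14.6,20.2,15.1,3.9,20.6,31.7,12.9
10,7.7,1.8,4.2,2.5,7.6,4.9,10.2,12.0,10.7
11,2.1,3.9,7.5,17.8,20.3,5.3,20.1,12.1,11.4
12,5.9,5.5,6.7,6.1,6.7,6.6,8.3,7.2,5.6
13,1.2,3.4,2.3,2.3,2.9,2.2,3.7,2.7,1.4
14,3.5,3.6,3.6,5.6,3.8,4.5,6.5,3.5,5.3
15,1.4,5.2,8.4,6.7,5.7,6.6,6.4,7.3,6.1
16,1.9,5.3,4.3,4.8,3.4,4.0,4.5,5.9,4.8
17,1.2,1.6,1.1,0.4,0.8,1.3,1.9,1.4,2.6
18,1.0,1.1,2.0,0.2,0.8,1.4,1.7,4.1,1.2
19,31.0,25.2,51.0,45.5,44.9,41.7,55.9,63.2,52.2
20,11.7,16.2,18.4,20.5,17.0,15.5,16.7,27.2,19.3
21,9.3,15.8,9.1,7.1,6.7,11.2,14.2,16.1,15.1
22,12.5,7.3,4.6,0.7,0.1,0.0,0.0,0.8,0.0
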