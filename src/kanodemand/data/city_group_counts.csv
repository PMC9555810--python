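attribute_id,group,M,O,A,I,Q,R
1,Yangzhou,3,13,88,59,6,4
1,Nantong,5,21,82,63,1,3
2,Yangzhou,2,16,84,66,3,2
2,Nantong,2,17,90,62,3,1
3,Yangzhou,0,18,88,57,4,6
3,Nantong,4,18,82,60,4,7
4,Yangzhou,4,18,82,63,3,3
4,Nantong,7,19,83,63,2,1
5,Yangzhou,3,20,86,58,3,3
5,Nantong,8,16,83,63,3,2
6,Yangzhou,50,49,33,35,4,2
6,Nantong,55,39,40,38,3,0
7,Yangzhou,1,91,39,37,0,5
7,Nantong,5,75,43,44,4,4
8,Yangzhou,2,102,43,25,0,1
8,Nantong,5,91,41,34,4,0
9,Yangzhou,1,19,52,96,1,4
9,Nantong,4,21,68,76,4,2
10,Yangzhou,2,20,58,87,4,2
10,Nantong,3,19,65,83,4,1
11,Yangzhou,80,22,45,23,2,1
11,Nantong,87,26,27,30,3,2
12,Yangzhou,81,30,31,28,2,1
12,Nantong,72,34,32,35,2,0
13,Yangzhou,1,104,40,22,2,4
13,Nantong,5,97,42,26,2,3
14,Yangzhou,3,94,45,28,1,2
14,Nantong,4,100,43,26,2,0
15,Yangzhou,1,96,48,24,2,2
15,Nantong,6,100,40,25,2,2
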