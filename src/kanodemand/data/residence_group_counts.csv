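attribute_id,group,M,O,A,I,Q,R
1,rural,4,16,81,65,4,3
1,urban,4,18,89,57,3,4
2,rural,2,14,81,71,2,3
2,urban,2,19,93,57,4,0
3,rural,2,16,83,60,4,8
3,urban,2,20,87,57,4,5
4,rural,4,17,83,64,2,3
4,urban,7,20,82,62,3,1
5,rural,5,18,83,61,2,4
5,urban,6,18,86,60,4,1
6,rural,53,40,35,40,3,2
6,urban,52,48,38,33,4,0
7,rural,2,84,39,40,3,5
7,urban,4,82,43,41,1,4
8,rural,4,92,44,31,1,1
8,urban,3,101,40,28,3,0
9,rural,2,17,66,81,4,3
9,urban,3,23,54,91,1,3
10,rural,3,19,64,82,3,2
10,urban,2,20,59,88,5,1
11,rural,79,23,39,27,3,2
11,urban,88,25,33,26,2,1
12,rural,75,30,34,32,1,1
12,urban,78,34,29,31,3,0
13,rural,3,93,46,26,2,3
13,urban,3,108,36,22,2,4
14,rural,3,94,45,26,3,2
14,urban,4,100,43,28,0,0
15,rural,4,93,45,28,2,1
15,urban,3,103,43,21,2,3
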