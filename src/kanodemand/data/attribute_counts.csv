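attribute_id,M,O,A,I,Q,R
1,8,34,170,122,7,7
2,4,33,174,128,6,3
3,4,36,170,117,8,13
4,11,37,165,126,5,4
5,11,36,169,121,6,5
6,105,88,73,73,7,2
7,6,166,82,81,4,9
8,7,193,84,59,4,1
9,5,40,120,172,5,6
10,5,39,123,170,8,3
11,167,48,72,53,5,3
12,153,64,63,63,4,1
13,6,201,82,48,4,7
14,7,194,88,54,3,2
15,7,196,88,49,4,4
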