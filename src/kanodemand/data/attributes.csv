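attribute_id,label
1,"Remote education on home safety prevention (fall prevention, fraud prevention, etc.)"
2,Teletraining on care skills (mastering physical and mental care skills to enhance self-care and family and community support)
3,Remote lectures about disease prevention
4,Remote screening for diseases (screening for diseases after the relevant indicators are entered into the database)
5,Distance intervention for disease risk factors
6,"Remote monitoring of vital signs and sleep, etc."
7,Remote diagnosis of diseases
8,Remote health counseling
9,"Remote calls for life needs (turning over, patting on the back, etc.)"
10,"Remote calls for nursing needs (pressure injury care, etc.)"
11,Remote one-button emergency caller
12,"Remote emergency assistance arrangement (Arranging emergency measures according to the condition and opening ""green passages"" with the corresponding hospitals)"
13,Remote rehabilitation guidance
14,Remote return visits and related health education
15,"Regular family visits (physical examination, etc.)"
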