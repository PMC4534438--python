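# Synthetic question registry: texts for indices 11,21,26,27,31,34,36,37,43,44 are the
# published wordings; all other texts are synthetic placeholders (the full published
# questionnaire is not redistributed here). Texts are metadata only.
index	short_label	text
1	Q1	Synthetic placeholder wording for questionnaire item 1.
2	Q2	Synthetic placeholder wording for questionnaire item 2.
3	Q3	Synthetic placeholder wording for questionnaire item 3.
4	Q4	Synthetic placeholder wording for questionnaire item 4.
5	Q5	Synthetic placeholder wording for questionnaire item 5.
6	Q6	Synthetic placeholder wording for questionnaire item 6.
7	Q7	Synthetic placeholder wording for questionnaire item 7.
8	Q8	Synthetic placeholder wording for questionnaire item 8.
9	Q9	Synthetic placeholder wording for questionnaire item 9.
10	Q10	Synthetic placeholder wording for questionnaire item 10.
11	Q11	Did your child already suffer from pneumonia and stayed alert and happy throughout?
12	Q12	Synthetic placeholder wording for questionnaire item 12.
13	Q13	Synthetic placeholder wording for questionnaire item 13.
14	Q14	Synthetic placeholder wording for questionnaire item 14.
15	Q15	Synthetic placeholder wording for questionnaire item 15.
16	Q16	Synthetic placeholder wording for questionnaire item 16.
17	Q17	Synthetic placeholder wording for questionnaire item 17.
18	Q18	Synthetic placeholder wording for questionnaire item 18.
19	Q19	Synthetic placeholder wording for questionnaire item 19.
20	Q20	Synthetic placeholder wording for questionnaire item 20.
21	Q21	Did your child experience fever while suffering from pulmonary or respiratory problems?
22	Q22	Synthetic placeholder wording for questionnaire item 22.
23	Q23	Synthetic placeholder wording for questionnaire item 23.
24	Q24	Synthetic placeholder wording for questionnaire item 24.
25	Q25	Synthetic placeholder wording for questionnaire item 25.
26	Q26	Would you say that your child is suffering from cough since birth?
27	Q27	Do you think that your child often suffers from an inflammation of the middle ear?
28	Q28	Synthetic placeholder wording for questionnaire item 28.
29	Q29	Synthetic placeholder wording for questionnaire item 29.
30	Q30	Synthetic placeholder wording for questionnaire item 30.
31	Q31	Are there any allergies detected in your child?
32	Q32	Synthetic placeholder wording for questionnaire item 32.
33	Q33	Synthetic placeholder wording for questionnaire item 33.
34	Q34	Would you say that your child's running nose is not influenced by the season?
35	Q35	Synthetic placeholder wording for questionnaire item 35.
36	Q36	Were you under the impression that your child is or was slower in its development than other children (e.g. learning to walk)?
37	Q37	Are there relatives with chronic pulmonary diseases (e.g. cystic fibrosis or similar)?
38	Q38	Would you say that infections in your child never clear up completely, but affect the ears first and then continue by affecting the lungs?
39	Q39	Synthetic placeholder wording for questionnaire item 39.
40	Q40	Synthetic placeholder wording for questionnaire item 40.
41	Q41	Synthetic placeholder wording for questionnaire item 41.
42	Q42	Synthetic placeholder wording for questionnaire item 42.
43	Q43	Do you perceive a whistling/wheezing sound when your child is breathing?
44	Q44	Do you or did you notice alternating days when your child was drowsy on one and feeling fine on the other?
45	Q45	Synthetic placeholder wording for questionnaire item 45.
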