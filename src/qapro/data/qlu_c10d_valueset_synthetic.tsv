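dimension	item_ids	level	decrement
physical	q1;q2;q3;q4;q5	1	0
physical	q1;q2;q3;q4;q5	2	0.04
physical	q1;q2;q3;q4;q5	3	0.1
physical	q1;q2;q3;q4;q5	4	0.2
role	q6;q7	1	0
role	q6;q7	2	0.03
role	q6;q7	3	0.07
role	q6;q7	4	0.13
social	q26;q27	1	0
social	q26;q27	2	0.03
social	q26;q27	3	0.07
social	q26;q27	4	0.12
emotional	q21;q22;q23;q24	1	0
emotional	q21;q22;q23;q24	2	0.03
emotional	q21;q22;q23;q24	3	0.08
emotional	q21;q22;q23;q24	4	0.14
pain	q9;q19	1	0
pain	q9;q19	2	0.04
pain	q9;q19	3	0.11
pain	q9;q19	4	0.19
fatigue	q10;q12;q18	1	0
fatigue	q10;q12;q18	2	0.03
fatigue	q10;q12;q18	3	0.06
fatigue	q10;q12;q18	4	0.11
sleep	q11	1	0
sleep	q11	2	0.02
sleep	q11	3	0.04
sleep	q11	4	0.07
appetite	q13	1	0
appetite	q13	2	0.01
appetite	q13	3	0.03
appetite	q13	4	0.05
nausea	q14;q15	1	0
nausea	q14;q15	2	0.02
nausea	q14;q15	3	0.05
nausea	q14;q15	4	0.09
bowel	q16;q17	1	0
bowel	q16;q17	2	0.01
bowel	q16;q17	3	0.03
bowel	q16;q17	4	0.05
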