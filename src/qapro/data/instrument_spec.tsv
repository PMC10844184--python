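instrument	domain_id	item_id	direction	item_range	summary_eligible
QLQC30	physical	q1	functional	3	yes
QLQC30	physical	q2	functional	3	yes
QLQC30	physical	q3	functional	3	yes
QLQC30	physical	q4	functional	3	yes
QLQC30	physical	q5	functional	3	yes
QLQC30	role	q6	functional	3	yes
QLQC30	role	q7	functional	3	yes
QLQC30	emotional	q21	functional	3	yes
QLQC30	emotional	q22	functional	3	yes
QLQC30	emotional	q23	functional	3	yes
QLQC30	emotional	q24	functional	3	yes
QLQC30	cognitive	q20	functional	3	yes
QLQC30	cognitive	q25	functional	3	yes
QLQC30	social	q26	functional	3	yes
QLQC30	social	q27	functional	3	yes
QLQC30	ghs_qol	q29	ghs	6	no
QLQC30	ghs_qol	q30	ghs	6	no
QLQC30	fatigue	q10	symptom	3	yes
QLQC30	fatigue	q12	symptom	3	yes
QLQC30	fatigue	q18	symptom	3	yes
QLQC30	nausea_vomiting	q14	symptom	3	yes
QLQC30	nausea_vomiting	q15	symptom	3	yes
QLQC30	pain	q9	symptom	3	yes
QLQC30	pain	q19	symptom	3	yes
QLQC30	dyspnea	q8	symptom	3	yes
QLQC30	insomnia	q11	symptom	3	yes
QLQC30	appetite_loss	q13	symptom	3	yes
QLQC30	constipation	q16	symptom	3	yes
QLQC30	diarrhea	q17	symptom	3	yes
QLQC30	financial	q28	symptom	3	no
QLQMY20	disease_symptoms	my1	symptom	3	no
QLQMY20	disease_symptoms	my2	symptom	3	no
QLQMY20	disease_symptoms	my3	symptom	3	no
QLQMY20	disease_symptoms	my4	symptom	3	no
QLQMY20	disease_symptoms	my5	symptom	3	no
QLQMY20	disease_symptoms	my6	symptom	3	no
QLQMY20	side_effects	my7	symptom	3	no
QLQMY20	side_effects	my8	symptom	3	no
QLQMY20	side_effects	my9	symptom	3	no
QLQMY20	side_effects	my10	symptom	3	no
QLQMY20	side_effects	my11	symptom	3	no
QLQMY20	side_effects	my12	symptom	3	no
QLQMY20	side_effects	my13	symptom	3	no
QLQMY20	side_effects	my14	symptom	3	no
QLQMY20	side_effects	my15	symptom	3	no
QLQMY20	side_effects	my16	symptom	3	no
QLQMY20	body_image	my17	functional	3	no
QLQMY20	future_perspectives	my18	functional	3	no
QLQMY20	future_perspectives	my19	functional	3	no
QLQMY20	future_perspectives	my20	functional	3	no
FACTGOGNTX	fact_ntx	ntx1	fact	4	no
FACTGOGNTX	fact_ntx	ntx2	fact	4	no
FACTGOGNTX	fact_ntx	ntx3	fact	4	no
FACTGOGNTX	fact_ntx	ntx4	fact	4	no
FACTGOGNTX	fact_ntx	ntx5	fact	4	no
FACTGOGNTX	fact_ntx	ntx6	fact	4	no
FACTGOGNTX	fact_ntx	ntx7	fact	4	no
FACTGOGNTX	fact_ntx	ntx8	fact	4	no
FACTGOGNTX	fact_ntx	ntx9	fact	4	no
FACTGOGNTX	fact_ntx	ntx10	fact	4	no
FACTGOGNTX	fact_ntx	ntx11	fact	4	no
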