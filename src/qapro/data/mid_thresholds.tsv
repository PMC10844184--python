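domain_id	between_group_mid	within_group_mid	sensitivity_mid	source
summary	10	10		prespecified
disease_symptoms	10	10		recommended
side_effects	10	10		recommended
body_image	13	13		recommended
future_perspectives	9	9		recommended
fact_ntx	4.4	4.4	11.8	recommended
ghs_qol	4	4		representative
physical	5	5		representative
role	6	6		representative
emotional	5	5		representative
cognitive	3	3		representative
social	5	5		representative
fatigue	5	5		representative
nausea_vomiting	3	3		representative
pain	6	6		representative
dyspnea	4	4		representative
insomnia	4	4		representative
appetite_loss	5	5		representative
constipation	5	5		representative
diarrhea	3	3		representative
financial	3	3		representative
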