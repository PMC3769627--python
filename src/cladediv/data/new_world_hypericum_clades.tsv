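clade	n_species	age_mean	age_lower_hpd	age_upper_hpd
Triadenum+Myriandra+Brathys s.l.	184	26.77	19.57	34.41
Triadenum	6	4.48	2.07	7.78
Myriandra	29	11.35	7.15	16.02
Brathys s.l.	149	13.92	9.45	19.09
Trigynobrathys s.str.	52	7.47	4.17	11.59
Brathys	97	9.79	6.28	13.83
Páramo	67	3.83	2.26	5.62
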