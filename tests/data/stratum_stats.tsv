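rsid	chr	pos	or_a	ci_lo_a	ci_hi_a	p_a	or_b	ci_lo_b	ci_hi_b	p_b	p_diff_published	p_joint_published
rs10922095	1	196662031	2.29	2.17	2.41	NA	1.81	1.72	1.90	NA	5.91e-11	NA
rs10922109	1	196704632	2.81	2.67	2.97	NA	2.50	2.37	2.63	NA	1.36e-3	NA
rs3750846	10	124215565	2.97	2.83	3.13	NA	2.64	2.51	2.78	NA	1.04e-3	NA
rs2070780	15	89760997	1.13	1.08	1.18	5.29e-8	1.05	1.01	1.10	0.0258	0.019	3.19e-8
rs9973159	18	597950	1.19	1.12	1.28	1.78e-7	1.09	1.12	1.16	0.0079	0.052	3.91e-8
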