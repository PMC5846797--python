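locus	chr	gene	expressed_retina	expressed_rpe_choroid	mgi_eye_phenotype	has_credible_variant	protein_altering	utr_5_or_3	other_exonic_splice	promoter_1kb	local_eqtl	essential_exac	mendelian_retinopathy
RLBP1	15	ABHD2	+	+	-	+	-	+	+	+	-	+	-
RLBP1	15	RLBP1	+	+	+	+	-	+	+	+	-	-	0
RLBP1	15	FANCI	-	-	-	-	-	-	-	-	-	-	-
RLBP1	15	POLG	+	+	-	-	-	-	-	-	+	-	-
RLBP1	15	MIR6766	NA	NA	-	-	-	-	-	-	-	NA	-
CLUL1	18	COLEC12	+	+	-	-	-	-	-	-	-	+	-
CLUL1	18	CETN1	-	-	-	-	-	-	-	-	-	+	-
CLUL1	18	CLUL1	+	+	-	+	-	+	+	+	-	-	-
CLUL1	18	C18orf56	-	-	-	-	-	-	-	-	-	+	-
CLUL1	18	TYMS	-	-	-	-	-	-	-	-	-	+	-
CLUL1	18	ENOSF1	+	+	-	-	-	-	-	-	-	-	-
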