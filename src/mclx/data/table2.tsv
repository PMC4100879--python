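amino_acid	zucker	ex_recon1	ex_mcl	trans_recon1	trans_mcl
Arginine	-	+	0	0	-
Leucine	+	0	0	+	0
Phenylalanine	0	+	0	0	0
Cysteine	0	0	0	-	0
Glutamine	-	0	+	+	0
Serine	-	+	0	+	0
Asparagine	-	0	0	+	0
Tryptophan	-	0	0	0	-
Proline	0	-	0	0	0
Threonine	-	0	0	+	0
Aspartate	0	+	+	0	0
Glycine	-	0	0	-	0
Glutamate	+	0	0	-	0
Isoleucine	+	0	+	0	+
Lysine	-	0	0	0	+
Valine	+	0	0	+	+
Methionine	-	+	+	0	+
Tyrosine	-	0	-	-	-
Alanine	0	-	+	0	0
Histidine	-	+	-	-	+
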