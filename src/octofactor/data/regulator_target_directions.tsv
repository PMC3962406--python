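gene_symbol	116:114	121:114
Acadvl	-	-1
Acat1	+1	+1
Acox1	-1	-1
Acsl1	+1	-1
Aldh2	+1	-
Aldob	+1	-
Arg1	-	+1
Ass1	+1	+1
Bhmt	+1	+1
Ca3	-1	-1
Cat	-1	-1
Cbr1	+1	+1
Cps1	+1	-
Cyp2a6	+1	-
Cyp2e1	+1	-1
Dbi	-1	-
Ech1	-	-1
Ehhadh	-	-1
Ephx2	-	-1
Fabp1	-1	-1
Ftcd	+1	-
Glul	+1	-1
Gpt	+1	-
Gpx1	-1	-
Gstm1	+1	-
Gstp1	+1	-1
Gstz1	-	-1
Hacl1	+1	-
Hadha	+1	-1
Hmgcs2	+1	-1
Hsd17b10	+1	-
Hsd17b4	-	-1
Hsp90b1	-	-1
Hspa5	-1	-1
Krt8	+1	+1
Oat	+1	-
Pc	+1	+1
Por	+1	-
Prdx1	+1	-
Rgn	-	-1
Rplp0	-	-1
Scp2	-1	-1
Selenbp1	-	+1
Serpina3k	-	-1
Sod1	-	-1
Tf	+1	+1
Uox	-	-1
Vcp	+1	-
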