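regulator	target	sign
NRF2	Bhmt	+
NRF2	Cbr1	+
NRF2	Fabp1	-
NRF2	Gstm1	+
NRF2	Gstp1	+
NRF2	Prdx1	+
NRF2	Vcp	+
NRF2	Hsp90b1	?
NRF2	Rplp0	?
NRF2	Serpina3k	?
NRF2	Uox	?
PPARA	Acat1	?
PPARA	Acox1	+
PPARA	Aldh2	-
PPARA	Aldob	-
PPARA	Ass1	-
PPARA	Cat	+
PPARA	Cps1	-
PPARA	Dbi	+
PPARA	Fabp1	+
PPARA	Ftcd	-
PPARA	Gstp1	-
PPARA	Hacl1	?
PPARA	Hadha	?
PPARA	Hsd17b10	?
PPARA	Krt8	?
PPARA	Pc	?
PPARA	Por	?
PPARA	Scp2	+
PPARA	Acadvl	?
PPARA	Arg1	?
PPARA	Ech1	?
PPARA	Ehhadh	?
PPARA	Gstz1	?
PPARA	Hsd17b4	?
PPARA	Selenbp1	?
CTNNB1	Ca3	?
CTNNB1	Cyp2a6	?
CTNNB1	Cyp2e1	?
CTNNB1	Glul	?
CTNNB1	Oat	?
CTNNB1	Rgn	?
ACOX1	Acox1	?
ACOX1	Acsl1	?
ACOX1	Cat	?
ACOX1	Hspa5	?
ACOX1	Acadvl	?
ACOX1	Ehhadh	?
ACOX1	Uox	?
RXRA	Acox1	?
RXRA	Fabp1	?
RXRA	Gpt	?
RXRA	Gpx1	?
NR1I2	Acox1	?
NR1I2	Bhmt	?
NR1I2	Glul	?
NR1I2	Gstm1	?
NR1I2	Gstp1	?
NR1I2	Hmgcs2	?
NR1I2	Por	?
NR1I2	Tf	?
NR1I2	Uox	?
MED1	Acox1	?
MED1	Gstp1	?
MED1	Scp2	?
MED1	Ehhadh	?
MED1	Hsd17b4	?
LEP	Acox1	?
LEP	Aldob	?
LEP	Ass1	?
LEP	Cps1	?
LEP	Cyp2e1	?
LEP	Gpx1	?
LEP	Prdx1	?
LEP	Scp2	?
LEP	Acadvl	?
LEP	Ech1	?
LEP	Ehhadh	?
LEP	Ephx2	?
LEP	Sod1	?
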