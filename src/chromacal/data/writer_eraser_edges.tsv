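modifier	mark	relation
EZH2	H3:K27:me3	writes
EZH1	H3:K27:me3	writes
EZH2	H3:K27:me2	writes
KDM6A	H3:K27:me3	erases
KDM6B	H3:K27:me3	erases
EP300	H3:K27:ac	writes
CREBBP	H3:K27:ac	writes
HDAC1	H3:K27:ac	erases
HDAC2	H3:K27:ac	erases
DOT1L	H3:K79:me1	writes
DOT1L	H3:K79:me2	writes
NSD1	H3:K36:me2	writes
NSD2	H3:K36:me2	writes
SETMAR	H3:K36:me2	writes
SETD2	H3:K36:me3	writes
KDM2A	H3:K36:me2	erases
KDM4A	H3:K36:me3	erases
SUV39H1	H3:K9:me3	writes
SUV39H2	H3:K9:me3	writes
SETDB1	H3:K9:me3	writes
EHMT2	H3:K9:me2	writes
EHMT1	H3:K9:me2	writes
KDM3A	H3:K9:me2	erases
KDM4A	H3:K9:me3	erases
KDM4B	H3:K9:me3	erases
KDM4C	H3:K9:me3	erases
KMT2A	H3:K4:me3	writes
SETD1A	H3:K4:me3	writes
KDM1A	H3:K4:me2	erases
KDM5A	H3:K4:me3	erases
KDM5B	H3:K4:me3	erases
KAT5	H4:K16:ac	writes
KAT8	H4:K16:ac	writes
SIRT1	H4:K16:ac	erases
HAT1	H4:K5:ac	writes
HDAC3	H4:K5:ac	erases
SMYD3	H4:K5:me1	writes
SUV420H1	H4:K20:me2	writes
SUV420H2	H4:K20:me3	writes
PHF8	H4:K20:me1	erases
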