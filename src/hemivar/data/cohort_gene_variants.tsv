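# Per-gene protein-altering variant tally transcribed from a published
# 127-patient 22q11.2 deletion cohort (rare counts use the <=5% population
# AND cohort frequency rule). percent_sequenced_coding is the fraction of
# the gene's coding bases that were sequenceable in that cohort.
gene	percent_sequenced_coding	stop_gain_total	stop_gain_rare	frameshift_insertion_total	frameshift_insertion_rare	non_synonymous_total	non_synonymous_rare	omim_literature	mouse_ko
AIFM3	100	0	0	0	0	9	8
ARVCF	100	0	0	0	0	11	8	22q11-associated	abnormal gait and cataract
C22orf29	100	0	0	0	0	3	3
C22orf39	100	0	0	0	0	0	0
CDC45	100	0	0	0	0	1	1		embryonic lethal
CLDN5	100	1	0	0	0	1	1		blood-brain barrier loosening, premature neonatal lethality
CLTCL1	99	0	0	1	0	14	9
COMT	100	0	0	0	0	1	0	22q11-associated; schizophrenia	increased dopamine levels; behavioral changes
CRKL	100	0	0	0	0	0	0	22q11-associated; cat eye syndrome; conotruncal heart defects
DGCR14	100	0	0	0	0	4	3
DGCR2	100	0	0	0	0	2	1	22q11-associated; schizophrenia
DGCR6L	0	0	0	0	0	0	0
DGCR8	100	0	0	0	0	2	2	22q11-associated; schizophrenia	embryonic lethal
GNB1L	100	0	0	0	0	5	3	22q11-associated	embryonic lethal
GP1BB	45	0	0	0	0	0	0	22q11-associated; Bernard-Soulier syndrome (AR)	giant platelets, severe bleeding
GSC2	52	0	0	0	0	0	0		normal
HIRA	100	0	0	0	0	0	0	22q11-associated	disrupted embryonic development, embryonic lethal
KLHL22	100	0	0	0	0	0	0
LOC388849	0	0	0	0	0	0	0
LZTR1	100	0	0	0	0	1	1	schwannomatosis 2; Noonan syndrome
MED15	100	0	0	0	0	1	1
MRPL40	100	0	0	0	0	2	0
P2RX6	100	0	0	0	0	1	0		increased thermal response latency, seizure resistant
PI4KA	72	0	0	0	0	2	2	perisylvian polymicrogyria, cerebellar hypoplasia, arthrogryposis (AR)	embryonic lethal
PRODH	22	1	1	0	0	2	1	22q11-associated; schizophrenia; hyperprolinemia type I (AR)	hyperprolinemia, increased startle reflex
RANBP1	98	0	0	0	0	0	0	22q11-associated	growth retardation, male infertility
RIMBP3	0	0	0	0	0	0	0		male infertility
RTN4R	98	0	0	0	0	0	0	schizophrenia	impaired behavior and coordination
SCARF2	90	0	0	0	0	8	2	Van den Ende-Gupta syndrome (AR)
SEPT5	96	0	0	0	0	0	0	Bernard-Soulier syndrome (AR)	synaptic transmission and platelet secretion defects
SERPIND1	100	0	0	0	0	4	4		normal
SLC25A1	86	0	0	0	0	0	0	22q11-associated; combined D-2-/L-2-hydroxyglutaric aciduria (AR)
SLC7A4	100	0	0	0	0	4	2
SNAP29	100	0	0	1	1	2	2	CEDNIK syndrome (AR)
TANGO2	100	0	0	0	0	1	1
TBX1	78	1	1	0	0	2	0	22q11-associated; conotruncal heart malformations; tetralogy of Fallot	neonatal lethality, abnormal vessel and ear development
THAP7	100	0	0	0	0	2	1
TMEM191B	0	0	0	0	0	0	0
TRMT2A	100	0	0	0	0	3	2
TSSK2	100	0	0	0	0	3	2		male infertility
TXNRD2	100	0	0	0	0	0	0	22q11-associated	embryonic lethal
UFD1L	100	0	0	0	0	1	1		normal
ZDHHC8	32	0	0	0	0	0	0	schizophrenia	behavioral changes
ZNF74	100	0	0	0	0	3	2	22q11-associated
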