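locus	total_cases	ns	s	indel	biofilm_cases	planktonic_cases	highest_frequency	functional_class
argJ	3	3	0	0	2	1	13.5	Arginine biosynthesis
soxA	3	2	1	0	1	2	14.7	Carbon compound catabolism
aer2	5	3	2	0	3	2	14.2	Chemotaxis
bdlA	3	3	0	0	3	0	14.7	Chemotaxis
cobG	3	2	0	1	1	2	61.8	Cofactor biosynthesis
mutS	3	3	0	0	2	1	100	DNA replication
napF	3	3	0	0	2	1	13.8	Energy metabolism
nqrE	3	3	0	0	1	2	11.7	Energy metabolism
nuoG	3	3	0	0	1	2	13.9	Energy metabolism
PA14_53110	7	7	0	0	2	5	14.8	Putative enzymes
pslI	7	7	0	0	3	4	16.7	Putative enzymes
algF	3	3	0	0	2	1	13.1	Secreted factors
fha1	4	4	0	0	3	1	35.8	Secreted factors
rpoB	4	4	0	0	4	0	100	Transcription
PA14_13150	3	3	0	0	3	0	100	Transcriptional regulators
PA14_18200	6	6	0	0	5	1	22.3	Transcriptional regulators
PA14_51840	3	3	0	0	0	3	16.6	Transcriptional regulators
PA14_58510	5	3	2	0	4	1	23	Transcriptional regulators
PA14_71750	3	3	0	0	3	0	93.9	Transcriptional regulators
dsbA2	4	2	2	0	3	1	20.8	Translation
rluB	10	8	2	0	4	6	17.7	Translation
nosD	5	4	1	0	1	4	15.3	Transporter
PA14_09300	3	3	0	0	2	1	18.6	Transporter
PA14_22650	7	7	0	0	3	4	43.2	Transporter
PA14_45060	6	6	0	0	2	4	24.4	Transporter
PA14_46110	7	7	0	0	1	6	15.5	Transporter
PA14_47900	3	3	0	0	0	3	19.9	Transporter
pchF	3	3	0	0	3	0	19	Transporter
pitA	4	2	0	2	2	3	100	Transporter
pntB	5	3	2	0	1	4	15.6	Transporter
PA14_10770	3	2	1	0	1	2	100	Two-component regulatory systems
PA14_32300	3	3	0	0	2	1	17.1	Two-component regulatory systems
gacS	3	3	0	0	3	0	92.2	Two-component regulatory systems
PA14_01160	3	3	0	0	1	2	14.3	Unknown
PA14_20510	6	6	0	0	3	3	11.9	Unknown
PA14_31070	10	5	5	0	4	6	19.3	Unknown
PA14_32830	6	6	0	0	2	4	13.8	Unknown
PA14_54810	3	3	0	0	3	0	11.7	Unknown
PA14_58070	6	6	0	0	5	1	20.8	Unknown
PA14_69010	5	5	0	0	3	2	20.1	Unknown
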