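# token	aliases (comma-separated; matching is case- and punctuation-insensitive)
ND1	NADH1,NAD1,NADH dehydrogenase subunit 1,NADH-1
ND2	NADH2,NAD2,NADH dehydrogenase subunit 2,NADH-2
ND3	NADH3,NAD3,NADH dehydrogenase subunit 3,NADH-3
ND4	NADH4,NAD4,NADH dehydrogenase subunit 4,NADH-4
ND4L	NADH4L,NAD4L,NADH dehydrogenase subunit 4L
ND5	NADH5,NAD5,NADH dehydrogenase subunit 5,NADH-5
ND6	NADH6,NAD6,NADH dehydrogenase subunit 6,NADH-6
COI	CO1,COX1,COXI,cytochrome c oxidase subunit I,cytochrome c oxidase subunit 1,cytochrome oxidase subunit I
COII	CO2,COX2,COXII,cytochrome c oxidase subunit II,cytochrome c oxidase subunit 2,cytochrome oxidase subunit II
COIII	CO3,COX3,COXIII,cytochrome c oxidase subunit III,cytochrome c oxidase subunit 3,cytochrome oxidase subunit III
ATP6	ATPase6,ATPase 6,ATP synthase F0 subunit 6,ATP synthase subunit 6
ATP8	ATPase8,ATPase 8,ATP synthase F0 subunit 8,ATP synthase subunit 8
Cytb	CYTB,cob,cytochrome b,cyt b,CytB
rrnS	12S,12S rRNA,12S ribosomal RNA,s-rRNA,small subunit ribosomal RNA,rrn12,ssu rRNA,12SrRNA
rrnL	16S,16S rRNA,16S ribosomal RNA,l-rRNA,large subunit ribosomal RNA,rrn16,lsu rRNA,16SrRNA
OL	O-L,OriL,L-strand origin,origin of L-strand replication,light strand replication origin,light-strand origin
CR	D-loop,control region,D loop,putative control region,CR region
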