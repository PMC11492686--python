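species	id	kind	length	depth	chromosome	start1	end1	start2	end2
C_carlesii	contig1	contig	177754	161.9	.	1	177754	.	.
C_carlesii	contig2	contig	72929	176.9	.	463145	536073	.	.
C_carlesii	contig3	contig	66674	178.7	.	232048	298721	.	.
C_carlesii	contig4	contig	62899	196.0	.	345375	408273	.	.
C_carlesii	contig5	contig	48020	144.7	.	184028	232047	.	.
C_carlesii	contig6	contig	37342	162.9	.	308033	345374	.	.
C_carlesii	contig7	contig	32331	140.6	.	421503	453833	.	.
C_carlesii	contig8	contig	31975	156.3	.	549303	581277	.	.
C_carlesii	LR9	repeat	13229	301.9	.	408274	421502	536074	549302
C_carlesii	LR10	repeat	9311	295.4	.	298722	308032	453834	463144
C_carlesii	LR11	repeat	6273	283.4	.	177755	184027	581278	587550
C_carlesii	contig12	contig	5152	128.9	.	587551	592702	.	.
Ca_henryi	contig1	contig	226901	348.3	1	22251	249151	.	.
Ca_henryi	contig2	contig	55245	333.6	2	651	55895	.	.
Ca_henryi	contig3	contig	40401	264.4	3	651	41051	.	.
Ca_henryi	contig4	contig	21309	300.4	2	65543	86851	.	.
Ca_henryi	contig5	contig	19374	299.8	1	1	19374	.	.
Ca_henryi	contig6	contig	8685	310.5	2	56377	65061	.	.
Ca_henryi	LR7	repeat	2876	679.7	1	19375	22250	249152	252027
Ca_henryi	LR8	repeat	650	581.1	2,3	1	650	1	650
Ca_henryi	LR9	repeat	481	606.3	2	55896	56376	65062	65542
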