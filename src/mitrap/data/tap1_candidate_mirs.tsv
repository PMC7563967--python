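accession	mir_id	enrichment_ratio	miRWalk	microrna.org	miRDB	TargetScan	RNA22	RNAhybrid	votes	binding_energy
MIMAT0020601	hsa-miR-1273f	0.9	yes	Yes	no	yes	no	yes	4	-30.1
MIMAT0005797	hsa-miR-1301-3p	9.2	yes	Yes	no	yes	yes	yes	5	-29.0
MIMAT0004597	hsa-miR-140-3p	1.3	yes	Yes	no	yes	yes	yes	5	-24.0
MIMAT0004697	hsa-miR-151a-5p	19.1	yes	Yes	no	yes	yes	yes	5	-26.1
MIMAT0010214	hsa-miR-151b	6.3	yes	Yes	no	yes	no	yes	4	-24.8
MIMAT0004494	hsa-miR-21-3p	1036.0	yes	Yes	yes	yes	no	yes	5	-20.3
MIMAT0000077	hsa-miR-22-3p	102.9	yes	Yes	no	yes	yes	yes	5	-21.6
MIMAT0000079	hsa-miR-24-1-5p	5.0	yes	Yes	no	yes	no	yes	4	-25.8
MIMAT0004497	hsa-miR-24-2-5p	17.2	yes	Yes	no	yes	no	yes	4	-25.9
MIMAT0000082	hsa-miR-26a-5p	74.1	yes	Yes	no	yes	no	yes	4	-25.1
MIMAT0000083	hsa-miR-26b-5p	92.1	yes	Yes	no	yes	no	yes	4	-25.4
MIMAT0000085	hsa-miR-28-5p	16.1	yes	Yes	no	yes	no	yes	4	-20.9
MIMAT0000751	hsa-miR-330-3p	21.7	yes	Yes	no	yes	no	yes	4	-24.8
MIMAT0026612	hsa-miR-504-3p	16.2	yes	Yes	no	yes	no	yes	4	-27.2
MIMAT0004778	hsa-miR-508-5p	3.4	yes	Yes	no	yes	no	yes	4	-25.5
MIMAT0002823	hsa-miR-512-3p	4.0	yes	Yes	no	yes	no	yes	4	-27.0
MIMAT0002888	hsa-miR-532-5p	65.5	yes	Yes	no	yes	no	yes	4	-20.5
MIMAT0003254	hsa-miR-548b-3p	1.3	yes	Yes	yes	yes	no	yes	5	-22.4
MIMAT0004801	hsa-miR-590-3p	289.2	yes	Yes	yes	yes	no	yes	5	-12.8
MIMAT0026619	hsa-miR-597-3p	2.7	yes	Yes	no	yes	no	yes	4	-23.5
MIMAT0004926	hsa-miR-708-5p	13.8	yes	Yes	no	yes	no	yes	4	-24.3
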