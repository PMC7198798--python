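# Synthetic stand-in for the unified 9-node literature reference network
# (50 directed signed edges; plausible, not curated).
source	target	sign	weight	confidence	provenance
CK1	CK17	1	1.0	0.92	synthetic-standin
CK1	MK1A	1	1.0	0.95	synthetic-standin
CK1	MK1B	1	1.0	0.85	synthetic-standin
CK1	MK23	1	1.0	0.96	synthetic-standin
CK17	MK15	-1	1.0	0.93	synthetic-standin
CK17	MK1A	-1	1.0	0.98	synthetic-standin
CK17	MK1B	-1	1.0	0.98	synthetic-standin
CK2	CK1	1	1.0	0.95	synthetic-standin
CK2	MK1A	1	1.0	0.92	synthetic-standin
CK2	MK1B	1	1.0	0.99	synthetic-standin
CK2	MK23	-1	1.0	0.81	synthetic-standin
MK15	CK1	1	1.0	0.82	synthetic-standin
MK15	CK17	1	1.0	0.86	synthetic-standin
MK15	CK2	1	1.0	0.85	synthetic-standin
MK1A	CK1	-1	1.0	0.93	synthetic-standin
MK1A	CK2	-1	1.0	0.9	synthetic-standin
MK1A	MK15	-1	1.0	0.86	synthetic-standin
MK1A	MK1B	1	1.0	0.92	synthetic-standin
MK1A	MK2	1	1.0	0.96	synthetic-standin
MK1A	MK23	-1	1.0	0.95	synthetic-standin
MK1A	MK6	1	1.0	0.84	synthetic-standin
MK1B	CK1	-1	1.0	0.81	synthetic-standin
MK1B	CK2	-1	1.0	0.98	synthetic-standin
MK1B	MK15	-1	1.0	0.94	synthetic-standin
MK1B	MK1A	1	1.0	0.98	synthetic-standin
MK1B	MK2	1	1.0	0.84	synthetic-standin
MK1B	MK23	-1	1.0	0.97	synthetic-standin
MK1B	MK6	1	1.0	0.95	synthetic-standin
MK2	CK1	-1	1.0	0.98	synthetic-standin
MK2	CK17	-1	1.0	0.88	synthetic-standin
MK2	CK2	1	1.0	0.82	synthetic-standin
MK2	MK15	-1	1.0	0.8	synthetic-standin
MK2	MK1A	-1	1.0	0.83	synthetic-standin
MK2	MK1B	-1	1.0	0.82	synthetic-standin
MK2	MK23	1	1.0	0.95	synthetic-standin
MK2	MK6	-1	1.0	0.95	synthetic-standin
MK23	CK1	1	1.0	0.83	synthetic-standin
MK23	CK17	1	1.0	0.97	synthetic-standin
MK23	CK2	-1	1.0	0.85	synthetic-standin
MK23	MK1A	1	1.0	0.93	synthetic-standin
MK23	MK1B	1	1.0	0.83	synthetic-standin
MK23	MK2	1	1.0	0.97	synthetic-standin
MK23	MK6	-1	1.0	0.97	synthetic-standin
MK6	CK1	-1	1.0	0.92	synthetic-standin
MK6	CK17	1	1.0	0.92	synthetic-standin
MK6	MK15	1	1.0	0.97	synthetic-standin
MK6	MK1A	1	1.0	0.87	synthetic-standin
MK6	MK1B	1	1.0	0.88	synthetic-standin
MK6	MK2	1	1.0	0.8	synthetic-standin
MK6	MK23	1	1.0	0.81	synthetic-standin
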