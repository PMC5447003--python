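species	receptor	composition	ext_domain	m5m4	m1	p19	p20	p2124	p2529	int_domain	pf_percent	pf_sem	source
H	α4β4	α4β4 1:1	-12.75	-5	-5	0	0	0	-2.5	36.5	1.5	0.2	Lax et al.
M	αβγδ	α1β1γδ 2:1:1:1	-63	-3	-4	0	-1	1	0	22.6	2.1	0.3	Ragozzino et al.
C	α4β4	α4β4 1:1	-17.25	-5	-5	0	0	0	-2.5	35	2.1	0.2	Lax et al.
H	α4β2	α4β2 1:1	-34.25	-5	-5	0	0	0	-2.5	37	2.6	0.3	Lax et al.
H	α3β4	α3β4 1:1	-18.75	-5	-5	0	0	0	-2.5	26.5	2.7	0.2	Lax et al.
H	αβγδ	α1β1γδ 2:1:1:1	-53	-3	-4	0	-1	1	0	23.4	2.9	0.2	Fucile et al.
C	α4β2	α4β2 1:1	-25	-5	-5	0	0	0	-2.5	46.5	2.9	0.5	Ragozzino et al.
H	(β2α4)₂α4	(β2α4)2α4	-31.7	-5	-5	0	-1	0	-2	39	4.0	0.4	Sciaccaluga et al.
M	αβεδ	α1β1εδ 2:1:1:1	-69	-4	-4	0	-2	1	0	15.2	4.2	1.0	Ragozzino et al.
C	α3β4	α3β4 1:1	-23	-5	-5	0	0	0	-2.5	4.5	4.4	0.5	Lax et al.
H	αβεδ	α1β1εδ 2:1:1:1	-55.9	-4	-4	0	-2	1	0	17.8	7.2	1.1	Fucile et al.
H	(β2α4)₂α5	(β2α4)2α5	-32.1	-5	-5	-1	-1	0	-1	35	8.2	0.7	Sciaccaluga et al.
M	(β2α4)₂α5	(β2α4)2α5	-32	-5	-5	-1	-1	0	-1	43.6	8.8	1.1	Sciaccaluga et al.
R	α7	α7:5	-23.5	-5	-5	0	-5	0	-5	18	8.8	1.5	Fucile et al.
H	α7	α7:5	-23	-5	-5	0	-5	0	-5	16	11.4	1.3	Fucile et al.
R	α9α10	α9α10 1:1	-40.75	-2.5	-5	0	-5	0	-5	55.5	22	4	Fucile et al.
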