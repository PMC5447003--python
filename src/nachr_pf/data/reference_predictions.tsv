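receptor	composition	m5m4	m1	p19	p20	p2124	p2529	predicted_pf
α1	α1:5	-5	-5	0	-5	0	0	57.4
α2	α2:5	-5	-5	0	-5	0	0	57.4
α3	α3:5	-5	-5	0	-5	0	0	57.4
α4	α4:5	-5	-5	0	-5	0	0	57.4
α5	α5:5	-5	-5	-5	-5	0	0	66.7
α6	α6:5	-5	-5	0	-5	0	0	57.4
α7	α7:5	-5	-5	0	-5	0	-5	10.4
α7_E237A	α7_E237A:5	-5	0	0	-5	0	-5	0.0
α7β2	α7β2 4:1	-5	-5	0	-3	0	-5	3.6
α7β2	α7β2 3:2	-5	-5	0	-1	0	-5	1.2
α7β2	α7β2 2:3	-5	-5	0	1	0	-5	0.4
α7β2	α7β2 1:4	-5	-5	0	3	0	-5	0.1
α2β2	α2β2 1:1	-5	-5	0	0	0	-2.5	2.3
α3β4α5	α3β4α5 2:2:1	-5	-5	-1	-1	0	-1	8.5
α4β2α6	α4β2α6 2:2:1	-5	-5	0	-1	0	-2	5.0
α4β2α7	α4β2α7 1:2:2	-5	-5	0	-1	0	-4	1.9
α4β2α7	α4β2α7 2:2:1	-5	-5	0	-1	0	-3	3.1
α4α5α6β2	α4α5α6β2 1:1:1:2	-5	-5	-1	-1	0	-1	8.5
α6β4	α6β4 1:1	-5	-5	0	0	0	-2.5	2.3
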