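# Nearest-neighbor RNA/RNA duplex parameters (versioned data file, v1).
# provenance: Watson-Crick stack, duplex initiation and terminal-AU terms
#   transcribed from Xia et al. (1998) Biochemistry 37:14719 (1 M NaCl
#   reference conditions).  Wobble (GU) stack terms are a single generic
#   approximation (note 'approx'), adequate only for relative comparisons.
#   Loop/bulge initiation penalties are Turner-style dG37 values treated as
#   purely entropic under temperature scaling (dG(T) = dG37 * T / 310.15).
# stack keys read 5'XY3'/3'WZ5' with X paired to W and Y paired to Z; the
# 10 unique Watson-Crick doublets are listed, symmetric partners are
# expanded at load time.  dH kcal/mol, dS cal/(mol*K), dG37 kcal/mol.
kind	key	dH	dS	dG37	note
stack	AA/UU	-6.82	-19.0	-0.93	xia1998
stack	AU/UA	-9.38	-26.7	-1.10	xia1998
stack	UA/AU	-7.69	-20.5	-1.33	xia1998
stack	CU/GA	-10.48	-27.1	-2.08	xia1998
stack	CA/GU	-10.44	-26.9	-2.11	xia1998
stack	GU/CA	-11.40	-29.5	-2.24	xia1998
stack	GA/CU	-12.44	-32.5	-2.35	xia1998
stack	CG/GC	-10.64	-26.7	-2.36	xia1998
stack	GG/CC	-13.39	-32.7	-3.26	xia1998
stack	GC/CG	-14.88	-36.9	-3.42	xia1998
wobble_default	-	-8.00	-22.60	-0.99	approx
init	-	3.61	-1.5	4.09	xia1998
term_au	-	3.72	10.5	0.45	xia1998
bulge	1	0	-12.252	3.8	turner-style
bulge	2	0	-9.028	2.8	turner-style
bulge	3	0	-10.318	3.2	turner-style
bulge	4	0	-11.607	3.6	turner-style
bulge	5	0	-12.897	4.0	turner-style
bulge	6	0	-14.187	4.4	turner-style
internal	2	0	-4.837	1.5	turner-style
internal	3	0	-5.159	1.6	turner-style
internal	4	0	-5.481	1.7	turner-style
internal	5	0	-5.804	1.8	turner-style
internal	6	0	-6.449	2.0	turner-style
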