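# ripflash nearest-neighbor RNA duplex parameters, version 1
# free energies at 37 C, kcal/mol
# stack key 5'AB3'/3'CD5': pairs A-C and B-D, strand 2 written 3'->5'
stack	AA/UU	-0.93
stack	AC/UG	-2.24
stack	AG/UC	-2.08
stack	AG/UU	-0.55
stack	AU/UA	-1.10
stack	AU/UG	-1.36
stack	CA/GU	-2.11
stack	CC/GG	-3.26
stack	CG/GC	-2.36
stack	CG/GU	-1.41
stack	CU/GA	-2.08
stack	CU/GG	-1.25
stack	GA/CU	-2.35
stack	GA/UU	-1.27
stack	GC/CG	-3.42
stack	GC/UG	-2.51
stack	GG/CC	-3.26
stack	GG/CU	-1.53
stack	GG/UC	-1.25
stack	GG/UU	-0.50
stack	GU/CA	-2.24
stack	GU/CG	-2.51
stack	GU/UA	-1.36
stack	GU/UG	-0.50
stack	UA/AU	-1.33
stack	UA/GU	-1.00
stack	UC/AG	-2.35
stack	UC/GG	-1.53
stack	UG/AC	-2.11
stack	UG/AU	-1.00
stack	UG/GC	-1.41
stack	UG/GU	0.30
stack	UU/AA	-0.93
stack	UU/AG	-1.27
stack	UU/GA	-0.55
stack	UU/GG	-0.50
scalar	duplex_init	4.09
scalar	terminal_au_gu	0.45
scalar	loop_init	3.20
scalar	loop_per_nt	0.40
scalar	max_loop	15
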