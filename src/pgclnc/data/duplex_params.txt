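# Reduced nearest-neighbor free-energy set for intermolecular RNA duplexes
# (kcal/mol, 37 C). Stack keys are "XY,ZW": pair X-Y followed 5'->3' on
# strand A by pair Z-W (first letter = strand A base, second = strand B base).
# Watson-Crick/Watson-Crick stacks follow the standard nearest-neighbor set;
# stacks involving G.U wobbles carry a single package-chosen value. Users may
# substitute a full Turner table in the same format.
init	4.09
stack	AU,AU	-0.93
stack	UA,UA	-0.93
stack	AU,UA	-1.10
stack	UA,AU	-1.33
stack	CG,UA	-2.08
stack	AU,GC	-2.08
stack	CG,AU	-2.11
stack	UA,GC	-2.11
stack	GC,UA	-2.24
stack	AU,CG	-2.24
stack	GC,AU	-2.35
stack	UA,CG	-2.35
stack	CG,GC	-2.36
stack	GC,GC	-3.26
stack	CG,CG	-3.26
stack	GC,CG	-3.42
stack	GU,AU	-1.30
stack	GU,UA	-1.30
stack	GU,CG	-1.30
stack	GU,GC	-1.30
stack	UG,AU	-1.30
stack	UG,UA	-1.30
stack	UG,CG	-1.30
stack	UG,GC	-1.30
stack	AU,GU	-1.30
stack	UA,GU	-1.30
stack	CG,GU	-1.30
stack	GC,GU	-1.30
stack	AU,UG	-1.30
stack	UA,UG	-1.30
stack	CG,UG	-1.30
stack	GC,UG	-1.30
stack	GU,GU	-0.50
stack	GU,UG	-0.50
stack	UG,GU	-0.50
stack	UG,UG	-0.50
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
interior	2	1.50
interior	3	1.80
interior	4	2.00
interior	5	2.20
interior	6	2.50
# loops larger than the tabulated maximum: tabulated(max) + coeff * ln(n/max)
loop_extrapolation	1.08
# interior-loop asymmetry: per-unit penalty and cap
asymmetry	0.50	3.00
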