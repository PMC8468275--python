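top	bottom	dg_kcal_mol
AA	UU	-0.93
AC	UG	-2.24
AG	UC	-2.08
AG	UU	-0.60
AU	UA	-1.10
AU	UG	-0.60
CA	GU	-2.11
CC	GG	-3.26
CG	GC	-2.36
CG	GU	-1.40
CU	GA	-2.08
CU	GG	-1.40
GA	CU	-2.35
GA	UU	-0.60
GC	CG	-3.42
GC	UG	-1.40
GG	CC	-3.26
GG	CU	-1.40
GG	UC	-1.40
GG	UU	-0.40
GU	CA	-2.24
GU	CG	-1.40
GU	UA	-0.60
GU	UG	-0.40
UA	AU	-1.33
UA	GU	-0.60
UC	AG	-2.35
UC	GG	-1.40
UG	AC	-2.11
UG	AU	-0.60
UG	GC	-1.40
UG	GU	-0.40
UU	AA	-0.93
UU	AG	-0.60
UU	GA	-0.60
UU	GG	-0.40
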