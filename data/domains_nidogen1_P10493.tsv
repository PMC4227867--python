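# Best-effort domain ranges for murine nidogen-1 (UniProt P10493-style
# annotation, construct numbering).  Boundaries are approximate and meant
# as an editable starting point; refine against the UniProt release you
# work with.  Historic regions: G1 = NIDO, ua2 = "link", EGF2-5/TY1 = "rod".
protein_id	domain	start	end
NID1	NIDO	31	180
NID1	G2	400	667
NID1	EGF2	668	710
NID1	EGF3	711	755
NID1	EGF4	756	800
NID1	EGF5	801	845
NID1	TY1	846	929
NID1	G3	930	1245
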