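# Best-effort domain ranges for the laminin gamma-1 short arm (UniProt
# P02468-style annotation, construct numbering in which the nidogen-binding
# loop residues are Asp-834/Asn-836/Val-838 of LEb3).  Boundaries are
# approximate and meant as an editable starting point.
protein_id	domain	start	end
LAMC1	LN	1	250
LAMC1	LEa1	251	310
LAMC1	LEa2	311	370
LAMC1	LEa3	371	430
LAMC1	LEa4	431	490
LAMC1	LEa5.1	491	500
LAMC1	L4	501	720
LAMC1	LEa5.2	721	770
LAMC1	LEb1	771	790
LAMC1	LEb2	791	830
LAMC1	LEb3	831	870
LAMC1	LEb4	871	930
LAMC1	LEb5	931	990
LAMC1	LEb6	991	1000
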