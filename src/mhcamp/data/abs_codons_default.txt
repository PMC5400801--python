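# Default antigen-binding-site codon mask (mature-protein numbering).
# These are the commonly used peptide-binding-groove residues of the
# class I alpha-1/alpha-2 domains; the exact ABS definition varies
# between studies, so treat this file as an editable starting point and
# prefer an explicit study-specific list for published analyses.
5
7
9
24
25
33
34
45
59
62
63
66
67
69
70
73
74
76
77
80
81
84
95
97
99
114
116
118
123
124
133
143
146
147
152
155
156
159
160
163
167
171
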