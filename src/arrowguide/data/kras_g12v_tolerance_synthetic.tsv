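pam_index	new_base	indel_rate	source
3	A	0.45	synthetic-illustrative
3	C	0.30	synthetic-illustrative
3	G	0.55	synthetic-illustrative
6	C	0.40	synthetic-illustrative
6	G	0.25	synthetic-illustrative
6	T	0.50	synthetic-illustrative
9	A	0.52	synthetic-illustrative
9	C	0.38	synthetic-illustrative
9	G	0.60	synthetic-illustrative
12	C	0.48	synthetic-illustrative
12	G	0.58	synthetic-illustrative
12	T	0.42	synthetic-illustrative
15	A	0.62	synthetic-illustrative
15	C	0.50	synthetic-illustrative
15	T	0.66	synthetic-illustrative
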