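pam_index	new_base	indel_rate	source
1	A	0.04	synthetic-illustrative
1	G	0.02	synthetic-illustrative
1	T	0.07	synthetic-illustrative
3	A	0.09	synthetic-illustrative
3	C	0.03	synthetic-illustrative
3	G	0.06	synthetic-illustrative
6	C	0.05	synthetic-illustrative
6	G	0.02	synthetic-illustrative
6	T	0.10	synthetic-illustrative
9	A	0.22	synthetic-illustrative
9	G	0.12	synthetic-illustrative
9	T	0.30	synthetic-illustrative
11	A	0.18	synthetic-illustrative
11	C	0.25	synthetic-illustrative
11	T	0.11	synthetic-illustrative
15	A	0.28	synthetic-illustrative
15	C	0.20	synthetic-illustrative
15	T	0.33	synthetic-illustrative
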