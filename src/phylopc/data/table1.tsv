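component	X1	X11	X113	X2	X21	X211	X2111	X2112	X21121	X21122
1	1e-157	1e-41	.	1e-157	1e-85	1e-71	1e-7	1e-43	1e-31	1e-22
2	1e-17	.	.	1e-17	1e-18	1e-20	1e-14	.	1e-26	1e-53
3	.	.	.	.	.	.	.	.	.	1e-4
4	.	.	.	.	.	.	1e-11	1e-6	.	1e-15
5	.	.	.	.	.	.	1e-8	1e-3	.	1e-8
9	.	1e-3	.	.	.	.	.	.	.	.
11	.	.	.	.	.	.	1e-5	.	.	1e-6
12	.	.	.	.	.	.	.	.	.	1e-3
14	.	1e-3	.	.	.	.	.	.	.	.
18	.	1e-3	.	.	.	.	.	.	.	.
25	.	1e-5	.	.	.	.	.	.	.	.
27	.	1e-3	.	.	.	.	.	.	.	.
29	.	1e-3	.	.	.	.	.	.	.	.
33	1e-15	1e-42	1e-4	1e-15	.	.	.	.	.	1e-3
34	1e-6	1e-21	.	1e-6	1e-19	1e-15	.	1e-9	.	.
35	1e-6	1e-30	.	1e-6	.	.	.	.	.	.
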