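# synthetic COILS-style heptad propensity table (residue x heptad position)
aa	a	b	c	d	e	f	g
A	1.2375	1.3184	1.3184	1.2489	1.0132	1.3184	1.0132
C	0.3663	0.3902	0.3902	0.3697	0.1874	0.3902	0.1874
D	0.3392	1.0840	1.0840	0.3423	0.8678	1.0840	0.8678
E	0.6783	2.1680	2.1680	0.6846	3.4711	2.1680	3.4711
F	0.7794	0.4152	0.4152	0.5899	0.1994	0.4152	0.1994
G	0.1238	0.3955	0.3955	0.1249	0.1266	0.3955	0.1266
H	0.5283	1.1257	1.1257	0.5332	0.7209	1.1257	0.7209
I	2.0200	0.5739	0.5739	1.3591	0.4135	0.5739	0.4135
K	0.6316	1.6821	1.6821	0.7967	2.9086	1.6821	2.9086
L	2.7750	0.8869	0.8869	3.2674	0.5680	0.8869	0.5680
M	2.1978	0.7805	0.7805	2.9575	0.7498	0.7805	0.7498
N	0.6105	1.3008	1.3008	0.8215	0.8331	1.3008	0.8331
P	0.0470	0.2502	0.2502	0.0474	0.0481	0.2502	0.0481
Q	1.0774	2.2956	2.2956	1.0873	3.3078	2.2956	3.3078
R	0.5283	1.1257	1.1257	0.5332	1.8023	1.1257	1.8023
S	0.4820	1.3693	1.3693	0.4864	0.8221	1.3693	0.8221
T	0.5387	0.9565	0.9565	0.5437	0.7351	0.9565	0.7351
V	1.5053	0.5346	0.5346	1.0128	0.3852	0.5346	0.3852
W	0.3522	0.3752	0.3752	0.3555	0.3605	0.3752	0.3605
Y	0.5723	0.6098	0.6098	0.5776	0.4393	0.6098	0.4393
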