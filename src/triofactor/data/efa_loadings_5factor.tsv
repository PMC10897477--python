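trait	p	NDV	PSYCH	CONS	RESID	error
ADHD	0.211	0.425	0.014	-0.051	-0.022	0.772
ANOR	0.173	0.094	0.073	0.127	-0.056	0.937
ASD	0.166	0.625	0.003	0.026	0.012	0.581
BIPO	0.111	0.019	0.436	-0.003	0.030	0.796
MDD	0.747	-0.003	-0.004	-0.007	0.636	0.037
NEUR	0.504	-0.070	-0.057	0.057	0.047	0.732
OCD	0.062	-0.014	0.073	0.217	-0.026	0.943
PTSD	0.277	-0.009	0.022	-0.035	-0.107	0.910
SCHZ	0.166	0.002	0.374	0.028	-0.055	0.829
ANXI	0.496	0.022	-0.031	-0.027	0.002	0.752
AUD	0.150	-0.036	0.015	-0.108	-0.067	0.960
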