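trait	p	NDV	PSYCH	CONS
ADHD	0.211	0.425	0	0
ANOR	0.173	0	0	0.127
ASD	0.166	0.625	0	0
BIPO	0.111	0	0.436	0
MDD	0.747	0	0	0
NEUR	0.504	0	0	0
OCD	0.062	0	0	0.217
PTSD	0.277	0	0	0
SCHZ	0.166	0	0.374	0
ANXI	0.496	0	0	0
AUD	0.150	0	0	-0.108
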