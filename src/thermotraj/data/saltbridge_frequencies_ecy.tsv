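# Published replica-mean salt-bridge frequencies for the mesophilic CheY (EcY)
# at the five simulated temperatures (K).  "elements" names the secondary
# structures the pair connects; a single label means an intra-element pair.
# basic	acidic	elements	302	328	374	400	450
ARG22	GLU35	a1-b2	0.980	0.956	0.859	0.768	0.272
LYS45	ASP41	a2	0.964	0.951	0.912	0.898	0.695
LYS109	ASP57	b3-b5/a5	0.812	0.727	0.515	0.434	0.173
LYS109	ASP12	b1/a1-b5/a5	0.636	0.527	0.215	0.092	0.023
ARG18	GLU35	a1-b2	0.634	0.718	0.783	0.804	0.197
ARG18	GLU37	a1-b2/a2	0.398	0.346	0.418	0.451	0.167
LYS91	GLU89	b4/a4	0.375	0.334	0.219	0.179	0.165
LYS70	GLU67	a3	0.300	0.348	0.412	0.267	0.372
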