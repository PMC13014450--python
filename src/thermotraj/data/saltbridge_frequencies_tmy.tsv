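# Published replica-mean salt-bridge frequencies for the hyperthermophilic
# CheY (TmY) at the five simulated temperatures (K).
# basic	acidic	elements	302	328	374	400	450
LYS104	ASP9	b1/a1-b5/a5	0.981	0.987	0.979	0.970	0.486
LYS104	ASP54	b3-b5/a5	0.948	0.978	0.950	0.944	0.885
LYS24	ASP20	a1	0.909	0.881	0.856	0.849	0.740
ARG15	GLU32	a1-b2	0.682	0.701	0.715	0.712	0.676
LYS19	GLU32	a1-b2	0.668	0.649	0.618	0.636	0.622
ARG110	GLU113	a5	0.662	0.487	0.505	0.488	0.466
LYS77	ASP49	a2/b3-a3/b4	0.560	0.533	0.453	0.482	0.475
LYS117	ASP100	b5-a5	0.554	0.593	0.625	0.630	0.524
ARG110	ASP100	b5-a5	0.491	0.605	0.714	0.741	0.570
ARG37	GLU68	a2-a3	0.468	0.501	0.372	0.383	0.173
LYS95	GLU92	a4	0.427	0.462	0.523	0.552	0.346
ARG4	GLU28	b1-b2	0.420	0.424	0.422	0.426	0.435
ARG37	ASP64	a2-a3	0.404	0.517	0.334	0.384	0.318
LYS71	GLU68	a3	0.382	0.465	0.469	0.470	0.516
LYS44	GLU41	a2	0.362	0.371	0.424	0.432	0.463
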