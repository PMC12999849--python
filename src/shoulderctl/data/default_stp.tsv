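# spatial tuning pattern; window_ms=1000.0
# provenance: synthetic EMG fixture (seed 0), 17 subjects
muscle	flexion	extension	adduction	abduction	flexion_adduction	flexion_abduction	extension_adduction	extension_abduction	baseline
ant_deltoid	0.2076494281	0.5297093419	0.209339093	0.3865914263	0.2055910078	0.2084796178	0.2170490046	0.729897426	0.0459096904
mid_deltoid	0.1996343691	0.2909143142	0.6257032609	0.2019080171	0.2417551518	0.2008563474	0.6736410002	0.2011220111	0.04591605258
post_deltoid	0.6757141359	0.2073214908	0.2609002929	0.207499309	0.6393966874	0.2836732628	0.2112654369	0.2047947466	0.04630298768
pect_major_clav	0.2022431855	0.2387162482	0.2003093629	0.687283992	0.2037513691	0.3050475672	0.2013760435	0.6225218647	0.04579483142
pect_major_stern	0.2488003043	0.2024746496	0.2025640003	0.6788820255	0.2100373573	0.6294907102	0.2068711307	0.2984630026	0.0460678249
latissimus_dorsi	0.5294720055	0.2063796327	0.2015483099	0.3970176764	0.2125469345	0.7272479263	0.2013299855	0.2023137101	0.04625834897
infraspinatus	0.2082498088	0.4444127209	0.1992578358	0.491017753	0.1939532594	0.2007409668	0.2125246494	0.7347695337	0.04607269133
biceps_brachii	0.1311870727	0.4633147944	0.1249647548	0.1340502218	0.1300251677	0.1268761679	0.2485568544	0.3455371405	0.02955345831
triceps_brachii	0.385129841	0.1091325302	0.1106163188	0.1222687886	0.1914258966	0.3164491016	0.1129216562	0.1105069868	0.02525895989
upper_trapezius	0.452398486	0.2057188388	0.2036745514	0.4549620233	0.2091123964	0.7406601254	0.1993472296	0.2006883823	0.0462087853
middle_trapezius	0.2088627114	0.4636478546	0.1978731449	0.4633686026	0.1987784736	0.198777011	0.2009276532	0.7412236087	0.04615510927
lower_trapezius	0.2061128777	0.7414444019	0.2071771026	0.1958776479	0.2037503775	0.2015015765	0.454613028	0.4569611356	0.04575786991
serratus_anterior	0.4605602293	0.2015008088	0.4604489328	0.2104317057	0.7414859672	0.2033628369	0.2044987151	0.2026714501	0.04567265987
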