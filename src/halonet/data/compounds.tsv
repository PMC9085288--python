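number	name	formula	compound_class	adduct	loss_chain	source_species	note
1	4beta-hydroxydictyodial	C20H30O3	xeniane diterpene	[M+H]+	H2O;H2O	Canistrocarpus cervicornis; Dictyota mertensii	F1 node m/z 319.2274 (RT 8.96 min); successive water losses to 301.2172 and 283.2065
2	4beta-acetoxydictyodial A	C22H32O4	xeniane diterpene	[M+H]+	H2O;H2O	Canistrocarpus cervicornis; Dictyota mertensii	F1 node m/z 361.2383 (RT 10.48 min); acetylated derivative of 1 (+42 Da)
3	18,4-dihydroxydictyo-19-al A	C20H32O3	xeniane diterpene	[M+H]+	H2O;H2O;H2O	Canistrocarpus cervicornis; Dictyota mertensii	F1 node m/z 321.2441 (RT 7.74 min); three successive water losses
4	18-acetoxy-4-hydroxydictyo-19-al A	C22H34O4	xeniane diterpene	[M+Na]+	NaOH;H2O;ketene	Canistrocarpus cervicornis; Dictyota mertensii	F1 sodiated precursor m/z 385.2359; NaOH/H2O/ketene loss ladder to 267.2134
5	dictyotadiol	C20H32O2	guaiane prenylated diterpene	[M+Na]+	NaOH;H2O	Dictyota dichotoma	F1 sodiated precursor m/z 327.2287; isomeric with 6
6	dictyol B	C20H32O2	guaiane prenylated diterpene	[M+Na]+	NaOH;H2O	Dictyota crenulata	F1 sodiated precursor m/z 327.2287; isomeric with 5
7	dictyol B acetate	C22H34O3	guaiane prenylated diterpene	[M+Na]+	NaOH;H2O	Dictyota dichotoma	F1 node m/z 369.2395 (RT 12.00 min); acetylated derivative of 5/6 (+42 Da)
8	dictyoxide	C20H32O	guaiane prenylated diterpene	[M+H]+	H2O	Dictyota mertensii	F1 precursor m/z 289.2550 (RT 13.09 min); isomeric with 9
9	pachydictyol A	C20H32O	guaiane prenylated diterpene	[M+H]+	H2O	Dictyota mertensii	F1 precursor m/z 289.2550; isolated from extract DM2
10	9-hydroxy-4,10-dibromo-3-chloro-alpha-chamigrene	C15H23Br2ClO	chamigrane sesquiterpene	[M+H]+	HBr;HBr;HCl	Laurencia nidifica; L. nipponica; L. pacifica	F3 node m/z 412.9883 (LC2); Br2Cl cluster 3:7:5:1
11	2,10-dibromo-3-chloro-8-hydroxy-beta-chamigrene	C15H23Br2ClO	chamigrane sesquiterpene	[M+H]+	HBr;HBr;HCl	Laurencia nipponica	F3 node m/z 412.9883 (LC2)
12	laucapyranoid A	C15H23Br2ClO	bisabolane-related	[M+H]+	HBr;HBr;HCl	Laurencia caespitosa	F3 node m/z 412.9883 (LC2); rearranged bisabolane skeleton
13	laucapyranoid B	C15H23Br2ClO2	bisabolane-related	[M+H]+	H2O;HBr	Laurencia caespitosa	F4 precursor m/z 428.9848 (LC2)
14	laucapyranoid C	C15H23Br2ClO2	bisabolane-related	[M+H]+	H2O;HBr	Laurencia caespitosa	F4 precursor m/z 428.9848 (LC2)
15	4,10-dibromo-3-chloro-7,8-epoxy-9-hydroxychamigrane	C15H23Br2ClO2	chamigrane sesquiterpene	[M+H]+	H2O;HBr	Laurencia glomerata; L. flagellifera	F4 precursor m/z 428.9848 (LC2)
16	4,10-dibromo-3-chloro-7,8-epoxychamigrane	C15H23Br2ClO2	chamigrane sesquiterpene	[M+H]+	H2O;HBr	Laurencia sp.	F4 precursor m/z 428.9848 (LC2)
17	4,10-dibromo-3-chloro-7,8-epoxy-5-hydroxychamigrane	C15H23Br2ClO2	chamigrane sesquiterpene	[M+H]+	H2O;HBr	Laurencia scoparia	F4 precursor m/z 428.9848 (LC2)
18	laurendecumallene A	C15H22Br2O4	C15-acetogenin	[M+H]+	H2O;H2O;Br	Laurencia decumbens	F7 precursor m/z 424.9951 (LC1, RT 5.46 min); Br2 cluster 1:2:1
19	laurendecumallene B	C15H22Br2O4	C15-acetogenin	[M+H]+	H2O;H2O;Br	Laurencia decumbens	F7 precursor m/z 424.9951 (LC1)
20	prepacifenol epoxide	C15H21Br2ClO3	chamigrane sesquiterpene	[M+H]+	HCl;H2O	Laurencia catarinensis (LC1); L. composita; L. johnstonii	F7 precursor m/z 442.9620 (RT 7.93 min); isolated from LC1
21	johnstonol	C15H21Br2ClO3	chamigrane sesquiterpene	[M+H]+	HCl;H2O	Laurencia catarinensis (LC1); L. nidifica; L. okamurai	F7 precursor m/z 442.9620; isolated from LC1; rearrangement product of 20
22	laureepoxide	C15H20Br2O2	C15-acetogenin	[M+H]+	H2O;HBr	Laurencia nipponica	individual node m/z 390.9898 (LC1); Br2 cluster 1:2:1; one tetrahydrofuran ring
23	(3E)-elatenyne	C15H20Br2O2	C15-acetogenin	[M+H]+	H2O;HBr	Laurencia majuscula	individual node m/z 390.9898 (LC1); two isolated tetrahydrofuran rings
24	elatenyne	C15H20Br2O2	C15-acetogenin	[M+H]+	H2O;HBr	Laurencia decumbens; L. elata	individual node m/z 390.9898 (LC1)
25	kumausallene	C15H20Br2O2	C15-acetogenin	[M+H]+	H2O;HBr	Laurencia nipponica	individual node m/z 390.9898 (LC1); two fused tetrahydrofuran rings
26	laurobtusin	C15H20Br2O2	C15-acetogenin	[M+H]+	H2O;HBr	Laurencia obtusa	individual node m/z 390.9898 (LC1); six-membered cyclic ether
27	pacifenol	C15H21Br2ClO2	chamigrane sesquiterpene	[M+H]+	H2O	Laurencia catarinensis (LC1); L. filiformis; L. majuscula	individual nodes m/z 408.9581/410.9542 (RT 9.80 min); isolated from LC1
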