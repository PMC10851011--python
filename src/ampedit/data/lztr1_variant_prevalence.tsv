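variant_label	protein_label	inheritance	second_variant	freq_exome_v2	freq_genome_v2	freq_genome_v3	printed_mean
c.1407G>A	p.W469*	recessive	p.Y749C	0,000138	0,000223	0,0001708	0,00017727
c.1943-256C>T		recessive	p.Q10Afs*; p.Y726*; p.R688G; c.2325+G>A; c.1943-256C>T	0,00004073	0,0001597	0,00007911	0,00009318
c.628C>T	p.R210*	recessive	p.D531N; p.V579M; c.2220-17C>A	0,00007195	0,00009567	0,00009873	0,00008878
c.2062C>T	p.R688C	recessive	c.1149+1G>T	0,00004431	0,00009575	0,0000526	0,00006422
c.1084C>T	p.R362*	recessive	c.1149+1G>T	0,00005975	0,00006378	0,00006572	0,00006308
c.27dupG	p.Q10Afs*	recessive	c.1943-256C>T	0,0001004	0,00003187	0,000046	0,00005942
c.27delG	p.Q10Rfs*	recessive	c.1149+G>A	0,00006274	not detected	0,00001972	0,00002749
c.1385T>C	p.I462T	recessive	p.A461D	0,00001613	0,00003187	0,00001314	0,00002038
c.1591G>A	p.D531N	recessive	p.R210*	0,00002566	not detected	0,00003285	0,00001950
c.2462T>C	p.I821T	recessive	p.I821T	not detected	0,00003187	0,00001314	0,00001500
c.2090G>A	p.R697Q	recessive	c.2407-2A>G	0,00002388	not detected	0,00001972	0,00001453
c.2220-17C>A		recessive	p.R210*	0,000003994	0,00003189	not detected	0,00001196
c.1735G>A	p.V579M	recessive	p.R210*; c.2070-2A>G	0,00001998	not detected	0,00001314	0,00001104
c.508C>T	p.R170W	recessive	p.I205T	0,00001195	not detected	0,00001972	0,00001056
c.1964T>C	p.M655T	recessive	p.M655T	0,00001194	not detected	0,00001972	0,00001055
c.-38T>A		recessive	p.W437*	0,000008025	not detected	0,00001315	0,00000706
c.2246A>G	p.Y749C	recessive	p.W469*	0,000003981	not detected	0,00001318	0,00000572
c.1149+1G>A		recessive	p.Q10fs*	0,000008114	not detected	0,000006571	0,00000490
c.2407-2A>G		recessive	p.R697Q	not detected	not detected	0,00001315	0,00000438
c.2325+1G>A		recessive	c.1943-256C>T	not detected	not detected	0,00001314	0,00000438
c.2074T>A	p.F692L	recessive	p.F692L	0,00000398	not detected	0,000006571	0,00000352
c.1430C>T	p.A477V	dominant		0,000008276	not detected	not detected	0,00000276
c.614T>C	p.I205T	recessive	p.R170W	0,000007978	not detected	not detected	0,00000266
c.850C>T	p.R284C	dominant		not detected	not detected	0,000006572	0,00000219
c.848G>A	p.R283Q	dominant		not detected	not detected	0,000006571	0,00000219
c.2102C>A	p.P701H	recessive	c.2069+2T>C	not detected	not detected	0,000006571	0,00000219
c.1311G>A	p.W437*	recessive	c.-38T>A	not detected	not detected	0,000006569	0,00000219
c.1149+1G>T		recessive	p.R362*; p.R688C	0,000004057	not detected	not detected	0,00000135
c.1687G>C	p.E563Q	recessive	p.E563Q	0,000004	not detected	not detected	0,00000133
c.2178C>A	p.Y726*	recessive	c.1943-256C>T	0,000003986	not detected	not detected	0,00000133
c.2264G>A	p.R755Q	recessive	p.H121D	0,000003982	not detected	not detected	0,00000133
c.2070-2A>G		recessive	p.V579M	0,000003981	not detected	not detected	0,00000133
c.290G>T	p.R97L	dominant		not detected	not detected	not detected	–
c.347C>T	p.A116V	dominant		not detected	not detected	not detected	–
c.355T>C	p.Y119H	dominant		not detected	not detected	not detected	–
c.356A>G	p.Y119C	dominant		not detected	not detected	not detected	–
c.361C>G	p.H121D	recessive	p.R755Q	not detected	not detected	not detected	–
c.406T>C	p.Y136H	dominant		not detected	not detected	not detected	–
c.407A>G	p.Y136C	dominant		not detected	not detected	not detected	–
c.428A>G	p.N143S	dominant		not detected	not detected	not detected	–
c.434A>T	p.N145I	dominant		not detected	not detected	not detected	–
c.509G>C	p.R170P	recessive	p.C792G	not detected	not detected	not detected	–
c.606_650del	p.M202fs*	dominant		not detected	not detected	not detected	–
c.650A>C	p.E217A	recessive	p.E217A	not detected	not detected	not detected	–
c.730T>C	p.S244P	dominant		not detected	not detected	not detected	–
c.731C>G	p.S244C	dominant		not detected	not detected	not detected	–
c.740G>A	p.S247N	dominant		not detected	not detected	not detected	–
c.742G>A	p.G248R	dominant		not detected	not detected	not detected	–
c.743G>A	p.G248E	dominant		not detected	not detected	not detected	–
c.756_758del	p.N253del	dominant		not detected	not detected	not detected	–
c.859C>T	p.H287Y	dominant		not detected	not detected	not detected	–
c.1382C>A	p.A461D	recessive	p.I462T	not detected	not detected	not detected	–
c.1660G>C	p.A554P	dominant		not detected	not detected	not detected	–
c.1739T>C	p.L580P	recessive	p.L580P	not detected	not detected	not detected	–
c.2062C>G	p.R688G	recessive	c.1943-256C>T	not detected	not detected	not detected	–
c.2069+2T>C		recessive	p.P701H	not detected	not detected	not detected	–
c.2374T>G	p.C792G	recessive	p.R170P	not detected	not detected	not detected	–
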