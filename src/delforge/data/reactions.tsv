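name	role	smarts
sulfonylation	sulfonylation	[#7:1].[Cl:2][S:3]( = [O:4]) = [O:5]>>[#7:1][S:3]( = [O:4]) = [O:5]
reductive_amination	reductive_amination	[#7:1].[*:4]-[#6:2] = [O:3]>>[#7:1]-[#6;h2:2]-[*:4]
acylation	acylation	[#7:1].[#8;h1:2]-[#6:3] = [O:4]>>[#7:1]-[#6:3] = [O:4]
suzuki_I	suzuki_I	I[*:1].[#8]-[#5](-[#8])-[*:2]>>[#6:2]-[*:1]
suzuki_Br	suzuki_Br	Br[*:1].[#8]-[#5](-[#8])-[*:2]>>[#6:2]-[*:1]
primary_amine_dummy	dummy_template	[#7;h2:1]>>[#6]-[#7]-[#6]( = O)-[#6]−1-[#6](-[#6]-[#6]-[#7]−1-[#6]-[#6]−1 = [#6]-[#6](C#N) = [#6](-[#6]−2-[#6]-[#6]−2)-[#6](F) = [#6]−1)-[#6]−1 = [#6]-[#6](-[#7;h1:1]) = [#6]-[#6] = [#6]−1
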