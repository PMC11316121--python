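# Cohort table: published case series of 39 infertile men carrying biallelic
# variants in 14 piRNA-pathway genes (azoo-, crypto-, or extreme
# oligozoospermia). Transcribed verbatim from the printed table, including
# its formatting quirks (embedded spaces, one stray "c." prefix); phenotype
# column holds "semen phenotype; histology [TESE outcome]" tokens.
id	gene	variant_c	variant_p	phenotype
M928	DDX4	[1532 C>T];[1532 C>T]	[(Ala511Val)];[(Ala511Val)]	Crypto; RsA
M2546	FKBP6	[508_529dup];[832 C>T]	[(Phe177Cysfs*20)];[(Arg278*)]	Crypto; RsA
M2548	FKBP6	[508_529dup];[508_529dup]	[(Phe177Cysfs*20)];[(Phe177Cysfs*20)]	Crypto; RsA
M1400	FKBP6	[589-2 A>G];[589-2 A>G]	[(Ala197Glyfs*31)];[(Ala197Glyfs*31)]	Crypto; RsA
MI-0042P	GPAT2	[146G>A];[146G>A]	[(Arg49His)];[(Arg49His)]	ExtOligo
M2556	GPAT2	[1156-1G>A];[1156-1G>A]	[(Glu386Valfs*16)];[(Glu386Valfs*16)]	Crypto; MeiA
M13	GPAT2	[1130A>G];[1954C>T]	[(His377Arg)];[(Arg652*)]	Azoo; SCO
M454	GPAT2	[1130A>G];[146G>A]	[(His377Arg)];[(Arg49His)]	Azoo; SCO
17-051	GPAT2	[1388C>T];[1388C>T]	[(Thr463Met)];[(Thr463Met)]	Azoo; SCO
15-0730	GPAT2	[1388C>T];[1388C>T]	[(Thr463Met)];[(Thr463Met)]	Azoo; SCO
M690	GPAT2	[1879C>T];[1879C>T]	[(Arg627Trp)];[(Arg627Trp)]	Azoo; MeiA
M1844	GPAT2	[1879C>T];[1879C>T]	[(Arg627Trp)];[(Arg627Trp)]	Azoo; SCO
M2043	GTSF1	[97C>A];[97C>A]	[(His33Asn)];[(His33Asn)]	Azoo; MeiA
M2243	GTSF1	[221_222del];[221_222del]	[(Arg74Lysfs*4)];[(Arg74Lysfs*4)]	Azoo; MeiA
M3079	HENMT1	[400A>T];[400A>T]	[(Ile134Leu)];[(Ile134Leu)]	Azoo; RsA
M2435	MAEL	[799C>T];[908+1G>C]	[(Arg267*)];[(Cys283_Ala303del)]	Azoo, MeiA
TP17	MOV10L1	[2179+3A>G];[2179+3A>G]	[(Asn691*)];[(Asn691*)]	Azoo; SpgA
M1948	MOV10L1	[2258T>C];[2258T>C]	[(Val753Ala)];[(Val753Ala)]	Azoo
TP24	MOV10L1	[3115G>A];[3115G>A]	[(Glu1039Lys)];[(Glu1039Lys)]	Azoo; SCO
MI_Proband02199	MOV10L1	[3268G>T];[3268G>T]	[(Val1090Phe)];[(Val1090Phe)]	Azoo; SCO
M2006	PIWIL1	[688C>T];[688C>T]	[(Arg230*)];[(Arg230*)]	Azoo; RsA
TP32	PIWIL2	[839A>C];[839A>C]	[(Tyr280Ser)];[(Tyr280Ser)]	Azoo; SCO
M2949	PIWIL2	[1697G>A];[1697G>A]	[(Arg566His)];[(Arg566His)]	Azoo
M2173	PLD6	[1A>T];[1A>T]	[(Met1?)];[(Met1?)]	Azoo; SCO
M2803	PLD6	[469del];[469del]	[(His157Thrfs*102)];[(His157Thrfs*102)]	Azoo; SCO
M3274	PNLDC1	[790G>T]; [790G>T]	[(Val264Leu)];[(Val264Leu)]	Crypto
M1125	PNLDC1	[1058A>G];[1058A>G]	[(Tyr353Cys)];[(Tyr353Cys)]	Crypto; ES+
M1648	TDRD1	[887C>A];[887C>A]	[(Ser296Tyr)];[(Ser296Tyr)]	Azoo; MeiA
M2842	TDRD9	[1243G>T];[1243G>T]	[(Val415Phe)];[(Val415Phe)]	ExtOligo
M800	TDRD9	[3148dup];[3148dup]	[(Val1050Glyfs*49)];[(Val1050Glyfs*49)]	ExtOligo, ES+ positive TESE
M3007	TDRD9	[3716+3A>G];[c.3716+3A>G]	[(Ser1208Leufs*56)];[(Ser1208Leufs*56)]	ExtOligo
M2442	TDRD9	[3826 G>T];[3826 G>T]	[(Val1276Phe)];[(Val1276Phe)]	Crypto
M2662	TDRD12	[287A>C];[287A>C]	[(Asp96Ala)];[(Asp96Ala)]	Azoo; SCO
M1642	TDRD12	[593A>G];[593A>G]	[(Asn198Ser)];[(Asn198Ser)]	Azoo; SCO
TP5	TDRD12	[963+1G>T];[963+1G>T]	[(Asp289Alafs*3)];[(Asp289Alafs*3)]	Azoo; MeiA
M2227	TDRD12	[986G>A];[986G>A]	[(Trp329*)];[(Trp329*)]	Azoo; RsA
M2940	TDRD12	[2419C>T];[2419C>T]	[(Arg807Cys)];[(Arg807Cys)]	Crypto
M2317	TDRD12	[2432G>A];[2432G>A]	[(Arg811Gln)];[(Arg811Gln)]	Azoo; ES+
M2595	TDRD12	[3157del];[3157del]	[(Leu1053Phefs*4)];[(Leu1053Phefs*4)]	Azoo; ES+
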