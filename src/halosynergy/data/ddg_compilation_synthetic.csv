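# Synthetic reconstruction of the per-pair DDG compilation for the three
# halophilic proteins (ferredoxin 1DOI, protein L 2KAC, dihydrofolate
# reductase 2ITH).  The individual values are NOT measured: they were
# constructed to be consistent with every published summary constraint
# (18 folded pairs at b_KCl = 2 mol/kg with 5 synergistic, 3 fully
# shielded and 10 interfering; one weakly synergistic site at -0.5 at
# b_KCl = 0.15 mol/kg; synergistic magnitudes -0.5..-2; overall range
# -3 < DDG < +3; synergy most frequent in protein L; unfolded protein L
# almost entirely synergistic).  Units kcal/mol.
protein,pdb_id,state,salt_molality,pair,ddg
protein_L,2KAC,folded,2.0,"(D,N36)...E41Q",-1.8
protein_L,2KAC,folded,2.0,"(D,N38)...E41Q",-1.2
protein_L,2KAC,folded,2.0,"(E,Q27)...D24N",-0.6
protein_L,2KAC,folded,2.0,"(D,N49)...E46Q",0.2
protein_L,2KAC,folded,2.0,"(E,Q16)...D19N",-0.3
protein_L,2KAC,folded,2.0,"(D,N24)...E27Q",0.8
protein_L,2KAC,folded,2.0,"(E,Q32)...D29N",1.3
protein_L,2KAC,folded,2.0,"(D,N55)...D53N",0.9
ferredoxin,1DOI,folded,2.0,"(D,N70)...E73Q",-0.9
ferredoxin,1DOI,folded,2.0,"(E,Q12)...D15N",0.4
ferredoxin,1DOI,folded,2.0,"(D,N39)...D41N",0.6
ferredoxin,1DOI,folded,2.0,"(E,Q57)...E60Q",1.1
ferredoxin,1DOI,folded,2.0,"(D,N85)...E88Q",1.6
ferredoxin,1DOI,folded,2.0,"(E,Q94)...D97N",0.7
dhfr,2ITH,folded,2.0,"(D,N104)...E107Q",-0.7
dhfr,2ITH,folded,2.0,"(E,Q48)...D51N",1.0
dhfr,2ITH,folded,2.0,"(D,N131)...D134N",0.5
dhfr,2ITH,folded,2.0,"(E,Q22)...E25Q",1.9
protein_L,2KAC,folded,0.15,"(D,N38)...E41Q",-0.5
protein_L,2KAC,folded,0.15,"(D,N36)...E41Q",0.9
protein_L,2KAC,folded,0.15,"(E,Q27)...D24N",1.4
protein_L,2KAC,folded,0.15,"(D,N24)...E27Q",0.6
ferredoxin,1DOI,folded,0.15,"(D,N70)...E73Q",1.8
ferredoxin,1DOI,folded,0.15,"(E,Q12)...D15N",1.1
ferredoxin,1DOI,folded,0.15,"(D,N39)...D41N",0.7
ferredoxin,1DOI,folded,0.15,"(E,Q57)...E60Q",1.5
protein_L,2KAC,unfolded,2.0,"(D,N36)...E41Q",-2.6
protein_L,2KAC,unfolded,2.0,"(D,N38)...E41Q",-1.9
protein_L,2KAC,unfolded,2.0,"(E,Q27)...D24N",-1.4
protein_L,2KAC,unfolded,2.0,"(D,N49)...E46Q",-0.8
protein_L,2KAC,unfolded,2.0,"(E,Q16)...D19N",-0.7
protein_L,2KAC,unfolded,2.0,"(D,N55)...D53N",0.3
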