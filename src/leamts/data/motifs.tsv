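# Presequence cleavage-motif definitions.
# pattern: comma-separated residue-class tokens; "|" marks the scissile bond.
# Tokens: X = any residue; PHI = hydrophobic {AVLIMFWYC}; PSI = hydrophilic
# (the complement of PHI); X{a..b} = a to b arbitrary residues (variable gap);
# any other token is an explicit residue alternative set.
# plant: whether the motif class is observed in plant presequences.
# priority: specificity rank used when one bond matches several motifs
# (lower = more specific).
id	pattern	plant	priority	description
minus3R_plant	R,X,FYL,|,SA,SAT,X	yes	1	plant -3R consensus with Ser/Ala enrichment after the bond
minus3R_general	R,X,FYL,|,AS,X	yes	2	general -3R motif, Arg three residues before the bond
minus10R	R,X,FLI,X,X,TSG,X,X,X,X,|,X	no	3	-10R motif; not observed in plant presequences
minus2R	R,X,|,X	yes	4	-2R motif, Arg two residues before the bond
noR_plant	FY,|,SA	yes	5	no-R motif conserved in plants, aromatic before the bond
MPP_core	RK,X{0..10},R,X,|,PHI,PSI,PSI	yes	9	MPP recognition core; corroborating annotation only
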