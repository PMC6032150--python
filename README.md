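# leamts

Structural analysis of N-terminal mitochondrial targeting sequences (MTS)
for small plant LEA_3-family proteins — built for the question of why one
of two near-identical paralogs is imported into mitochondria while the
other stays cytosolic.

The package is aimed at protein scientists dissecting presequences: it
turns a FASTA record plus a first-helix annotation into a helical-wheel
projection, a hydrophobic moment, a cleavage-site call, and an auditable
mitochondrial/cytosolic verdict.

## What it computes

**Helical-wheel geometry.** Residue *k* of an 18-residue window is placed
at (100·*k*) mod 360°, the ideal α-helix rise. The hydrophobic moment is

&nbsp;&nbsp;&nbsp;&nbsp;**μ** = (1/N) Σₖ *h*ₖ (cos θₖ, sin θₖ),&nbsp;&nbsp;θₖ = 100°·k,

with *h*ₖ from a bundled hydrophobicity scale (Fauchère–Pliska by
default). The hydrophobic face is the longest circular run of occupied
20° slots whose residues are all nonpolar; charged residues are zoned as
face, interface (≤ 40° from a face end), opposite pole (> 90° from the
face center), or other.

**Cleavage motifs.** A scanner for the presequence motif classes
-2R {R-X↓X}, -3R {R-X-(F/Y/L)↓(A/S)-X}, the plant -3R consensus
{R-X-(F/Y/L)↓(S/A)-(S/A/T)-X}, -10R, the plant no-R motif {(F/Y)↓(S/A)},
and the MPP core {(R/K)-Xn-R-X↓Φ-Ψ-Ψ} (corroboration only). An MPP site
followed by Ala/Ser is trimmed by one residue by the ICP55 step, yielding
two adjacent mature N-termini.

**Targeting rule.** A sequence is called mitochondrial iff (C1) the face
has ≥ 5 residues — four is not enough; (C2) exactly two K/R sit at the
opposite pole, one pair separated by four sequence positions (40° on the
wheel); (C3) exactly one D/E sits at the interface; and (C4) a -3R motif
fires in residues 1–60 **and** the 11 residues after the last cleavage
site contain ≥ 3 Ser.

**Construct algebra.** Segment deletion, segment replacement, point
substitution, and adjacent-pair charge inversion, with declared-original
safety checks, plus the nine-member GFP construct panel
(LEA2, LEA38, LEA2del, LEA38del, LEA2.1–LEA2.5) and its empirical
localization labels.

**Consensus/logo.** Per-column frequencies and information content
(log₂20 − H, optional small-sample correction 19/(2·ln2·n)) over aligned
40-residue N-termini, and degenerate-consensus extraction such as
{R-R-G-(Y/F)↓A↓A-(A/T)-(A/S)}.

**Synthetic data.** A seeded generator of rule-positive sequences,
single-condition decoys (face_shrink, charge_swap, negative_move,
segment_delete, motif_kill), and conserved aligned families with a
planted consensus. Labels are rule-defined, not biological.

## Worked example

```python
import leamts as lm

base2, base38 = lm.lea2_like(), lm.lea38_like()   # synthetic 91/97-aa stand-ins

# two adjacent cleavage sites on the printed presequence segment
sites = lm.best_cleavage(base38)
print([(s.motif_id, s.cleave_after, s.source) for s in sites])
# [('minus3R_plant', 28, 'MPP'), ('minus3R_plant', 29, 'ICP55')]

series = lm.build_construct_series(base2, base38)
print(lm.classify_panel(series)[["construct", "verdict", "empirical", "agree"]])
```

```
  construct        verdict      empirical  agree
0      LEA2      cytosolic      cytosolic   True
1     LEA38  mitochondrial  mitochondrial   True
2   LEA2del      cytosolic      cytosolic   True
3  LEA38del      cytosolic      cytosolic   True
4    LEA2.1  mitochondrial  mitochondrial   True
5    LEA2.2      cytosolic      cytosolic   True
6    LEA2.3      cytosolic      cytosolic   True
7    LEA2.4      cytosolic      cytosolic   True
8    LEA2.5  mitochondrial  mitochondrial   True
```

The presequence is cut after position 28 (the Tyr of the -3R context) and
again after 29 once ICP55 removes the first Ala; the panel shows that
only the wild-type mitochondrial protein, the 43-residue N-terminal
chimera, and the triple mutant (segment replacement + Q11V + EK→KE
inversion) satisfy all four conditions — deleting the downstream
Ser-rich segment, restoring the face alone, or restoring the charges
alone each leaves the verdict cytosolic.

The same pipeline is scriptable from the shell:

```bash
leamts mutate bases.fasta --panel --out panel.fasta
leamts analyze panel.fasta --helix LEA38:7-24 ... --out-prefix panel
leamts simulate --seed 1 --n 20 --ablation charge_swap --out-prefix decoys
```

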