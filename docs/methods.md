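# Methods

## The model

Cleavable N-terminal mitochondrial targeting sequences (MTS) tend to fold
into an amphiphilic α-helix: hydrophobic residues cluster on one side of
the helical cylinder, positive charges on the other. `leamts`
operationalizes that picture for a family of short plant LEA_3 proteins
as an explicit, auditable rule over two measurable objects — the helical
wheel of the first N-terminal helix and the cleavage-site context — and
packages everything needed to test the rule without external data.

### Wheel geometry

Residue *k* (0-based) of the annotated window is placed at
θₖ = (100·k) mod 360°, the rise of an ideal α-helix. An 18-residue
window is the canonical choice because 18·100° ≡ 0 (mod 360°): every one
of the eighteen 20° slots is occupied exactly once, so "adjacent slots"
is well defined. Windows of 6–17 residues are accepted; shorter or
longer ones are rejected (a 19th residue would alias the first).

The hydrophobic moment is the *mean* resultant of per-residue
hydrophobicity vectors (mean rather than sum, so magnitudes compare
across window sizes). The rotation direction and the zero angle are
conventions; property tests assert that magnitudes, face membership and
charge zones are invariant to both.

The hydrophobic face is the longest circular run of consecutive occupied
slots whose residues all belong to the nonpolar set
{A, C, F, G, I, L, M, V, W, Y}. Gly and Ala are deliberately included:
the faces this family actually shows (AGAL, VAGAL, VAVVL) contain both.
Ties between equally long runs are broken toward the run whose angular
center lies closest to the moment direction, then by smallest start
angle; both steps are deterministic. Face detection is verified against
an exhaustive enumeration of all circular runs on random windows.

Charge zones, evaluated in this order per charged residue (K/R, D/E):
**face** (a member slot — unreachable for charges with the default
nonpolar set, kept for configurability), **interface** (within one slot,
≤ 40°, of a face end; the smallest tolerance that makes "at the border
between the faces" meaningful at 20° granularity), **opposite pole**
(> 90° from the face center), **other**. With an empty face all zones
are reported as `other` with an explicit flag.

### Cleavage motifs and the MPP → ICP55 model

Motif classes are position-class patterns with one scissile-bond marker,
shipped as a plain data file (`leamts/data/motifs.tsv`) so users can add
motifs. The executable hydrophobic class Φ = {A, V, L, I, M, F, W, Y, C}
and hydrophilic Ψ = its complement make the MPP core pattern
{(R/K)-Xn-R-X↓Φ-Ψ-Ψ} concrete; the variable gap is bounded at n ≤ 10 to
keep matching finite. The MPP core is annotation only — it corroborates
a site found by a named motif class but never creates one. The -10R
motif is bundled but excluded from plant-mode scanning (it has not been
observed in plant presequences).

`cleave_after` is the 1-based position of the last presequence residue;
re-slicing at any reported site reconstructs presequence + mature with
no gap or overlap (a tested invariant, alongside equivalence with an
independent regex matcher on 1000 random sequences).

The two-site model: MPP cuts first; when the residue immediately after
the MPP site is Ala or Ser, the ICP55 step removes exactly one residue,
producing a second site one position downstream. The trim set {A, S} is
configurable; the {A, S} default generalizes the observation that two
successive small residues after the bond relax ICP55's specificity,
releasing two mature N-termini. Whether two adjacent experimental sites
arise as MPP-then-ICP55 or as two MPP events is not observable here; the
MPP→ICP55 interpretation is a model assumption of this package. Trimming
applies once by contract — an ICP55 site cannot be trimmed again.

`best_cleavage` ranks motifs by specificity (minus3R_plant >
minus3R_general > minus10R > minus2R > noR_plant), breaking ties by the
smallest cleavage position, and returns the primary site plus its
optional trim.

### The targeting rule

| condition | default | rationale |
|---|---|---|
| C1 face size | ≥ 5 | five nonpolar residues on contiguous slots; four is not enough |
| C2 positives | exactly 2 K/R, both opposite-pole, one pair at sequence separation 4 | separation 4 = three intervening residues = 40° wheel adjacency |
| C3 negative | exactly 1 D/E at the interface | the single Glu must border the hydrophobic face |
| C4 downstream | a -3R motif fires in 1..60 **and** ≥ 3 Ser in the 11 residues after the last site | the helix is essential but not sufficient; plant presequences are Ser-enriched just downstream of cleavage |

Decisions worth stating:

* "Separated by three residues" is read as sequence separation 4 (three
  residues in between), which the wheel maps to 40°; the separation is a
  config field.
* Whether C2 means *exactly* two or *at least* two positives is
  genuinely open; the default is "exactly" (matching the modeled
  window's composition) and the count is configurable.
* C4 fuses two observations — a firing cleavage motif and a Ser-rich
  downstream segment — into one condition, because deleting the
  downstream segment abolishes targeting even when the helix is intact.
  The Ser threshold 3 on an 11-residue window lets the modeled segment
  AQGSVSSGGRS (4 Ser) pass and KTALD-context windows (0 Ser) fail with
  one residue of slack.
* C4's evidence motifs default to the two -3R classes. The -2R and no-R
  classes stay out of the default evidence set: they are weak patterns
  that fire on almost any Arg- or aromatic-containing region, and the
  cleavage analysis this rule encodes is anchored on the -3R consensus.
  The set is a config field.
* The verdict is binary (all enabled conditions AND-ed), matching
  all-or-none protoplast localizations. Partial-penetrance outcomes —
  the triple mutant reaches mitochondria in only about half of
  transformed protoplasts — are outside the model: the rule says
  "import-competent", not "always imported".
* Scan region 1–60 covers observed plant MTS lengths (19–109 reported
  across species, 28–43 predicted for this pair) without scanning deep
  into mature regions.

### Consensus and logo statistics

Information content per column is log₂20 − H against a uniform
background (the standard logo convention; no compositional background in
v1), with the optional small-sample correction (20−1)/(2·ln2·n) floored
at zero. Gap characters are excluded from frequencies with per-column
coverage reported. Consensus extraction adds residues per column in
descending frequency (alphabetic tie-break) until the cumulative
frequency reaches the threshold; 1 residue → fixed, 2–3 → alternative
set, more → wildcard. The cap of 3 alternatives reproduces the shape of
printed family consensi (at most 2 alternatives per column). The default
inclusion threshold 0.9 is a package choice — no threshold is published
for the printed consensus.

## The synthetic-data generator

No full-length sequences of the real paralog pair are printed in the
source material, so the package carries two engineered stand-ins
(`lea2_like`, 91 aa; `lea38_like`, 97 aa). Every printed fragment sits
at its printed coordinate — KTALD at 33–37, AQGSVSSGGRS at 33–43,
FRRGYAATA at 24–32, RRGFAAAAKT at 25–34, Gln11, E17-K18 — and the helix
windows (5–22 and 7–24) were laid out on the wheel so that the described
geometry emerges exactly: the cytosolic base shows a four-residue AGAL
face with the Glu at the opposite pole, the Q11V substitution extends it
to VAGAL, the EK→KE inversion moves the charges into the
interface/opposite-pole arrangement, and the mitochondrial base shows
the five-residue VAVVL face. The shared mature-region scaffold begins
with eight Ser-free residues so deletion constructs lose the Ser-rich
downstream window cleanly.

`generate_positive` constructs an 18-residue window by direct placement:
nonpolar letters on the first `face_size` slots (0°, 20°, …), the Glu
one slot past the face end, the K/R pair on the first sequence-adjacent
slot pair (separation 4) that is opposite-pole *and* more than one slot
from both face ends (so a face-size change of one cannot silently re-zone
them), polar filler elsewhere. Feasible face sizes are 1–9; beyond 9 the
face would collide with the slot reserved for the cleavage-context
overlap. Filler pools are deliberately restricted: in-window filler
{T, N, Q} contains no Ser (a Ser beside an in-window Arg could spawn a
spurious -3R match upstream of the designed context), no Gly/Ala (would
extend the face), no Pro (helix-breaking); out-of-window filler
{T, N, Q, G} contains no Arg/aromatics (motif-inert) and no Ser, so
condition C4 is controlled solely by the designed context and segment
and generated labels are deterministic functions of the configuration.

Each decoy applies exactly one condition-breaking edit to a positive:
`face_shrink` removes the last face residue (C1), `charge_swap` moves
one positive charge to an interface slot (C2), `negative_move` sends the
Glu to the opposite pole (C3), `segment_delete` removes the downstream
segment (C4), `motif_kill` mutates the -3R anchor arginine to Gly (C4,
emptying the scan). Labels are rule-defined: "mitochondrial" means
"satisfies the default rule", and passing tests certify the machinery,
not biological import. Real presequences vary helix position and length,
carry compositional biases the neutral filler lacks, and blur every
threshold the rule makes sharp — results on generated data bound what
the implementation does, not how the rule generalizes.

`generate_family` samples aligned 40-residue blocks column-wise: each
column emits its planted content with probability `conservation`
(default 0.95) or a uniform draw over the remaining residues. The
planted consensus R-R-G-(Y/F)-A-A-(A/T)-(A/S) occupies columns 25–32;
two-residue columns split their planted mass 55/45 so extraction sees a
dominant-plus-minor pair. Background columns take their dominant residue
from the mitochondrial stand-in's N-terminus.

The consensus-recovery experiment extracts at threshold 0.85 rather than
the 0.9 default: with n = 100 and conservation 0.95, the planted mass of
a column is Binomial(100, 0.95)/100, whose lower tail crosses 0.9 with
probability ≈ 1% per column — a threshold inside the sampling noise
would measure binomial fluctuation, not recovery. 0.85 sits more than
four standard errors below the planted mass. Recovered alternative sets
are compared as unordered residue sets; the display order of
alternatives (by sampled frequency) is not part of the pattern identity.

## Numerical and engineering choices

* 1-based inclusive coordinates everywhere ("residues 33 to 37" = five
  residues); conversion happens only at I/O boundaries.
* Average (not monoisotopic) residue masses, via Biopython.
* Ambiguity codes (B, Z, X, U, …) and gaps are rejected at record
  construction, not translated.
* Mutation specs carry the expected original segment when one is known
  (KTALD, AQGSVSSGGRS, Q at 11, EK at 17–18) and verification is
  mandatory — a mismatch is a "construct/sequence disagreement" error.
* Moment direction is undefined below magnitude 1e-9 (homopolymer
  windows cancel exactly by symmetry; floating point leaves ~1e-16).
* The analysis path is seed-free and deterministic; all randomness lives
  in the generator behind a single integer seed.
* Hydrophobicity scales (Fauchère–Pliska default, Kyte–Doolittle,
  Eisenberg) live in `leamts/data/scales.tsv` and are selected by id.

## Problem sizes

The bundled suites run at desk scale: oracle-equivalence checks use 1000
random windows/sequences, label soundness 500 seeded draws, ablation
audits 200 seeded cases (5 ablations × 40 seeds), consensus recovery 20
seeds × 100 sequences × 40 columns. The whole test suite and the
acceptance script each complete in a few seconds on one CPU.

## Known limitations

* Helix windows are inputs (annotations), not predictions; no secondary
  structure prediction is performed.
* The classifier is a hard rule, not a scorer: no probabilities, no
  training, and no chloroplast/secretory discrimination.
* The stand-in bases are synthetic; conclusions about the real paralog
  pair require the real sequences, which users can supply to
  `build_construct_series` and `classify_panel` unchanged.
* Consensus extraction assumes essentially ungapped N-terminal blocks;
  heavily gapped alignments will report low coverage rather than a
  meaningful consensus.
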