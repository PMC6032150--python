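"""Seeded generator of rule-labeled LEA_3-like sequences, single-condition
decoys, and conserved N-terminal families.

Labels are defined by the targeting rule, not by biology: a record is
labeled "mitochondrial" exactly when it satisfies the default
:class:`~leamts.rules.RuleConfig`, so generated labels certify the rule
machinery, never real import outcomes.

The module also provides the two synthetic base proteins used by the
construct panel.  The paper-printed segments of the real paralog pair
(KTALD at 33..37, AQGSVSSGGRS at 33..43, the cleavage contexts FRRGYAATA
at 24..32 and RRGFAAAAKT at 25..34, Gln11, the E17-K18 pair) are placed at
their printed coordinates inside otherwise invented carrier sequences; the
full real sequences are not published in the source material, so these
bases are synthetic stand-ins, engineered so that the first-helix wheel
shows the described four-residue (AGAL) vs five-residue (VAVVL/VAGAL)
hydrophobic faces and charge dispositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import ProteinRecord, SequenceError
from .rules import RuleConfig, classify
from .wheel import (
    ANGLE_STEP,
    INTERFACE_TOL,
    OPPOSITE_POLE_MIN,
    HelixWindow,
    circular_distance,
)

ABLATIONS = ("none", "face_shrink", "charge_swap", "negative_move",
             "segment_delete", "motif_kill")

#: Shared mature-region scaffold (54 residues, Ser-free start so deletion
#: constructs lose the Ser-rich downstream segment cleanly).
_MATURE38 = "GKDAEKAQTVEKAGEYGKQAMEKTGEHAKDAGQKLTESKGNAVEHAKDTAGRKA"
#: The cytosolic paralog's mature region: same scaffold with a few
#: divergent positions (paralogs, not identical twins).
_MATURE2 = "GKDTEKAQTVEKQGEYGKQAMEKTGEHAKDTGQNLTESKGNAVEHAKDTAGRKA"

#: Synthetic cytosolic base, 91 aa.  First helix annotated 5..23 (window
#: 5..22).  The wheel of that window shows a four-residue AGAL face with
#: Glu17 at the pole opposite the face and Lys18/Lys21 mislocated — the
#: configuration the rule rejects.
_LEA2_SEQ = (
    "MAST"  # 1-4
    "TSNAQSQTNSGQEKLTKA"  # 5-22: helix window
    "SQ"  # 23-24
    "RRGFAAAAKT"  # 25-34: -3R cleavage context (K33 T34 begin KTALD)
    "ALD"  # 35-37: KTALD tail
    + _MATURE2  # 38-91
)

#: Synthetic mitochondrial base, 97 aa.  First helix annotated 7..24
#: (window 7..24): VAVVL face on slots 0..80 deg, Lys13/Arg17 at the
#: opposite pole four residues apart, Glu19 one slot past the face end.
_LEA38_SEQ = (
    "MASNTQ"  # 1-6
    "VSTNVQKSLTRAENQVSF"  # 7-24: helix window (F24 opens the context)
    "RRGYAATA"  # 25-32: rest of FRRGYAATA
    "AQGSVSSGGRS"  # 33-43: Ser-rich downstream segment
    + _MATURE38  # 44-97
)


def lea2_like() -> ProteinRecord:
    """Synthetic stand-in for the cytosolic paralog (91 aa)."""
    return ProteinRecord(id="LEA2", seq=_LEA2_SEQ,
                         description="synthetic cytosolic-paralog stand-in")


def lea38_like() -> ProteinRecord:
    """Synthetic stand-in for the mitochondrial paralog (97 aa)."""
    return ProteinRecord(id="LEA38", seq=_LEA38_SEQ,
                         description="synthetic mitochondrial-paralog stand-in")


class InfeasiblePlacement(ValueError):
    """Raised when the requested wheel placements cannot coexist."""


#: Planted family consensus: pattern columns and their 1-based offset.
PLANTED_CONSENSUS: tuple[tuple[str, ...], ...] = (
    ("R",), ("R",), ("G",), ("Y", "F"), ("A",), ("A",), ("A", "T"), ("A", "S"),
)
PLANTED_OFFSET = 25


def consensus_matches_planted(columns: Sequence[tuple[str, ...]],
                              planted: Sequence[tuple[str, ...]] = PLANTED_CONSENSUS,
                              offset: int = PLANTED_OFFSET) -> bool:
    """Whether extracted consensus columns recover the planted pattern.

    Column alternatives are unordered residue sets; extraction orders them
    by sampled frequency, which is not part of the pattern identity.
    """
    got = columns[offset - 1 : offset - 1 + len(planted)]
    if len(got) != len(planted):
        return False
    return all(frozenset(g) == frozenset(p) for g, p in zip(got, planted))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the generator.

    Defaults mirror the modeled protein: 97 residues total, an 18-residue
    first-helix window starting at 7, a five-residue hydrophobic face,
    the FRRGYAATA cleavage context at 24 and the AQGSVSSGGRS segment at
    33.  ``seed`` is mandatory: all draws flow from it.
    """

    seed: int
    n_sequences: int = 1
    length: int = 97
    helix_start: int = 7
    face_size: int = 5
    cleavage_context: str = "FRRGYAATA"
    context_start: int = 24
    downstream_segment: str = "AQGSVSSGGRS"
    segment_start: int = 33
    ablation: str = "none"
    # family mode
    family_length: int = 40
    conservation: float = 0.95
    planted_consensus: tuple[tuple[str, ...], ...] = PLANTED_CONSENSUS
    planted_offset: int = PLANTED_OFFSET

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; one of {ABLATIONS}")
        if not 1 <= self.face_size <= 9:
            raise InfeasiblePlacement(
                f"face_size {self.face_size} outside the feasible range 1..9 "
                "(larger faces collide with the cleavage-context overlap slot)"
            )
        ctx_end = self.context_start + len(self.cleavage_context) - 1
        seg_end = self.segment_start + len(self.downstream_segment) - 1
        if max(ctx_end, seg_end, self.helix_start + 17) > self.length:
            raise InfeasiblePlacement("placements exceed the sequence length")


@dataclass(frozen=True)
class LabeledRecord:
    """A generated record with its rule-defined ground-truth label."""

    record: ProteinRecord
    label: str  # "mitochondrial" | "cytosolic"
    ablation: Optional[str] = None


# wheel bookkeeping for the 18-residue window ---------------------------------

_K_OF_ANGLE = {int((k * ANGLE_STEP) % 360): k for k in range(18)}

# nonpolar letters assigned to face slots 0, 20, 40, ... in order; the
# first five spell the modeled VAVVL face
_FACE_LETTERS = "VAVVLAVLI"
# in-window polar filler: no Ser (a Ser next to an in-window Arg could
# spawn a spurious -3R match upstream of the designed context), no
# Gly/Ala (would extend the face), no Pro (helix-breaking)
_WINDOW_FILLER = "TNQ"
# out-of-window filler: hydrophilic, motif-inert (no R/F/Y/L) and
# Ser-free, so the Ser-rich downstream condition is controlled solely by
# the designed segment and decoy labels stay deterministic
_FLANK_FILLER = "TNQG"


def _design_window(face_size: int, reserved_k: set[int], rng: np.random.Generator
                   ) -> tuple[list[str], dict[str, list[int]]]:
    """Place face, charges, and filler on the 18 wheel slots.

    Returns the 18 window residues plus the k-indices of the structural
    elements.  Raises :class:`InfeasiblePlacement` when no arrangement
    satisfies the zone constraints.
    """
    face_angles = [20 * i for i in range(face_size)]
    face_ks = [_K_OF_ANGLE[a] for a in face_angles]
    if any(k in reserved_k for k in face_ks):
        raise InfeasiblePlacement("face collides with a reserved slot")
    center = 10.0 * (face_size - 1)
    ends = (face_angles[0], face_angles[-1])

    neg_angle = 20 * face_size  # one slot past the face end: interface
    neg_k = _K_OF_ANGLE[neg_angle % 360]
    if neg_k in face_ks or neg_k in reserved_k:
        raise InfeasiblePlacement("interface slot for the negative charge unavailable")

    used = set(face_ks) | {neg_k} | reserved_k

    def opposite_pole(angle: float) -> bool:
        return (
            circular_distance(angle, center) > OPPOSITE_POLE_MIN
            and all(circular_distance(angle, e) > INTERFACE_TOL for e in ends)
        )

    pos_pair = None
    for k in range(14):  # k and k+4 both inside the window
        ka, kb = k, k + 4
        if ka in used or kb in used:
            continue
        aa_angle = (ka * ANGLE_STEP) % 360
        bb_angle = (kb * ANGLE_STEP) % 360
        if opposite_pole(aa_angle) and opposite_pole(bb_angle):
            pos_pair = (ka, kb)
            break
    if pos_pair is None:
        raise InfeasiblePlacement(
            f"no opposite-pole slot pair at sequence separation 4 for face size {face_size}"
        )
    used |= set(pos_pair)

    window = [""] * 18
    for i, k in enumerate(face_ks):
        window[k] = _FACE_LETTERS[i]
    window[neg_k] = "E"
    window[pos_pair[0]] = "K"
    window[pos_pair[1]] = "R"
    for k in range(18):
        if not window[k] and k not in reserved_k:
            window[k] = _WINDOW_FILLER[rng.integers(0, len(_WINDOW_FILLER))]
    placements = {
        "face": face_ks,
        "negative": [neg_k],
        "positives": list(pos_pair),
        "center": [int(center)],
    }
    return window, placements


def _assemble(cfg: GeneratorConfig, rng: np.random.Generator,
              face_size: Optional[int] = None) -> tuple[list[str], dict[str, list[int]]]:
    n = cfg.length
    seq = [
        _FLANK_FILLER[rng.integers(0, len(_FLANK_FILLER))] for _ in range(n)
    ]
    seq[0] = "M"
    w0 = cfg.helix_start - 1  # 0-based window start
    ctx0 = cfg.context_start - 1
    reserved = {p - w0 for p in range(ctx0, ctx0 + len(cfg.cleavage_context))
                if w0 <= p < w0 + 18}
    window, placements = _design_window(
        cfg.face_size if face_size is None else face_size, reserved, rng
    )
    for k in range(18):
        if window[k]:
            seq[w0 + k] = window[k]
    for i, aa in enumerate(cfg.cleavage_context):
        seq[ctx0 + i] = aa
    for i, aa in enumerate(cfg.downstream_segment):
        seq[cfg.segment_start - 1 + i] = aa
    return seq, placements


def generate_positive(cfg: GeneratorConfig) -> LabeledRecord:
    """A sequence built to satisfy every rule condition.

    The record is verified through the classifier; a failure to classify
    as mitochondrial is an infeasible-placement error, not a label.
    """
    rng = np.random.default_rng(cfg.seed)
    seq, _ = _assemble(cfg, rng)
    rec = ProteinRecord(
        id=f"synt_pos_{cfg.seed}", seq="".join(seq),
        description="generated rule-positive sequence",
    )
    window = HelixWindow(rec, cfg.helix_start, cfg.helix_start + 17)
    call = classify(rec, window)
    if cfg.face_size >= 5:
        if call.verdict != "mitochondrial":
            raise InfeasiblePlacement(
                f"generated sequence fails conditions {call.conditions}"
            )
        return LabeledRecord(record=rec, label="mitochondrial", ablation=None)
    # sub-threshold face sizes are rule-negative by construction
    return LabeledRecord(record=rec, label="cytosolic", ablation="face_shrink")


def generate_decoy(cfg: GeneratorConfig, ablation: Optional[str] = None) -> LabeledRecord:
    """Start from a positive and break exactly one condition.

    Ablations: ``face_shrink`` (remove the last face residue, C1),
    ``charge_swap`` (move one positive charge off the opposite pole, C2),
    ``negative_move`` (move the Glu off the interface, C3),
    ``segment_delete`` (drop the Ser-rich downstream segment, C4),
    ``motif_kill`` (point-mutate the -3R anchor arginine, C4).
    """
    ablation = ablation or cfg.ablation
    if ablation not in ABLATIONS or ablation == "none":
        raise ValueError(f"unknown or empty ablation {ablation!r}")
    rng = np.random.default_rng(cfg.seed)
    seq, placements = _assemble(cfg, rng)
    w0 = cfg.helix_start - 1

    if ablation == "face_shrink":
        # drop the face member at the largest slot angle; the Glu one slot
        # further out stays within interface tolerance of the new end
        k_last = placements["face"][-1]
        seq[w0 + k_last] = "T"
    elif ablation == "charge_swap":
        # move the first positive to the slot just past the Glu: still in
        # the window but 40 deg from the face end, i.e. interface not pole
        k_from = placements["positives"][0]
        target_angle = (20 * (len(placements["face"]) + 1)) % 360
        k_to = _K_OF_ANGLE[target_angle]
        seq[w0 + k_to] = seq[w0 + k_from]
        seq[w0 + k_from] = "T"
    elif ablation == "negative_move":
        k_from = placements["negative"][0]
        center = placements["center"][0]
        ends = (0, 20 * (len(placements["face"]) - 1))
        k_to = None
        taken = set(placements["face"]) | set(placements["positives"]) | {17}
        for k in range(18):
            ang = (k * ANGLE_STEP) % 360
            if (
                k not in taken
                and k != k_from
                and circular_distance(ang, center) > OPPOSITE_POLE_MIN
                and all(circular_distance(ang, e) > INTERFACE_TOL for e in ends)
            ):
                k_to = k
                break
        if k_to is None:  # pragma: no cover - feasible for all face sizes
            raise InfeasiblePlacement("no opposite-pole slot for the moved Glu")
        seq[w0 + k_to] = "E"
        seq[w0 + k_from] = "T"
    elif ablation == "segment_delete":
        s0 = cfg.segment_start - 1
        del seq[s0 : s0 + len(cfg.downstream_segment)]
    elif ablation == "motif_kill":
        # the -3R anchor is the Arg three residues before the scissile
        # bond, i.e. context position 3 of FRRGYAATA (protein 26)
        anchor = cfg.context_start - 1 + 2
        if seq[anchor] != "R":
            raise InfeasiblePlacement("cleavage context has no -3R anchor arginine")
        seq[anchor] = "G"

    rec = ProteinRecord(
        id=f"synt_{ablation}_{cfg.seed}", seq="".join(seq),
        description=f"generated decoy ({ablation})",
    )
    return LabeledRecord(record=rec, label="cytosolic", ablation=ablation)


def generate_family(cfg: GeneratorConfig,
                    dominants: Optional[str] = None) -> list[LabeledRecord]:
    """Sample an aligned family of N-terminal blocks column-wise.

    Each column emits its planted content with probability
    ``cfg.conservation`` and a uniform draw over the remaining residues
    otherwise.  Planted-consensus columns (default R-R-G-(Y/F)-A-A-(A/T)-
    (A/S) at 25..32) override the background dominants; two-residue
    columns split their planted mass 55/45.  The background dominants
    default to the mitochondrial stand-in's first ``family_length``
    residues.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.family_length
    dom = (dominants or lea38_like().seq)[:L]
    if len(dom) < L:
        raise SequenceError(f"dominant profile shorter than {L} columns")
    alphabet = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))

    planted: dict[int, tuple[str, ...]] = {}
    for i, col in enumerate(cfg.planted_consensus):
        pos = cfg.planted_offset + i
        if pos <= L:
            planted[pos] = col

    columns: list[np.ndarray] = []
    for pos in range(1, L + 1):
        content = planted.get(pos, (dom[pos - 1],))
        others = np.array([aa for aa in alphabet if aa not in content])
        p = cfg.conservation
        if len(content) == 1:
            choices = np.concatenate(([content[0]], others))
            probs = np.concatenate(([p], np.full(len(others), (1 - p) / len(others))))
        else:
            choices = np.concatenate((list(content), others))
            probs = np.concatenate(
                ([0.55 * p, 0.45 * p], np.full(len(others), (1 - p) / len(others)))
            )
        columns.append(rng.choice(choices, size=cfg.n_sequences, p=probs))

    out = []
    for j in range(cfg.n_sequences):
        seq = "".join(columns[i][j] for i in range(L))
        rec = ProteinRecord(
            id=f"fam_{cfg.seed}_{j}", seq=seq,
            description="generated family N-terminal block",
        )
        out.append(LabeledRecord(record=rec, label="mitochondrial", ablation=None))
    return out


def echo_config(cfg: GeneratorConfig) -> dict:
    """The exact generator configuration as a plain dict (provenance)."""
    return {
        "seed": cfg.seed,
        "n_sequences": cfg.n_sequences,
        "length": cfg.length,
        "helix_start": cfg.helix_start,
        "face_size": cfg.face_size,
        "cleavage_context": cfg.cleavage_context,
        "context_start": cfg.context_start,
        "downstream_segment": cfg.downstream_segment,
        "segment_start": cfg.segment_start,
        "ablation": cfg.ablation,
        "family_length": cfg.family_length,
        "conservation": cfg.conservation,
        "planted_offset": cfg.planted_offset,
        "planted_consensus": ["/".join(c) for c in cfg.planted_consensus],
    }
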