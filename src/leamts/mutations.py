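"""Mutation-construct algebra: deletions, replacements, substitutions,
adjacent-pair charge inversions, and the nine-member GFP construct panel.

Every spec may declare the original segment expected at its range
(e.g. KTALD at 33..37); when declared, the base sequence is checked and a
mismatch raises ``construct/sequence disagreement`` rather than silently
mutating the wrong residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Literal, Optional, Sequence

from .records import ProteinRecord, SequenceError

MutationKind = Literal["delete_segment", "replace_segment", "substitute", "invert_pair"]

#: Empirical subcellular localizations of the construct panel
#: (protoplast GFP-fusion outcomes): only the wild-type mitochondrial
#: protein, the 43-residue N-terminal chimera, and the triple mutant
#: reach mitochondria.
PANEL_LABELS: dict[str, str] = {
    "LEA2": "cytosolic",
    "LEA38": "mitochondrial",
    "LEA2del": "cytosolic",
    "LEA38del": "cytosolic",
    "LEA2.1": "mitochondrial",
    "LEA2.2": "cytosolic",
    "LEA2.3": "cytosolic",
    "LEA2.4": "cytosolic",
    "LEA2.5": "mitochondrial",
}


@dataclass(frozen=True)
class MutationSpec:
    """One edit, in 1-based inclusive coordinates of the sequence it is
    applied to.

    ``expected`` optionally declares the original text at ``start..end``;
    when present it is verified before editing.
    """

    kind: MutationKind
    start: int
    end: int
    payload: str = ""
    expected: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SequenceError(
                f"spec {self.label!r}: bad range {self.start}..{self.end}"
            )
        if self.kind == "substitute":
            if self.start != self.end:
                raise SequenceError(
                    f"spec {self.label!r}: substitute range must be one position"
                )
            if len(self.payload) != 1:
                raise SequenceError(
                    f"spec {self.label!r}: substitute payload must be one residue"
                )
        if self.kind == "invert_pair" and self.end != self.start + 1:
            raise SequenceError(
                f"spec {self.label!r}: invert_pair must span exactly two adjacent positions"
            )
        if self.kind == "delete_segment" and self.payload:
            raise SequenceError(f"spec {self.label!r}: delete_segment takes no payload")

    @property
    def net_length_change(self) -> int:
        span = self.end - self.start + 1
        if self.kind == "delete_segment":
            return -span
        if self.kind == "replace_segment":
            return len(self.payload) - span
        return 0


def apply_mutation(rec: ProteinRecord, spec: MutationSpec) -> ProteinRecord:
    """Apply one :class:`MutationSpec`, returning a new record.

    The original record is untouched.  Length changes by
    ``len(payload) - (end - start + 1)`` for replacements, by the negated
    span for deletions, and not at all for substitutions/inversions.
    """
    if spec.end > len(rec):
        raise SequenceError(
            f"spec {spec.label!r}: range {spec.start}..{spec.end} outside "
            f"1..{len(rec)} of record {rec.id!r}"
        )
    original = rec.segment(spec.start, spec.end)
    if spec.expected and original != spec.expected:
        raise SequenceError(
            f"construct/sequence disagreement: spec {spec.label!r} expected "
            f"{spec.expected!r} at {spec.start}..{spec.end} of {rec.id!r}, "
            f"found {original!r}"
        )
    head = rec.seq[: spec.start - 1]
    tail = rec.seq[spec.end :]
    if spec.kind == "delete_segment":
        new = head + tail
    elif spec.kind == "replace_segment":
        new = head + spec.payload.upper() + tail
    elif spec.kind == "substitute":
        new = head + spec.payload.upper() + tail
    elif spec.kind == "invert_pair":
        new = head + original[1] + original[0] + tail
    else:  # pragma: no cover - kinds are closed
        raise SequenceError(f"unknown mutation kind {spec.kind!r}")
    new_id = spec.label or f"{rec.id}_mut"
    return ProteinRecord(id=new_id, seq=new, description=rec.description)


def apply_mutations(rec: ProteinRecord, specs: Sequence[MutationSpec],
                    label: str = "") -> ProteinRecord:
    """Apply an ordered list of specs; coordinates refer to the running
    (already-edited) sequence, matching how construct tables are read."""
    out = rec
    for spec in specs:
        out = apply_mutation(out, spec)
    if label:
        out = ProteinRecord(id=label, seq=out.seq, description=rec.description)
    return out


def shift_window(window: tuple[int, int],
                 specs: Sequence[MutationSpec]) -> Optional[tuple[int, int]]:
    """Map a 1-based inclusive helix window through a list of edits.

    Indels entirely downstream leave the window untouched; indels entirely
    upstream shift it by the net length change; an indel overlapping the
    window invalidates it (returns None).  Substitutions and pair
    inversions never move the window.
    """
    ws, we = window
    for spec in specs:
        d = spec.net_length_change
        if d == 0:
            continue
        if spec.end < ws:
            ws, we = ws + d, we + d
        elif spec.start > we:
            continue
        else:
            return None
    return (ws, we)


@dataclass(frozen=True)
class Construct:
    """One panel member: product record, empirical label, helix window."""

    record: ProteinRecord
    expected_location: str
    helix_window: Optional[tuple[int, int]]
    specs: tuple[MutationSpec, ...] = ()


@dataclass(frozen=True)
class ConstructSeries:
    """The nine-member construct panel derived from two base proteins."""

    base2: ProteinRecord
    base38: ProteinRecord
    constructs: tuple[Construct, ...]

    def __iter__(self):
        return iter(self.constructs)

    def __len__(self) -> int:
        return len(self.constructs)

    def get(self, label: str) -> Construct:
        for c in self.constructs:
            if c.record.id == label:
                return c
        raise KeyError(label)


def build_construct_series(
    base2: ProteinRecord,
    base38: ProteinRecord,
    window2: tuple[int, int] = (5, 22),
    window38: tuple[int, int] = (7, 24),
) -> ConstructSeries:
    """Build the nine-construct panel from the two base proteins.

    ``base2`` plays the cytosolic paralog (91 aa in the wild type, KTALD at
    33..37, Gln at 11, E17-K18); ``base38`` the mitochondrial one (97 aa,
    AQGSVSSGGRS at 33..43).  The panel:

    ==========  ===========================================================
    LEA2        base2 unchanged
    LEA38       base38 unchanged
    LEA2del     base2 without residues 33..37 (KTALD)
    LEA38del    base38 without residues 33..43 (AQGSVSSGGRS)
    LEA2.1      base38 residues 1..43 + base2 residues 38..91
    LEA2.2      base2 with KTALD replaced by AQGSVSSGGRS
    LEA2.3      LEA2.2 with Q11V
    LEA2.4      LEA2.2 with inversion at 17 and 18 (EK into KE)
    LEA2.5      LEA2.2 with Q11V and the 17/18 inversion
    ==========  ===========================================================

    Each product carries its empirical cytosolic/mitochondrial label and a
    helix window inherited from its base annotation (shifted through any
    upstream indel).
    """
    if len(base2) < 91:
        raise SequenceError(f"base2 must span at least 91 residues, got {len(base2)}")
    if len(base38) < 43:
        raise SequenceError(f"base38 must span at least 43 residues, got {len(base38)}")

    seg11 = "AQGSVSSGGRS"
    del2 = MutationSpec("delete_segment", 33, 37, expected="KTALD", label="LEA2del")
    del38 = MutationSpec("delete_segment", 33, 43, expected=seg11, label="LEA38del")
    rep22 = MutationSpec("replace_segment", 33, 37, payload=seg11,
                         expected="KTALD", label="LEA2.2")
    q11v = MutationSpec("substitute", 11, 11, payload="V", expected="Q", label="Q11V")
    ek_inv = MutationSpec("invert_pair", 17, 18, expected="EK", label="EK17KE")
    chim = MutationSpec(
        "replace_segment", 1, 37, payload=base38.segment(1, 43), label="LEA2.1"
    )

    recipes: list[tuple[str, ProteinRecord, tuple[MutationSpec, ...], tuple[int, int]]] = [
        ("LEA2", base2, (), window2),
        ("LEA38", base38, (), window38),
        ("LEA2del", base2, (del2,), window2),
        ("LEA38del", base38, (del38,), window38),
        # the chimera carries base38's N-terminus, so it inherits base38's
        # helix annotation rather than a shifted base2 window
        ("LEA2.1", base2, (chim,), window38),
        ("LEA2.2", base2, (rep22,), window2),
        ("LEA2.3", base2, (rep22, q11v), window2),
        ("LEA2.4", base2, (rep22, ek_inv), window2),
        ("LEA2.5", base2, (rep22, q11v, ek_inv), window2),
    ]

    constructs = []
    for label, base, specs, window in recipes:
        product = apply_mutations(base, specs, label=label) if specs else ProteinRecord(
            id=label, seq=base.seq, description=base.description
        )
        win = window if label == "LEA2.1" else shift_window(window, specs)
        constructs.append(
            Construct(
                record=product,
                expected_location=PANEL_LABELS[label],
                helix_window=win,
                specs=specs,
            )
        )
    return ConstructSeries(base2=base2, base38=base38, constructs=tuple(constructs))
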