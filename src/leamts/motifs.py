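"""Presequence cleavage-motif scanning and the MPP -> ICP55 two-step
cleavage model.

A matched motif is reported as the 1-based protein position *after which*
cleavage occurs (``cleave_after``): the residue at that position is the
last residue of the presequence, so slicing at the site reconstructs
presequence and mature protein with no gap or overlap.  ICP55 removes a
single N-terminal residue from the MPP product, yielding a second site at
``cleave_after + 1`` whenever the removed residue is in the trim set
(default {A, S} — two successive small residues after the bond relax the
peptidase's specificity, producing two adjacent mature N-termini).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

from .records import ProteinRecord, SequenceError, STANDARD_AA

PHI = frozenset("AVLIMFWYC")  # hydrophobic class
PSI = STANDARD_AA - PHI  # hydrophilic class
DEFAULT_TRIM_SET = frozenset("AS")
DEFAULT_SCAN_REGION = (1, 60)
#: Specificity order used to rank co-occurring motifs (most specific first).
PRIORITY_ORDER = ("minus3R_plant", "minus3R_general", "minus10R", "minus2R", "noR_plant")

_GAP_RE = re.compile(r"^X\{(\d+)\.\.(\d+)\}$")


@dataclass(frozen=True)
class _Token:
    """One pattern position: a residue-class set, or a variable gap."""

    classes: Optional[frozenset[str]]  # None for a gap token
    gap: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class MotifDefinition:
    id: str
    tokens: tuple[_Token, ...]
    scissile_index: int  # tokens before the bond
    plant: bool
    priority: int
    description: str

    @property
    def min_presequence_span(self) -> int:
        return sum(
            1 if t.gap is None else t.gap[0] for t in self.tokens[: self.scissile_index]
        )


def _parse_pattern(pattern: str) -> tuple[tuple[_Token, ...], int]:
    tokens: list[_Token] = []
    scissile = None
    for raw in pattern.split(","):
        raw = raw.strip()
        if raw == "|":
            if scissile is not None:
                raise SequenceError(f"pattern {pattern!r}: two scissile-bond markers")
            scissile = len(tokens)
            continue
        m = _GAP_RE.match(raw)
        if m:
            tokens.append(_Token(classes=None, gap=(int(m.group(1)), int(m.group(2)))))
            continue
        if raw == "X":
            tokens.append(_Token(classes=STANDARD_AA))
        elif raw == "PHI":
            tokens.append(_Token(classes=PHI))
        elif raw == "PSI":
            tokens.append(_Token(classes=PSI))
        else:
            bad = set(raw) - STANDARD_AA
            if bad:
                raise SequenceError(f"pattern {pattern!r}: unknown residues {bad}")
            tokens.append(_Token(classes=frozenset(raw)))
    if scissile is None:
        raise SequenceError(f"pattern {pattern!r}: missing scissile-bond marker")
    return tuple(tokens), scissile


def _load_motifs() -> dict[str, MotifDefinition]:
    text = resources.files("leamts.data").joinpath("motifs.tsv").read_text()
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    motifs = {}
    for row in reader:
        tokens, scissile = _parse_pattern(row["pattern"])
        motifs[row["id"]] = MotifDefinition(
            id=row["id"],
            tokens=tokens,
            scissile_index=scissile,
            plant=row["plant"] == "yes",
            priority=int(row["priority"]),
            description=row["description"],
        )
    return motifs


MOTIFS: dict[str, MotifDefinition] = _load_motifs()


@dataclass(frozen=True)
class CleavageSite:
    """A cleavage event after protein position ``cleave_after``."""

    motif_id: str
    cleave_after: int
    span: tuple[int, int]  # 1-based inclusive matched span
    source: str  # "MPP" or "ICP55"
    mpp_core_support: bool = False

    def presequence(self, rec: ProteinRecord) -> str:
        return rec.segment(1, self.cleave_after)

    def mature(self, rec: ProteinRecord) -> str:
        return rec.segment(self.cleave_after + 1, len(rec))


def _match_at(seq: str, motif: MotifDefinition, start0: int) -> Iterable[tuple[int, int]]:
    """Yield (match_length, presequence_offset) for every way the motif
    matches ``seq`` starting at 0-based ``start0``."""

    def rec_match(ti: int, pos: int, pre_len: int) -> Iterable[tuple[int, int]]:
        if ti == len(motif.tokens):
            yield pos - start0, pre_len
            return
        tok = motif.tokens[ti]
        before_bond = ti < motif.scissile_index
        if tok.gap is not None:
            lo, hi = tok.gap
            for g in range(lo, hi + 1):
                if pos + g > len(seq):
                    break
                yield from rec_match(ti + 1, pos + g, pre_len + (g if before_bond else 0))
            return
        if pos >= len(seq) or seq[pos] not in tok.classes:
            return
        yield from rec_match(ti + 1, pos + 1, pre_len + (1 if before_bond else 0))

    yield from rec_match(0, start0, 0)


def scan_motifs(
    rec: ProteinRecord,
    region: tuple[int, int] = DEFAULT_SCAN_REGION,
    motif_ids: Optional[Sequence[str]] = None,
) -> list[CleavageSite]:
    """All matches of the requested motifs whose span lies within
    ``region`` (1-based inclusive), as MPP cleavage sites sorted by
    position then motif id.  One bond is reported at most once per motif.
    """
    start, end = region
    if start < 1 or end > len(rec) or start > end:
        raise SequenceError(
            f"scan region {start}..{end} invalid for record {rec.id!r} "
            f"(1..{len(rec)})"
        )
    ids = list(motif_ids) if motif_ids is not None else list(MOTIFS)
    unknown = [i for i in ids if i not in MOTIFS]
    if unknown:
        raise KeyError(f"unknown motif id(s): {unknown}; available: {sorted(MOTIFS)}")

    sites: dict[tuple[str, int], CleavageSite] = {}
    for mid in ids:
        motif = MOTIFS[mid]
        for pos0 in range(start - 1, end):
            for mlen, pre_len in _match_at(rec.seq, motif, pos0):
                span = (pos0 + 1, pos0 + mlen)
                if span[1] > end:
                    continue
                cleave_after = pos0 + pre_len
                key = (mid, cleave_after)
                if key not in sites or (
                    sites[key].span[1] - sites[key].span[0] > mlen - 1
                ):
                    sites[key] = CleavageSite(
                        motif_id=mid, cleave_after=cleave_after, span=span, source="MPP"
                    )
    return sorted(sites.values(), key=lambda s: (s.cleave_after, s.motif_id))


def icp55_trim(
    site: CleavageSite,
    rec: ProteinRecord,
    trim_set: frozenset[str] = DEFAULT_TRIM_SET,
) -> Optional[CleavageSite]:
    """Apply the ICP55 single-residue trim to an MPP site.

    Returns the second site at ``cleave_after + 1`` when the removed
    residue is in ``trim_set`` and a non-empty mature protein remains;
    ``None`` otherwise (including the sequence-boundary case).  Trimming
    applies once: passing an ICP55 site is a contract violation.
    """
    if site.source != "MPP":
        raise SequenceError("icp55_trim applies only to MPP-generated sites")
    nxt = site.cleave_after + 1
    if nxt >= len(rec):  # boundary: nothing left to trim, or empty mature
        return None
    if rec.residue(nxt) not in trim_set:
        return None
    return CleavageSite(
        motif_id=site.motif_id,
        cleave_after=nxt,
        span=site.span,
        source="ICP55",
        mpp_core_support=site.mpp_core_support,
    )


def best_cleavage(
    rec: ProteinRecord,
    region: tuple[int, int] = DEFAULT_SCAN_REGION,
    motif_ids: Optional[Sequence[str]] = None,
    plant_mode: bool = True,
    trim_set: frozenset[str] = DEFAULT_TRIM_SET,
) -> list[CleavageSite]:
    """The primary MPP site plus its optional ICP55 trim.

    Sites are ranked by motif specificity (minus3R_plant > minus3R_general
    > minus10R > minus2R > noR_plant), ties broken by the smallest
    ``cleave_after``.  In plant mode the -10R motif (not observed in
    plants) is excluded from the default set.  MPP_core is never scanned
    as evidence; it only annotates the chosen site when an MPP_core match
    shares the same bond.  Returns an empty list when nothing fires.
    """
    if motif_ids is None:
        ids = [m for m in PRIORITY_ORDER if not (plant_mode and m == "minus10R")]
    else:
        ids = [m for m in motif_ids if m != "MPP_core"]
    region = (region[0], min(region[1], len(rec)))
    sites = scan_motifs(rec, region, ids)
    if not sites:
        return []
    primary = min(sites, key=lambda s: (MOTIFS[s.motif_id].priority, s.cleave_after))
    core_hits = scan_motifs(rec, region, ["MPP_core"])
    if any(c.cleave_after == primary.cleave_after for c in core_hits):
        primary = replace(primary, mpp_core_support=True)
    out = [primary]
    trimmed = icp55_trim(primary, rec, trim_set)
    if trimmed is not None:
        out.append(trimmed)
    return out
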