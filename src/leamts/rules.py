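"""Rule-based mitochondrial-targeting classifier.

The verdict combines four structural conditions on the first N-terminal
helix and the region just past the presequence cleavage site:

C1  the helical wheel shows a hydrophobic face of at least five residues
    (a four-residue grouping is not enough);
C2  exactly two positively charged residues (K/R) sit in the window, both
    at the pole opposite the hydrophobic face, with one pair separated by
    four sequence positions (three residues between, i.e. 40 deg on the
    wheel);
C3  exactly one negatively charged residue (D/E) sits in the window, at
    the hydrophobic/hydrophilic interface;
C4  a -3R cleavage motif fires in the N-terminal scan region AND the
    segment immediately downstream of the last cleavage site is Ser-rich
    (>= 3 Ser in 11 residues) — the helix alone is essential but not
    sufficient, so targeting also requires the post-cleavage segment.

A sequence is called mitochondrial iff every enabled condition holds.
The call is binary, matching all-or-none protoplast localizations, and
deterministic: no randomness enters the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .motifs import DEFAULT_TRIM_SET, best_cleavage
from .mutations import ConstructSeries
from .records import ProteinRecord
from .wheel import (
    DEFAULT_SCALE,
    HelixWindow,
    charge_disposition,
    detect_face,
    project_wheel,
)


@dataclass(frozen=True)
class RuleConfig:
    """Tunable thresholds of the targeting rule (defaults as documented
    in the module docstring)."""

    min_face_size: int = 5
    required_positive_count: int = 2
    positive_sequence_separation: int = 4
    positive_zone: str = "opposite-pole"
    negative_count: int = 1
    negative_zone: str = "interface"
    require_face: bool = True
    require_positive_charges: bool = True
    require_interface_negative: bool = True
    require_downstream_segment: bool = True
    downstream_window_length: int = 11
    downstream_min_serine: int = 3
    cleavage_scan_region: tuple[int, int] = (1, 60)
    cleavage_motifs: tuple[str, ...] = ("minus3R_plant", "minus3R_general")
    trim_set: frozenset[str] = DEFAULT_TRIM_SET
    scale_id: str = DEFAULT_SCALE

    def __post_init__(self) -> None:
        for name in (
            "min_face_size",
            "required_positive_count",
            "positive_sequence_separation",
            "negative_count",
            "downstream_window_length",
            "downstream_min_serine",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"RuleConfig.{name} must be a positive integer")


@dataclass(frozen=True)
class TargetingCall:
    """Per-condition booleans, evidence, and the final verdict."""

    record_id: str
    c1_face: bool
    c2_positives: bool
    c3_negative: bool
    c4_downstream: bool
    verdict: str  # "mitochondrial" | "cytosolic"
    evidence: dict = field(default_factory=dict)

    @property
    def conditions(self) -> dict[str, bool]:
        return {
            "C1": self.c1_face,
            "C2": self.c2_positives,
            "C3": self.c3_negative,
            "C4": self.c4_downstream,
        }


def classify(
    rec: ProteinRecord,
    helix: Optional[HelixWindow],
    cfg: RuleConfig = RuleConfig(),
) -> TargetingCall:
    """Evaluate the four targeting conditions on one record.

    A missing helix annotation yields a cytosolic call with the reason
    recorded in the evidence.
    """
    if helix is None:
        return TargetingCall(
            record_id=rec.id,
            c1_face=False,
            c2_positives=False,
            c3_negative=False,
            c4_downstream=False,
            verdict="cytosolic",
            evidence={"reason": "no helix annotation"},
        )

    proj = project_wheel(helix, cfg.scale_id)
    face = detect_face(proj)
    charges = charge_disposition(proj, face)

    c1 = face.size >= cfg.min_face_size

    positives = charges.positive_positions
    pos_zoned = all(charges.zones[p] == cfg.positive_zone for p in positives)
    pair_ok = any(
        abs(p - q) == cfg.positive_sequence_separation
        for i, p in enumerate(positives)
        for q in positives[i + 1 :]
    )
    c2 = (
        len(positives) == cfg.required_positive_count
        and pos_zoned
        and (pair_ok or cfg.required_positive_count < 2)
    )

    negatives = charges.negative_positions
    c3 = len(negatives) == cfg.negative_count and all(
        charges.zones[n] == cfg.negative_zone for n in negatives
    )

    lo, hi = cfg.cleavage_scan_region
    region = (lo, min(hi, len(rec)))
    sites = best_cleavage(
        rec, region, motif_ids=cfg.cleavage_motifs, trim_set=cfg.trim_set
    )
    if sites:
        last = max(s.cleave_after for s in sites)
        win_start = last + 1
        win_end = min(len(rec), last + cfg.downstream_window_length)
        downstream = rec.segment(win_start, win_end) if win_start <= len(rec) else ""
        ser = downstream.count("S")
        c4 = ser >= cfg.downstream_min_serine
    else:
        downstream, ser = "", 0
        c4 = False

    enabled = {
        "C1": (cfg.require_face, c1),
        "C2": (cfg.require_positive_charges, c2),
        "C3": (cfg.require_interface_negative, c3),
        "C4": (cfg.require_downstream_segment, c4),
    }
    mito = all(ok for req, ok in enabled.values() if req)

    evidence = {
        "window": (helix.start, helix.end),
        "face_size": face.size,
        "face_positions": face.member_positions,
        "face_center_deg": face.center_angle,
        "moment_magnitude": proj.moment_magnitude,
        "moment_direction_deg": proj.moment_direction,
        "positive_positions": positives,
        "negative_positions": negatives,
        "charge_zones": {p: z for p, z in charges.zones.items()},
        "cleavage_sites": [(s.motif_id, s.cleave_after, s.source) for s in sites],
        "downstream_segment": downstream,
        "downstream_serine": ser,
    }
    return TargetingCall(
        record_id=rec.id,
        c1_face=c1,
        c2_positives=c2,
        c3_negative=c3,
        c4_downstream=c4,
        verdict="mitochondrial" if mito else "cytosolic",
        evidence=evidence,
    )


def classify_panel(series: ConstructSeries, cfg: RuleConfig = RuleConfig()) -> pd.DataFrame:
    """Classify every construct in a series.

    Returns one row per construct with the four condition booleans, the
    verdict, the empirical label when present, and an agreement flag.
    A window invalidated by an overlapping deletion is recorded in the
    audit and classified as unannotated (cytosolic).
    """
    rows = []
    for construct in series:
        rec = construct.record
        window = (
            HelixWindow(rec, *construct.helix_window)
            if construct.helix_window is not None
            else None
        )
        call = classify(rec, window, cfg)
        if construct.helix_window is None:
            call.evidence["window_invalidated"] = "deletion overlaps helix window"
        rows.append(
            {
                "construct": rec.id,
                "length": len(rec),
                "C1_face": call.c1_face,
                "C2_positives": call.c2_positives,
                "C3_negative": call.c3_negative,
                "C4_downstream": call.c4_downstream,
                "verdict": call.verdict,
                "empirical": construct.expected_location,
                "agree": call.verdict == construct.expected_location,
                "face_size": call.evidence.get("face_size"),
                "downstream_serine": call.evidence.get("downstream_serine"),
            }
        )
    columns = [
        "construct",
        "length",
        "C1_face",
        "C2_positives",
        "C3_negative",
        "C4_downstream",
        "verdict",
        "empirical",
        "agree",
        "face_size",
        "downstream_serine",
    ]
    return pd.DataFrame(rows, columns=columns)
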