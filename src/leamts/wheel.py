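"""Helical-wheel projection, hydrophobic moment, hydrophobic-face
detection, and charge disposition for an N-terminal helix window.

The wheel places residue k of the window (k = 0, 1, ...) at an angle of
(k * 100) degrees modulo 360, the ideal alpha-helix rise of 100 deg per
residue.  For an 18-residue window this occupies each of the eighteen
20-degree slots exactly once, which is why projections are conventionally
drawn over 18-residue stretches.  The hydrophobic moment is the mean of
the per-residue hydrophobicity vectors; its magnitude measures
amphiphilicity and its direction points toward the hydrophobic face.

Conventions (angle zero at residue 1, counterclockwise-increasing angles)
are arbitrary; moment magnitudes, face membership, and charge zones are
invariant to them.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .records import ProteinRecord, SequenceError

ANGLE_STEP = 100.0  # degrees per residue, ideal alpha helix
SLOT = 20.0  # wheel slot granularity in degrees
MOMENT_TOL = 1e-9

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
#: Residues allowed in a hydrophobic face.  Includes Gly and Ala because
#: printed faces of this protein family (AGAL, VAGAL) contain both.
NONPOLAR_DEFAULT = frozenset("ACFGILMVWY")
#: A charge within one slot (<= 40 deg) of a face end sits at the
#: hydrophobic/hydrophilic interface.
INTERFACE_TOL = 40.0
#: A charge more than 90 deg from the face center sits at the opposite pole.
OPPOSITE_POLE_MIN = 90.0


def _load_scales() -> dict[str, dict[str, float]]:
    scales: dict[str, dict[str, float]] = {}
    text = resources.files("leamts.data").joinpath("scales.tsv").read_text()
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    reader = csv.reader(rows, delimiter="\t")
    header = next(reader)
    residues = header[1:]
    for row in reader:
        scales[row[0]] = {aa: float(v) for aa, v in zip(residues, row[1:])}
    return scales


HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = _load_scales()
DEFAULT_SCALE = "fauchere_pliska"


def circular_distance(a: float, b: float) -> float:
    """Smaller arc between two angles, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class HelixWindow:
    """An annotated helix window of a record, 1-based inclusive."""

    record: ProteinRecord
    start: int
    end: int

    def __post_init__(self) -> None:
        n = self.end - self.start + 1
        if not 6 <= n <= 18:
            raise SequenceError(
                f"helix window {self.start}..{self.end}: projection needs "
                f"6..18 residues, got {n}"
            )
        if self.start < 1 or self.end > len(self.record):
            raise SequenceError(
                f"helix window {self.start}..{self.end} outside record "
                f"{self.record.id!r} (1..{len(self.record)})"
            )

    @property
    def residues(self) -> str:
        return self.record.segment(self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


def first_helix_window(rec: ProteinRecord, helix_start: int, helix_end: int,
                       length: int = 18) -> HelixWindow:
    """The first ``length`` residues of an annotated helix (the projection
    convention for helices longer than one wheel turn set)."""
    end = min(helix_end, helix_start + length - 1)
    return HelixWindow(rec, helix_start, end)


@dataclass(frozen=True)
class WheelProjection:
    """Per-residue wheel placement plus the hydrophobic moment."""

    window: HelixWindow
    scale_id: str
    positions: tuple[int, ...]  # 1-based protein positions
    angles: tuple[float, ...]  # degrees, one per residue
    hydrophobicities: tuple[float, ...]
    moment_magnitude: float
    moment_direction: Optional[float]  # degrees; None when magnitude ~ 0
    slot_of: dict[int, float]  # protein position -> slot angle

    @property
    def occupied_slots(self) -> tuple[float, ...]:
        """Occupied slot angles in increasing angular order."""
        return tuple(sorted(set(self.slot_of.values())))

    def residue_at_slot(self, slot: float) -> str:
        for pos, s in self.slot_of.items():
            if s == slot:
                return self.window.record.residue(pos)
        raise KeyError(slot)

    def position_at_slot(self, slot: float) -> int:
        for pos, s in self.slot_of.items():
            if s == slot:
                return pos
        raise KeyError(slot)


def project_wheel(win: HelixWindow, scale_id: str = DEFAULT_SCALE) -> WheelProjection:
    """Project a helix window onto the wheel and compute its moment.

    Residue k of the window is placed at (k * 100) mod 360 degrees; the
    moment vector is the *mean* over residues of hydrophobicity times the
    unit vector at the residue's angle, so magnitudes are comparable
    across window sizes.
    """
    if scale_id not in HYDROPHOBICITY_SCALES:
        raise KeyError(
            f"unknown hydrophobicity scale {scale_id!r}; "
            f"available: {sorted(HYDROPHOBICITY_SCALES)}"
        )
    scale = HYDROPHOBICITY_SCALES[scale_id]
    residues = win.residues
    positions = tuple(range(win.start, win.end + 1))
    angles = tuple((k * ANGLE_STEP) % 360.0 for k in range(len(residues)))
    hydro = tuple(scale[aa] for aa in residues)
    rad = np.radians(angles)
    mx = float(np.mean(np.array(hydro) * np.cos(rad)))
    my = float(np.mean(np.array(hydro) * np.sin(rad)))
    magnitude = math.hypot(mx, my)
    direction = math.degrees(math.atan2(my, mx)) % 360.0 if magnitude > MOMENT_TOL else None
    slot_of = {pos: ang for pos, ang in zip(positions, angles)}
    if len(residues) == 18 and len(set(slot_of.values())) != 18:  # pragma: no cover
        raise AssertionError("18-residue window must occupy all 18 slots")
    return WheelProjection(
        window=win,
        scale_id=scale_id,
        positions=positions,
        angles=angles,
        hydrophobicities=hydro,
        moment_magnitude=magnitude,
        moment_direction=direction,
        slot_of=slot_of,
    )


@dataclass(frozen=True)
class FaceAnnotation:
    """The hydrophobic face: one angularly contiguous run of occupied
    slots whose residues are all nonpolar (possibly empty)."""

    member_positions: tuple[int, ...]  # 1-based, in angular run order
    member_slots: tuple[float, ...]
    size: int
    angular_span: float  # degrees from first to last member along the run
    center_angle: Optional[float]  # None when the face is empty
    interface_slots: tuple[float, ...]  # occupied slots flanking the run ends

    @property
    def end_slots(self) -> tuple[float, ...]:
        if not self.member_slots:
            return ()
        return (self.member_slots[0], self.member_slots[-1])


def _circular_runs(slots: Sequence[float], good: set[float]) -> list[list[float]]:
    """Maximal circular runs of consecutive occupied slots drawn from ``good``.

    ``slots`` is the full occupied-slot list in angular order; consecutive
    means adjacent in that circular ordering.
    """
    n = len(slots)
    flags = [s in good for s in slots]
    if all(flags):
        return [list(slots)]
    runs, current = [], []
    # rotate so the scan starts at a bad slot: runs never wrap the seam
    start = flags.index(False)
    for i in range(start, start + n):
        s = slots[i % n]
        if flags[i % n]:
            current.append(s)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def _run_center(run: Sequence[float]) -> tuple[float, float]:
    """(span, center angle) of an angularly ordered circular run."""
    first, last = run[0], run[-1]
    span = (last - first) % 360.0
    return span, (first + span / 2.0) % 360.0


def detect_face(proj: WheelProjection,
                nonpolar: frozenset[str] = NONPOLAR_DEFAULT) -> FaceAnnotation:
    """Longest circular run of occupied slots whose residues are all
    nonpolar.  Ties go to the run whose center is closest to the moment
    direction (falling back to the smallest start angle when the moment
    is undefined).  An all-polar window yields an empty face.
    """
    slots = list(proj.occupied_slots)
    good = {s for s in slots if proj.residue_at_slot(s) in nonpolar}
    if not good:
        return FaceAnnotation((), (), 0, 0.0, None, ())
    runs = _circular_runs(slots, good)
    best_size = max(len(r) for r in runs)
    candidates = [r for r in runs if len(r) == best_size]

    def tie_key(run: list[float]) -> tuple[float, float]:
        _, center = _run_center(run)
        if proj.moment_direction is not None:
            return (circular_distance(center, proj.moment_direction), run[0])
        return (0.0, run[0])

    run = min(candidates, key=tie_key)
    span, center = _run_center(run)
    members = tuple(proj.position_at_slot(s) for s in run)
    # occupied slots angularly adjacent to the two run ends
    idx = {s: i for i, s in enumerate(slots)}
    n = len(slots)
    before = slots[(idx[run[0]] - 1) % n]
    after = slots[(idx[run[-1]] + 1) % n]
    interface = tuple(dict.fromkeys([before, after])) if len(run) < n else ()
    return FaceAnnotation(
        member_positions=members,
        member_slots=tuple(run),
        size=len(run),
        angular_span=span,
        center_angle=center,
        interface_slots=interface,
    )


@dataclass(frozen=True)
class ChargeDisposition:
    """Placement of charged residues relative to the hydrophobic face.

    Zones are mutually exclusive per charge: ``face`` (a face member slot),
    ``interface`` (within one slot, <= 40 deg, of a face end),
    ``opposite-pole`` (more than 90 deg from the face center), or ``other``.
    With an empty face all zones are ``other`` and ``face_undefined`` is set.
    """

    positive_positions: tuple[int, ...]
    negative_positions: tuple[int, ...]
    angles: dict[int, float]
    zones: dict[int, str]
    angular_separations: dict[tuple[int, int], float]
    sequence_separations: dict[tuple[int, int], int]
    face_undefined: bool = False


def charge_disposition(proj: WheelProjection, face: FaceAnnotation) -> ChargeDisposition:
    """Locate and zone every K/R and D/E in the window, and report all
    pairwise angular and sequence separations among charges."""
    rec = proj.window.record
    positives = tuple(p for p in proj.positions if rec.residue(p) in POSITIVE)
    negatives = tuple(p for p in proj.positions if rec.residue(p) in NEGATIVE)
    charged = positives + negatives
    angles = {p: proj.slot_of[p] for p in charged}

    zones: dict[int, str] = {}
    undefined = face.size == 0
    member_slots = set(face.member_slots)
    for p in charged:
        a = angles[p]
        if undefined:
            zones[p] = "other"
        elif a in member_slots:
            zones[p] = "face"
        elif any(circular_distance(a, e) <= INTERFACE_TOL for e in face.end_slots):
            zones[p] = "interface"
        elif circular_distance(a, face.center_angle) > OPPOSITE_POLE_MIN:
            zones[p] = "opposite-pole"
        else:
            zones[p] = "other"

    ang_sep, seq_sep = {}, {}
    for i, p in enumerate(charged):
        for q in charged[i + 1 :]:
            key = (min(p, q), max(p, q))
            ang_sep[key] = circular_distance(angles[p], angles[q])
            seq_sep[key] = abs(p - q)
    return ChargeDisposition(
        positive_positions=positives,
        negative_positions=negatives,
        angles=angles,
        zones=zones,
        angular_separations=ang_sep,
        sequence_separations=seq_sep,
        face_undefined=undefined,
    )


def wheel_table(proj: WheelProjection, face: FaceAnnotation,
                charges: ChargeDisposition) -> list[dict]:
    """Structured per-residue export (position, residue, angle, slot,
    hydrophobicity, zone) for reports and TSV output."""
    rows = []
    face_slots = set(face.member_slots)
    for pos, ang, h in zip(proj.positions, proj.angles, proj.hydrophobicities):
        aa = proj.window.record.residue(pos)
        if pos in charges.zones:
            zone = charges.zones[pos]
        elif ang in face_slots:
            zone = "face"
        else:
            zone = "other"
        rows.append(
            {
                "position": pos,
                "residue": aa,
                "angle_deg": ang,
                "slot_deg": ang,
                "hydrophobicity": h,
                "zone": zone,
            }
        )
    return rows


def plot_wheel(proj: WheelProjection, face: FaceAnnotation, path: str) -> None:
    """Render the wheel to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    face_slots = set(face.member_slots)
    for pos, ang in zip(proj.positions, proj.angles):
        aa = proj.window.record.residue(pos)
        rad = math.radians(ang)
        x, y = math.cos(rad), math.sin(rad)
        if aa in POSITIVE:
            color = "tab:blue"
        elif aa in NEGATIVE:
            color = "tab:red"
        elif ang in face_slots:
            color = "gold"
        else:
            color = "lightgray"
        ax.add_patch(plt.Circle((x, y), 0.09, color=color, zorder=2))
        ax.text(x, y, f"{aa}{pos}", ha="center", va="center", fontsize=7, zorder=3)
    if proj.moment_direction is not None:
        rad = math.radians(proj.moment_direction)
        scale = min(0.8, proj.moment_magnitude)
        ax.arrow(0, 0, scale * math.cos(rad), scale * math.sin(rad),
                 head_width=0.05, color="black", zorder=1)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"{proj.window.record.id} {proj.window.start}-{proj.window.end}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
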