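"""Wheel geometry: angles, moments, face detection, charge zones.

Face detection is checked against an exhaustive, independent enumeration
of circular nonpolar runs, and moment magnitudes against direct
recomputation under shifted angular conventions.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leamts import HelixWindow, ProteinRecord, charge_disposition, detect_face, project_wheel
from leamts.wheel import (
    HYDROPHOBICITY_SCALES,
    NONPOLAR_DEFAULT,
    circular_distance,
)

aa = "ACDEFGHIKLMNPQRSTVWY"
windows_18 = st.text(alphabet=aa, min_size=18, max_size=18)


def brute_force_face(proj, nonpolar=NONPOLAR_DEFAULT):
    """Oracle: enumerate every circular run of occupied slots, keep the
    longest all-nonpolar one (ties resolved like the implementation)."""
    slots = list(proj.occupied_slots)
    n = len(slots)
    good = [proj.residue_at_slot(s) in nonpolar for s in slots]
    best = []
    if all(good):
        best = [slots]
    else:
        for i in range(n):
            for length in range(1, n):
                run = [slots[(i + j) % n] for j in range(length)]
                if all(good[(i + j) % n] for j in range(length)):
                    if not best or length > len(best[0]):
                        best = [run]
                    elif length == len(best[0]):
                        best.append(run)
                else:
                    break
    if not best:
        return frozenset()
    def center(run):
        span = (run[-1] - run[0]) % 360.0
        return (run[0] + span / 2.0) % 360.0
    if proj.moment_direction is not None:
        best.sort(key=lambda r: (circular_distance(center(r), proj.moment_direction), r[0]))
    else:
        best.sort(key=lambda r: r[0])
    return frozenset(best[0])


def make_window(seq):
    return HelixWindow(ProteinRecord(id="w", seq=seq), 1, len(seq))


def test_angle_assignment_100_degrees_per_residue():
    proj = project_wheel(make_window("A" * 18))
    assert proj.angles[0] == 0.0
    assert proj.angles[1] == 100.0
    assert proj.angles[3] == 300.0
    # residue 19 would alias residue 1: 18 * 100 = 1800 = 0 mod 360
    assert (18 * 100) % 360 == 0


@given(windows_18)
def test_slot_bijectivity_for_18_residue_windows(seq):
    proj = project_wheel(make_window(seq))
    slots = proj.occupied_slots
    assert len(slots) == 18
    assert set(slots) == {20.0 * i for i in range(18)}


@pytest.mark.parametrize("residue", sorted(aa))
def test_homopolymer_moment_vanishes(residue):
    proj = project_wheel(make_window(residue * 18))
    assert proj.moment_magnitude == pytest.approx(0.0, abs=1e-9)
    assert proj.moment_direction is None


@given(windows_18)
def test_moment_invariant_under_angular_offset(seq):
    """Direct recomputation with the start angle shifted by any constant
    leaves the magnitude (and face membership) unchanged."""
    proj = project_wheel(make_window(seq))
    scale = HYDROPHOBICITY_SCALES["fauchere_pliska"]
    for offset in (37.0, 180.0):
        rad = np.radians([a + offset for a in proj.angles])
        h = np.array([scale[c] for c in seq])
        mag = math.hypot(float(np.mean(h * np.cos(rad))), float(np.mean(h * np.sin(rad))))
        assert mag == pytest.approx(proj.moment_magnitude, abs=1e-9)


@given(windows_18)
def test_face_matches_brute_force(seq):
    proj = project_wheel(make_window(seq))
    face = detect_face(proj)
    assert frozenset(face.member_slots) == brute_force_face(proj)


def test_face_sizes_on_constructed_windows():
    # Leu on slots 0..80 (window indices 0, 11, 4, 15, 8), polar elsewhere
    chars = ["S"] * 18
    for k in (0, 11, 4, 15, 8):
        chars[k] = "L"
    face = detect_face(project_wheel(make_window("".join(chars))))
    assert face.size == 5
    assert set(face.member_slots) == {0.0, 20.0, 40.0, 60.0, 80.0}

    assert detect_face(project_wheel(make_window("S" * 18))).size == 0


def test_agal_scaffold_has_four_residue_face(bases):
    """The cytosolic paralog's window groups four nonpolar residues
    (AGAL) without reaching the five-residue face."""
    base2, _ = bases
    face = detect_face(project_wheel(HelixWindow(base2, 5, 22)))
    assert face.size == 4
    residues = [base2.residue(p) for p in face.member_positions]
    assert sorted(residues) == ["A", "A", "G", "L"]


def test_vavvl_face_and_charge_disposition(bases):
    """The mitochondrial paralog's window: five-residue face, Glu at the
    interface, two positives at the opposite pole 40 deg apart."""
    _, base38 = bases
    proj = project_wheel(HelixWindow(base38, 7, 24))
    face = detect_face(proj)
    assert face.size == 5
    assert [base38.residue(p) for p in face.member_positions] == list("VAVVL")
    charges = charge_disposition(proj, face)
    assert charges.negative_positions == (19,)
    assert charges.zones[19] == "interface"
    assert set(charges.positive_positions) == {13, 17}
    assert charges.zones[13] == charges.zones[17] == "opposite-pole"
    assert charges.sequence_separations[(13, 17)] == 4
    assert charges.angular_separations[(13, 17)] == pytest.approx(40.0)


def test_sequence_separation_four_means_40_degrees():
    chars = ["S"] * 18
    chars[2], chars[6] = "K", "K"
    proj = project_wheel(make_window("".join(chars)))
    face = detect_face(proj)
    charges = charge_disposition(proj, face)
    (pair,) = charges.angular_separations
    assert charges.angular_separations[pair] == pytest.approx(40.0)


def test_empty_face_zones_flagged():
    chars = ["S"] * 18
    chars[5] = "E"
    proj = project_wheel(make_window("".join(chars)))
    face = detect_face(proj)
    charges = charge_disposition(proj, face)
    assert face.size == 0
    assert charges.face_undefined
    assert charges.zones[6] == "other"


def test_window_length_limits(bases):
    base2, _ = bases
    with pytest.raises(Exception):
        HelixWindow(base2, 1, 5)  # too short
    with pytest.raises(Exception):
        HelixWindow(base2, 1, 19)  # too long
    with pytest.raises(KeyError):
        project_wheel(HelixWindow(base2, 5, 22), "no_such_scale")
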