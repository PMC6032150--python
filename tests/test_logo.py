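"""Logo statistics against closed forms and a naive counting oracle."""

import math
import random
from collections import Counter

import numpy as np
import pytest

from leamts import ProteinRecord, build_profile, extract_consensus, match_consensus
from leamts.logo import SequenceError, profile_table

aa = "ACDEFGHIKLMNPQRSTVWY"
LOG2_20 = math.log2(20)


class TestInformationContent:
    def test_uniform_column_is_zero_bits(self):
        seqs = [c * 3 for c in aa]  # 20 sequences, 3 identical columns
        profile = build_profile(seqs, length=3)
        assert profile.information == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)

    def test_conserved_column_is_log2_20_bits(self):
        profile = build_profile(["AAA"] * 50, length=3)
        assert profile.information == pytest.approx([LOG2_20] * 3, abs=1e-12)

    def test_small_sample_correction_at_n_100(self):
        profile = build_profile(["A" * 5] * 100, length=5, correction=True)
        expected = LOG2_20 - 19.0 / (2.0 * math.log(2) * 100)
        assert profile.information[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(LOG2_20 - 0.137, abs=5e-4)

    def test_correction_floors_at_zero(self):
        seqs = [c * 2 for c in aa]
        profile = build_profile(seqs, length=2, correction=True)
        assert (profile.information >= 0).all()

    def test_information_decreases_with_entropy(self):
        """More column diversity, fewer bits."""
        tight = ["A" * 4] * 95 + ["C" * 4] * 5
        loose = ["A" * 4] * 50 + ["C" * 4] * 50
        pt = build_profile(tight, length=4)
        pl = build_profile(loose, length=4)
        assert pt.information[0] > pl.information[0]

    def test_permutation_invariance(self):
        rng = random.Random(7)
        seqs = ["".join(rng.choice(aa) for _ in range(6)) for _ in range(30)]
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        a = build_profile(seqs, length=6)
        b = build_profile(shuffled, length=6)
        assert np.allclose(a.information, b.information)
        assert a.frequencies.equals(b.frequencies)


def test_frequencies_match_counting_oracle():
    rng = random.Random(13)
    seqs = ["".join(rng.choice(aa) for _ in range(8)) for _ in range(40)]
    profile = build_profile(seqs, length=8)
    for col in range(8):
        counts = Counter(s[col] for s in seqs)
        for res in aa:
            assert profile.frequencies.loc[col + 1, res] == pytest.approx(
                counts[res] / 40.0, abs=1e-12
            )


def test_gap_columns_excluded_with_coverage():
    profile = build_profile(["AAA", "A-A", "AAA", "A.A"], length=3)
    assert profile.coverage[1] == pytest.approx(0.5)
    assert profile.frequencies.loc[2, "A"] == pytest.approx(1.0)


def test_input_validation():
    with pytest.raises(SequenceError):
        build_profile(["AAAA"], length=4)  # fewer than two sequences
    with pytest.raises(SequenceError, match="shorter"):
        build_profile(["AAAA", "AA"], length=4)


class TestConsensus:
    def make_profile(self, columns, n=80):
        """Build a profile whose column compositions are given exactly."""
        seqs = [""] * n
        for comp in columns:
            letters = []
            for res, frac in comp.items():
                letters.extend(res * round(frac * n))
            assert len(letters) == n
            for i in range(n):
                seqs[i] += letters[i]
        return build_profile(seqs, length=len(columns))

    def test_extraction_rules(self):
        profile = self.make_profile(
            [
                {"Y": 0.6, "F": 0.4},  # two alternatives reach 0.9
                {"A": 0.95, "C": 0.05},  # single residue reaches 0.9
                {c: 0.125 for c in "ACDEFGHI"},  # needs > 3 residues
            ]
        )
        pattern = extract_consensus(profile, threshold=0.9)
        assert pattern.columns == (("Y", "F"), ("A",), ())

    def test_tie_break_frequency_then_alphabet(self):
        profile = self.make_profile([{"T": 0.5, "G": 0.5}])
        pattern = extract_consensus(profile, threshold=0.9)
        assert pattern.columns == (("G", "T"),)

    def test_threshold_validation(self):
        profile = self.make_profile([{"A": 1.0}])
        with pytest.raises(ValueError):
            extract_consensus(profile, threshold=0.4)

    def test_match_printed_cytosolic_segment(self, bases):
        """RRGFAAAA at 25..32 satisfies R-R-G-(Y/F)-A-A-(A/T)-(A/S)."""
        base2, _ = bases
        pattern = extract_consensus(
            self.make_profile(
                [
                    {"R": 1.0},
                    {"R": 1.0},
                    {"G": 1.0},
                    {"Y": 0.6, "F": 0.4},
                    {"A": 1.0},
                    {"A": 1.0},
                    {"A": 0.6, "T": 0.4},
                    {"A": 0.6, "S": 0.4},
                ]
            ),
            threshold=0.9,
        )
        ok, report = match_consensus(base2, pattern, offset=25)
        assert ok
        assert all(r["match"] for r in report)
        # L at the (Y/F) column fails, and the report localizes it
        bad = ProteinRecord(id="x", seq="RRGLAAAA")
        ok, report = match_consensus(bad, pattern, offset=1)
        assert not ok
        assert [r["match"] for r in report] == [True, True, True, False] + [True] * 4

    def test_all_wildcard_matches_anything(self):
        profile = self.make_profile([{c: 0.125 for c in "ACDEFGHI"}] * 2)
        pattern = extract_consensus(profile, threshold=0.9)
        ok, _ = match_consensus(ProteinRecord(id="x", seq="WW"), pattern, offset=1)
        assert ok
        with pytest.raises(SequenceError):
            match_consensus(ProteinRecord(id="x", seq="WW"), pattern, offset=2)

    def test_pattern_rendering(self):
        profile = self.make_profile(
            [{"R": 1.0}, {"Y": 0.6, "F": 0.4}, {c: 0.125 for c in "ACDEFGHI"}]
        )
        pattern = extract_consensus(profile, threshold=0.9)
        assert pattern.to_string() == "R-(Y/F)-X"


def test_profile_table_is_long_format():
    profile = build_profile(["AC", "AC", "AG"], length=2)
    table = profile_table(profile)
    assert set(table.columns) == {"column", "residue", "frequency", "bits", "column_bits"}
    assert (table[table["column"] == 1]["residue"] == "A").all()
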