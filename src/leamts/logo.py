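"""Column statistics, information content, and degenerate-consensus
extraction over aligned N-terminal blocks.

Information content per column is computed against a uniform background
over the 20 standard residues:

    IC = log2(20) - H(column) - correction

with the optional small-sample correction (19) / (2 ln2 n) for n aligned
sequences, floored at zero.  Gap characters are excluded from column
frequencies; per-column coverage is reported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import ProteinRecord, STANDARD_AA, SequenceError

ALPHABET = tuple(sorted(STANDARD_AA))
GAP_CHARS = frozenset("-.")
MAX_BITS = math.log2(20)
#: Columns needing more than this many residues to reach the inclusion
#: threshold collapse to a wildcard (printed consensus patterns of this
#: family never list more than two alternatives).
MAX_ALTERNATIVES = 3


@dataclass(frozen=True)
class LogoProfile:
    """Per-column residue frequencies and information content."""

    n_sequences: int
    length: int
    frequencies: pd.DataFrame  # index 1..length, columns ALPHABET
    information: np.ndarray  # bits per column
    coverage: np.ndarray  # non-gap fraction per column
    corrected: bool

    def column(self, pos: int) -> pd.Series:
        """Frequency vector of 1-based column ``pos``."""
        return self.frequencies.loc[pos]


def build_profile(
    seqs: Sequence[str | ProteinRecord],
    length: int = 40,
    correction: bool = False,
) -> LogoProfile:
    """Build a logo profile over the first ``length`` aligned columns.

    Sequences shorter than ``length`` are rejected with a report naming
    them; at least two sequences are required.
    """
    raw = [s.seq if isinstance(s, ProteinRecord) else s.upper() for s in seqs]
    if len(raw) < 2:
        raise SequenceError(f"profile needs >= 2 sequences, got {len(raw)}")
    short = [i for i, s in enumerate(raw) if len(s) < length]
    if short:
        raise SequenceError(
            f"{len(short)} sequence(s) shorter than {length} columns "
            f"(indices {short[:10]})"
        )
    n = len(raw)
    counts = np.zeros((length, len(ALPHABET)), dtype=float)
    cover = np.zeros(length, dtype=float)
    index = {aa: j for j, aa in enumerate(ALPHABET)}
    for s in raw:
        for i in range(length):
            aa = s[i]
            if aa in GAP_CHARS:
                continue
            if aa not in index:
                raise SequenceError(f"illegal residue {aa!r} in alignment column {i + 1}")
            counts[i, index[aa]] += 1
            cover[i] += 1
    if np.any(cover == 0):
        raise SequenceError("alignment column with only gaps")
    freqs = counts / cover[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=1)
    info = MAX_BITS - entropy
    if correction:
        info = info - (len(ALPHABET) - 1) / (2.0 * math.log(2) * n)
    info = np.maximum(info, 0.0)
    frame = pd.DataFrame(freqs, index=range(1, length + 1), columns=ALPHABET)
    return LogoProfile(
        n_sequences=n,
        length=length,
        frequencies=frame,
        information=info,
        coverage=cover / n,
        corrected=correction,
    )


@dataclass(frozen=True)
class ConsensusPattern:
    """Degenerate per-column consensus: fixed residue, alternative set,
    or wildcard, with optional scissile-bond annotations."""

    columns: tuple[tuple[str, ...], ...]  # () = wildcard
    threshold: float
    offset: int = 1  # 1-based position of the first column
    cleavage_after: tuple[int, ...] = ()  # pattern-local column indices

    def __len__(self) -> int:
        return len(self.columns)

    def to_string(self) -> str:
        parts = []
        for i, col in enumerate(self.columns, start=1):
            if not col:
                parts.append("X")
            elif len(col) == 1:
                parts.append(col[0])
            else:
                parts.append("(" + "/".join(col) + ")")
            if i in self.cleavage_after:
                parts.append("v")
        return "-".join(parts)


def extract_consensus(profile: LogoProfile, threshold: float = 0.9) -> ConsensusPattern:
    """Degenerate consensus from a profile.

    Per column, residues are added in descending frequency (frequency then
    alphabet tie-break) until the cumulative frequency reaches
    ``threshold``: one residue gives a fixed column, two or three an
    alternative set, more a wildcard.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1], got {threshold}")
    columns = []
    for pos in range(1, profile.length + 1):
        freqs = profile.column(pos)
        order = sorted(ALPHABET, key=lambda aa: (-freqs[aa], aa))
        cum, chosen = 0.0, []
        for aa in order:
            chosen.append(aa)
            cum += freqs[aa]
            if cum >= threshold - 1e-12:
                break
        if len(chosen) > MAX_ALTERNATIVES:
            columns.append(())
        else:
            columns.append(tuple(chosen))
    return ConsensusPattern(columns=tuple(columns), threshold=threshold)


def match_consensus(
    rec: ProteinRecord, pattern: ConsensusPattern, offset: int = 1
) -> tuple[bool, list[dict]]:
    """Match a pattern against a record starting at 1-based ``offset``.

    Returns the overall verdict plus a per-column report; wildcards always
    match.
    """
    end = offset + len(pattern) - 1
    if offset < 1 or end > len(rec):
        raise SequenceError(
            f"pattern columns {offset}..{end} outside record {rec.id!r} "
            f"(1..{len(rec)})"
        )
    report = []
    ok = True
    for i, col in enumerate(pattern.columns):
        pos = offset + i
        aa = rec.residue(pos)
        matched = (not col) or aa in col
        ok = ok and matched
        report.append(
            {
                "position": pos,
                "residue": aa,
                "allowed": "/".join(col) if col else "X",
                "match": matched,
            }
        )
    return ok, report


def profile_table(profile: LogoProfile) -> pd.DataFrame:
    """Long-format (column, residue, frequency, bits) table for TSV export."""
    rows = []
    for pos in range(1, profile.length + 1):
        freqs = profile.column(pos)
        bits = float(profile.information[pos - 1])
        for aa in ALPHABET:
            if freqs[aa] > 0:
                rows.append(
                    {
                        "column": pos,
                        "residue": aa,
                        "frequency": float(freqs[aa]),
                        "bits": bits * float(freqs[aa]),
                        "column_bits": bits,
                    }
                )
    return pd.DataFrame(rows, columns=["column", "residue", "frequency", "bits", "column_bits"])


def plot_logo(profile: LogoProfile, path: str) -> None:
    """Render a simple letter-stack logo (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, profile.length * 0.3), 2.5))
    for pos in range(1, profile.length + 1):
        freqs = profile.column(pos)
        bits = float(profile.information[pos - 1])
        stack = sorted(
            ((float(freqs[aa]) * bits, aa) for aa in ALPHABET if freqs[aa] > 0)
        )
        y = 0.0
        for h, aa in stack:
            if h <= 0:
                continue
            ax.text(
                pos,
                y + h / 2,
                aa,
                ha="center",
                va="center",
                fontsize=9,
                stretch="expanded",
            )
            y += h
    ax.set_xlim(0.5, profile.length + 0.5)
    ax.set_ylim(0, MAX_BITS)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
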