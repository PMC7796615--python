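"""Strand-specific coverage profiles and transcribed-fraction statistics.

Coverage is the mapped read count per base, kept separately for the two
transcript strands.  For visualisation-scale profiles, coverage is
summarised in non-overlapping windows (default 100 bp) and compressed with
``log10(coverage + 1) / log10(max_coverage + 1)``, which maps zero coverage
to 0 and the strand's maximum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import Plastome, StrandedAlignmentRecord

__all__ = [
    "CoverageVector",
    "WindowProfile",
    "per_base_coverage",
    "window_scores",
    "transcribed_fraction",
]


@dataclass
class CoverageVector:
    """Per-position mapped read counts for one transcript strand."""

    strand: str
    counts: np.ndarray  # int, length = genome length

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative coverage")


@dataclass
class WindowProfile:
    """Windowed coverage with the log-compressed score in [0, 1]."""

    strand: str
    window: int
    starts: np.ndarray
    raw: np.ndarray  # mean per-base count per window
    transformed: np.ndarray
    max_raw: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": self.starts,
                "end": np.minimum(self.starts + self.window, self.starts[-1] + self.window),
                "strand": self.strand,
                "raw": self.raw,
                "transformed": self.transformed,
            }
        )


def per_base_coverage(
    records: Iterable[StrandedAlignmentRecord], genome: Plastome
) -> dict[str, CoverageVector]:
    """Count reads covering each base, per transcript strand.

    Only M-aligned segments contribute; deletions span but do not cover.
    Records extending past the genome end are an error (simulated and
    desk-scale alignments never wrap).
    """
    L = genome.length
    diff = {"+": np.zeros(L + 1, dtype=np.int64), "-": np.zeros(L + 1, dtype=np.int64)}
    for rec in records:
        d = diff[rec.transcript_strand]
        for s, e in rec.aligned_blocks:
            if s < 0 or e > L:
                raise ValueError(f"read {rec.read_id} outside genome bounds [{s},{e})")
            d[s] += 1
            d[e] -= 1
    return {
        s: CoverageVector(s, np.cumsum(diff[s][:-1])) for s in ("+", "-")
    }


def window_scores(coverage: CoverageVector, window: int = 100) -> WindowProfile:
    """Mean coverage per non-overlapping window, log-compressed to [0, 1].

    ``transformed = log10(raw + 1) / log10(max_raw + 1)`` with ``max_raw``
    the largest window value on this strand; an all-zero strand maps to all
    zeros.  The final partial window is retained.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts = coverage.counts
    if counts.size == 0:
        raise ValueError("empty genome")
    n_full = counts.size // window
    means = []
    starts = []
    for i in range(n_full):
        means.append(counts[i * window : (i + 1) * window].mean())
        starts.append(i * window)
    if counts.size % window:
        means.append(counts[n_full * window :].mean())
        starts.append(n_full * window)
    raw = np.array(means)
    max_raw = float(raw.max())
    denom = np.log10(max_raw + 1)
    transformed = np.log10(raw + 1) / denom if denom > 0 else np.zeros_like(raw)
    return WindowProfile(
        strand=coverage.strand,
        window=window,
        starts=np.array(starts),
        raw=raw,
        transformed=transformed,
        max_raw=max_raw,
    )


def transcribed_fraction(
    coverage: dict[str, CoverageVector] | Sequence[CoverageVector],
    min_cov: int = 1,
) -> tuple[float, float, float]:
    """Fractions of positions covered on '+', on '-', and on either strand.

    A position counts as transcribed when its read count reaches
    ``min_cov``.  The combined fraction is over the union, so it is always
    at least the larger single-strand fraction.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not isinstance(coverage, dict):
        coverage = {c.strand: c for c in coverage}
    plus = coverage["+"].counts >= min_cov
    minus = coverage["-"].counts >= min_cov
    n = plus.size
    if n == 0:
        return (0.0, 0.0, 0.0)
    return (
        float(plus.mean()),
        float(minus.mean()),
        float((plus | minus).mean()),
    )
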