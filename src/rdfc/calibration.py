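"""Significance calibration and cohort statistics for rdFC matching.

The match-score significance threshold is calibrated by Monte Carlo:
pseudo-patterns with 15 iid Uniform(-1, 1) coordinates are scored
against the reference set (best of three) and the 95th percentile of the
null scores is the cutoff — by construction exactly 5% of random
patterns reach it.  Prevalence, lowest-coordinate prediction accuracy
and the exclusive-vs-double-match coordinate-gap comparison (two-sided
Mann-Whitney U with the common-language effect size U/(n1*n2)) complete
the statistical layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .core import RdfcPattern, compute_pattern, enumerate_permutations
from .matching import MatchResult, ReferenceSet, best_match, predict_reference, segment_directions

__all__ = [
    "ThresholdCalibration",
    "MatchVector",
    "GapTestResult",
    "generate_pseudo_patterns",
    "null_match_scores",
    "calibrate_threshold",
    "match_vector",
    "prevalence_summary",
    "prediction_accuracy",
    "gap_test",
]


@dataclass
class ThresholdCalibration:
    """Monte-Carlo null summary yielding the significance cutoff."""

    threshold: float
    n_patterns: int
    percentile: float
    seed: int
    score_sample: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "n_patterns": int(self.n_patterns),
            "percentile": float(self.percentile),
            "seed": int(self.seed),
        }


@dataclass
class MatchVector:
    """Per-reference counts of matching permutations of one triplet."""

    counts: tuple[int, int, int]
    triplet: tuple[str, str, str]
    epoch_start: float = 0.0

    def __post_init__(self) -> None:
        if sum(self.counts) > 6 or any(c < 0 for c in self.counts):
            raise ValueError("match-vector entries are counts over 6 permutations")


@dataclass
class GapTestResult:
    """Two-sided Mann-Whitney comparison of coordinate gaps."""

    U: float
    p: float
    cles: float
    median1: float
    median2: float
    iqr1: tuple[float, float]
    iqr2: tuple[float, float]
    n1: int
    n2: int


def generate_pseudo_patterns(n: int, seed: int) -> np.ndarray:
    """n pseudo-patterns: 5 points x 3 coordinates, iid Uniform(-1, 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(n, 5, 3))


def _unit_segments(points: np.ndarray) -> np.ndarray:
    """Vectorized unit segment directions for a stack of patterns."""
    segs = np.diff(points, axis=-2)
    norms = np.linalg.norm(segs, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        units = np.where(norms > 0, segs / np.where(norms > 0, norms, 1.0), 0.0)
    return units


def null_match_scores(refs: ReferenceSet, n: int, seed: int) -> np.ndarray:
    """Best-of-three match scores of n random pseudo-patterns."""
    ref_units = np.stack([segment_directions(p)[0] for p in refs.patterns])  # (3, 4, 3)
    if not np.any(np.linalg.norm(ref_units, axis=-1) > 0):
        raise ValueError("degenerate reference set: all segments have zero length")
    pseudo = generate_pseudo_patterns(n, seed)
    units = _unit_segments(pseudo)  # (n, 4, 3)
    scores = np.einsum("nsc,rsc->nr", units, ref_units)  # (n, 3)
    return scores.max(axis=1)


def calibrate_threshold(
    refs: ReferenceSet,
    n: int = 100_000,
    percentile: float = 95.0,
    seed: int = 0,
    keep_scores: bool = False,
) -> ThresholdCalibration:
    """Calibrate the significance threshold on the Monte-Carlo null.

    Returns the linear-interpolation empirical ``percentile`` of the
    best-of-three null scores; with the default 95 exactly 5% of random
    pseudo-patterns score at or above the threshold.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    best = null_match_scores(refs, n, seed)
    thr = float(np.percentile(best, percentile))
    return ThresholdCalibration(
        threshold=thr,
        n_patterns=n,
        percentile=percentile,
        seed=seed,
        score_sample=best if keep_scores else None,
    )


def match_vector(
    triplet: Sequence[str],
    epoch,
    refs: ReferenceSet,
    threshold: float,
    window: int | None = None,
    orders: int = 5,
) -> MatchVector:
    """Count, per reference, how many of the 6 permutations match.

    Only significant patterns are counted, each under its best-matching
    reference; entries therefore sum to at most 6.
    """
    counts = [0, 0, 0]
    for seq in enumerate_permutations(triplet):
        pat = compute_pattern(epoch, seq, window=window, orders=orders)
        res = best_match(pat, refs, threshold)
        if res.significant:
            counts[res.best_id - 1] += 1
    return MatchVector(
        counts=tuple(counts),
        triplet=tuple(triplet),
        epoch_start=float(getattr(epoch, "start_time", 0.0)),
    )


def prevalence_summary(results: Iterable[MatchResult | MatchVector]) -> dict:
    """Prevalence of the three references among significant matches.

    Accepts MatchResults (per-pattern) and/or MatchVectors (per-triplet);
    returns per-reference percentage frequencies among matches, the
    overall match percentage (significant / all patterns, available for
    MatchResults only), and the histogram of match-vector entries 0..6.
    """
    results = list(results)
    if not results:
        raise ValueError("empty result collection")
    ref_counts = np.zeros(3, dtype=int)
    n_patterns = 0
    n_significant = 0
    hist = np.zeros(7, dtype=int)
    have_hist = False
    for r in results:
        if isinstance(r, MatchVector):
            ref_counts += np.asarray(r.counts)
            have_hist = True
            for c in r.counts:
                hist[c] += 1
        else:
            n_patterns += 1
            if r.significant:
                n_significant += 1
                ref_counts[r.best_id - 1] += 1
    total = int(ref_counts.sum())
    freqs = 100.0 * ref_counts / total if total else np.full(3, np.nan)
    out = {
        "reference_frequencies_pct": freqs,
        "n_matches": total,
    }
    if n_patterns:
        out["match_percentage"] = 100.0 * n_significant / n_patterns
        out["n_patterns"] = n_patterns
    if have_hist:
        out["match_vector_histogram"] = hist
    return out


def prediction_accuracy(
    patterns: Iterable[RdfcPattern],
    refs: ReferenceSet,
    threshold: float,
) -> dict:
    """Lowest-coordinate prediction accuracy among exclusive matches.

    For every pattern matching exactly one reference, the reference is
    predicted from the first-order point alone (axis of the lowest
    coefficient, via the set's mapping) and compared with the
    best-of-three match.  Also reports the exclusivity rate: the share
    of significant matches that are exclusive.
    """
    n_exclusive = 0
    n_correct = 0
    n_significant = 0
    n_patterns = 0
    for pat in patterns:
        n_patterns += 1
        res = best_match(pat, refs, threshold)
        if not res.significant:
            continue
        n_significant += 1
        if not res.exclusive:
            continue
        pred, _ = predict_reference(pat, refs.mapping)
        if pred is None:  # tied lowest coordinates: excluded from denominator
            continue
        n_exclusive += 1
        if pred == res.best_id:
            n_correct += 1
    if n_patterns == 0:
        raise ValueError("empty pattern collection")
    return {
        "accuracy_pct": 100.0 * n_correct / n_exclusive if n_exclusive else float("nan"),
        "n_exclusive": n_exclusive,
        "exclusivity_rate_pct": (
            100.0 * n_exclusive / n_significant if n_significant else float("nan")
        ),
        "n_significant": n_significant,
        "n_patterns": n_patterns,
    }


def gap_test(group_exclusive: Sequence[float], group_double: Sequence[float]) -> GapTestResult:
    """Two-sided Mann-Whitney U on coordinate gaps of two groups.

    No Fisher transform is applied (the test is rank-based and the gaps
    are bounded differences of correlations); the common-language effect
    size is the larger U divided by n1*n2, which equals the area under
    the ROC curve of the two groups.
    """
    g1 = np.asarray(group_exclusive, dtype=float)
    g2 = np.asarray(group_double, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be nonempty")
    res = spstats.mannwhitneyu(g1, g2, alternative="two-sided", method="auto")
    u1 = float(res.statistic)
    u_larger = max(u1, g1.size * g2.size - u1)
    q1_1, q3_1 = np.percentile(g1, [25, 75])
    q1_2, q3_2 = np.percentile(g2, [25, 75])
    return GapTestResult(
        U=u_larger,
        p=float(res.pvalue),
        cles=u_larger / (g1.size * g2.size),
        median1=float(np.median(g1)),
        median2=float(np.median(g2)),
        iqr1=(float(q1_1), float(q3_1)),
        iqr2=(float(q1_2), float(q3_2)),
        n1=int(g1.size),
        n2=int(g2.size),
    )
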