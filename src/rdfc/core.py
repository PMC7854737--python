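"""Recursive dynamic functional connectivity (rdFC).

The central computation of the package: a sliding-window Pearson
correlation is applied to a triplet of signals and then re-applied,
recursively, to its own output.  Each recursion depth is an "order" of
dynamic functional connectivity; the full-length Pearson coefficients of
the three series at each order form one 3D point, and the points of all
orders (five by default) form the rdFC pattern.

Pairing convention (fixed throughout the package): for an ordered channel
sequence ``(e1, e2, e3)`` the three pairwise series/coefficients are
assigned as ``x <- corr(e1, e2)``, ``y <- corr(e1, e3)``,
``z <- corr(e2, e3)``, identically at every order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TripletSequence",
    "DfcSeries",
    "RdfcPattern",
    "sliding_correlation",
    "dfc_step",
    "static_summary",
    "compute_pattern",
    "enumerate_permutations",
    "count_static_measures",
    "degenerate_window_count",
    "reset_degenerate_window_count",
    "PAIR_INDICES",
]

# Pair ordering (x, y, z) over channel indices of an ordered sequence.
PAIR_INDICES: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 2))

# Windows (or whole series) with zero variance cannot yield a Pearson
# coefficient; they are assigned 0 and counted here so callers can audit.
_DEGENERATE_WINDOWS = 0

# Rolling sums are recomputed from scratch on this block size to bound
# floating-point drift over long step-1 sweeps.
_BLOCK = 1 << 16


def degenerate_window_count() -> int:
    """Number of zero-variance windows encountered since the last reset."""
    return _DEGENERATE_WINDOWS


def reset_degenerate_window_count() -> None:
    global _DEGENERATE_WINDOWS
    _DEGENERATE_WINDOWS = 0


def _count_degenerate(n: int) -> None:
    global _DEGENERATE_WINDOWS
    _DEGENERATE_WINDOWS += int(n)


@dataclass(frozen=True)
class TripletSequence:
    """An ordered arrangement of a triplet of channel labels.

    ``permutation_id`` indexes the 6 possible arrangements (1-based,
    lexicographic over the canonical input order; id 1 is the identity).
    """

    labels: tuple[str, str, str]
    permutation_id: int = 1

    def __post_init__(self) -> None:
        if len(set(self.labels)) != 3:
            raise ValueError(f"triplet labels must be distinct, got {self.labels}")
        if not 1 <= self.permutation_id <= 6:
            raise ValueError("permutation_id must be in 1..6")


@dataclass
class DfcSeries:
    """One order of dynamic-connectivity time series (3 x length)."""

    order: int
    series: np.ndarray
    window: int
    source_length: int

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] != 3:
            raise ValueError("series must be a 3 x length matrix")
        expected = self.source_length - self.window + 1
        if self.series.shape[1] != expected:
            raise ValueError(
                f"series length {self.series.shape[1]} != "
                f"source_length - window + 1 = {expected}"
            )


@dataclass
class RdfcPattern:
    """A multi-order connectivity pattern: one 3D point per order.

    ``points[i]`` holds the three order-(i+1) static Pearson coefficients
    assigned to (x, y, z) by the package pairing convention.  All entries
    lie in [-1, 1].
    """

    points: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an orders x 3 matrix")
        if np.any(np.abs(self.points) > 1 + 1e-9):
            raise ValueError("pattern coordinates must lie in [-1, 1]")

    @property
    def orders(self) -> int:
        return self.points.shape[0]

    def first_order(self) -> np.ndarray:
        return self.points[0]


def _validate_window(length: int, window: int) -> None:
    if window < 2:
        raise ValueError(f"window must be >= 2 samples, got {window}")
    if window > length:
        raise ValueError(f"window ({window}) exceeds signal length ({length})")


def sliding_correlation(
    a: np.ndarray, b: np.ndarray, window: int, step: int = 1
) -> np.ndarray:
    """Windowed Pearson correlation of two equal-length signals.

    Entry ``t`` is the Pearson coefficient of ``a[t*step : t*step+window]``
    with the matching window of ``b``; output length is
    ``(len - window) // step + 1``.  Zero-variance windows yield 0 and
    increment the module degenerate-window counter.

    Uses blockwise rolling sums (O(N) per pair), recomputed every 2**16
    windows to bound accumulation error; correctness against a direct
    per-window evaluation is part of the test suite.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("signals must have equal length")
    _validate_window(a.size, window)
    if step < 1:
        raise ValueError("step must be >= 1")

    # Per-window Pearson is invariant to a constant offset; removing the
    # global mean keeps the sum-of-products formula well conditioned.
    a = a - a.mean()
    b = b - b.mean()

    n_out = (a.size - window) // step + 1
    out = np.empty(n_out, dtype=float)
    degen = 0
    for blk_start in range(0, n_out, _BLOCK):
        blk = min(_BLOCK, n_out - blk_start)
        s0 = blk_start * step
        s1 = (blk_start + blk - 1) * step + window
        xa = a[s0:s1]
        xb = b[s0:s1]
        ca = np.concatenate(([0.0], np.cumsum(xa)))
        cb = np.concatenate(([0.0], np.cumsum(xb)))
        caa = np.concatenate(([0.0], np.cumsum(xa * xa)))
        cbb = np.concatenate(([0.0], np.cumsum(xb * xb)))
        cab = np.concatenate(([0.0], np.cumsum(xa * xb)))
        idx = np.arange(blk) * step
        sa = ca[idx + window] - ca[idx]
        sb = cb[idx + window] - cb[idx]
        saa = caa[idx + window] - caa[idx]
        sbb = cbb[idx + window] - cbb[idx]
        sab = cab[idx + window] - cab[idx]
        var_a = saa - sa * sa / window
        var_b = sbb - sb * sb / window
        cov = sab - sa * sb / window
        # Relative zero-variance test: catches exactly-constant windows
        # (variance is pure rounding residue) and all-zero windows.
        bad = (var_a <= 1e-12 * saa) | (var_b <= 1e-12 * sbb)
        denom = np.sqrt(np.where(bad, 1.0, var_a * var_b))
        r = np.where(bad, 0.0, cov) / denom
        degen += int(bad.sum())
        out[blk_start : blk_start + blk] = r
    if degen:
        _count_degenerate(degen)
    return np.clip(out, -1.0, 1.0)


def dfc_step(tri: np.ndarray, window: int, step: int = 1) -> DfcSeries:
    """One recursion step: the three pairwise sliding correlations.

    ``tri`` is a 3 x length array (an order-(n-1) series or raw signals);
    rows of the result follow the (x, y, z) pairing convention.
    """
    tri = np.asarray(tri, dtype=float)
    if tri.ndim != 2 or tri.shape[0] != 3:
        raise ValueError("tri must be a 3 x length matrix")
    rows = [sliding_correlation(tri[i], tri[j], window, step) for i, j in PAIR_INDICES]
    return DfcSeries(
        order=0,  # caller overwrites; kept simple for composability
        series=np.vstack(rows),
        window=window,
        source_length=tri.shape[1],
    )


def static_summary(tri: np.ndarray) -> np.ndarray:
    """Full-length Pearson coefficients of the three pairings of ``tri``.

    Constant rows follow the degenerate rule: the affected coefficients
    are 0 and the module counter is incremented.
    """
    tri = np.asarray(tri, dtype=float)
    if tri.ndim != 2 or tri.shape[0] != 3:
        raise ValueError("tri must be a 3 x length matrix")
    if tri.shape[1] < 2:
        raise ValueError("signals must have length >= 2 for a correlation")
    centered = tri - tri.mean(axis=1, keepdims=True)
    ss = np.einsum("it,it->i", centered, centered)
    degenerate_row = ss <= 1e-12 * np.einsum("it,it->i", tri, tri)
    out = np.empty(3, dtype=float)
    degen = 0
    for k, (i, j) in enumerate(PAIR_INDICES):
        if degenerate_row[i] or degenerate_row[j]:
            out[k] = 0.0
            degen += 1
        else:
            out[k] = float(centered[i] @ centered[j] / math.sqrt(ss[i] * ss[j]))
    if degen:
        _count_degenerate(degen)
    return np.clip(out, -1.0, 1.0)


def min_epoch_length(window: int, orders: int) -> int:
    """Shortest signal admitting ``orders`` orders at the given window."""
    return (orders - 1) * (window - 1) + 2


def compute_pattern(
    epoch,
    seq: TripletSequence | Sequence[str],
    window: int | None = None,
    orders: int = 5,
    step: int = 1,
) -> RdfcPattern:
    """Compute the rdFC pattern of a triplet sequence on an epoch.

    Parameters
    ----------
    epoch
        An object with ``samples`` (channels x time), ``rate`` and
        ``labels`` attributes (``EEGEpoch``), or a bare 3 x time array.
    seq
        Ordered channel sequence; fixes the coordinate assignment.
    window
        Window length in samples.  Defaults to ``round(rate)`` (a 1 s
        window), the package-wide analysis window.
    orders
        Number of pattern points; 5 by default.  Row 1 summarizes the raw
        signals, row n (n >= 2) summarizes the order-(n-1) dynamic series.
    """
    if isinstance(seq, TripletSequence):
        labels = seq.labels
        perm_id = seq.permutation_id
    else:
        labels = tuple(seq)
        perm_id = 1
    if hasattr(epoch, "samples"):
        rate = float(epoch.rate)
        missing = [lab for lab in labels if lab not in epoch.labels]
        if missing:
            raise KeyError(f"channels not present in epoch: {missing}")
        idx = [list(epoch.labels).index(lab) for lab in labels]
        tri = np.asarray(epoch.samples, dtype=float)[idx]
        start_time = getattr(epoch, "start_time", 0.0)
    else:
        tri = np.asarray(epoch, dtype=float)
        rate = float(tri.shape[1])  # nominal; only recorded in meta
        start_time = 0.0
    if tri.shape[0] != 3:
        raise ValueError("a triplet requires exactly 3 channels")
    if window is None:
        window = int(round(rate))
    if orders < 1:
        raise ValueError("orders must be >= 1")
    need = min_epoch_length(window, orders)
    if tri.shape[1] < need:
        raise ValueError(
            f"epoch of {tri.shape[1]} samples too short for {orders} orders "
            f"at window {window} (needs >= {need})"
        )

    points = np.empty((orders, 3), dtype=float)
    series = tri
    points[0] = static_summary(series)
    for n in range(2, orders + 1):
        stepres = dfc_step(series, window, step)
        stepres.order = n - 1
        series = stepres.series
        points[n - 1] = static_summary(series)
    return RdfcPattern(
        points=points,
        meta={
            "labels": tuple(labels),
            "permutation_id": perm_id,
            "epoch_start": float(start_time),
            "window": int(window),
            "rate": rate,
            "step": int(step),
        },
    )


def enumerate_permutations(triplet: Sequence[str]) -> list[TripletSequence]:
    """All 6 ordered sequences of an unordered triplet.

    Deterministically indexed: permutation_id 1 is the input order, and
    ids follow lexicographic order of index permutations of the input.
    """
    labels = tuple(triplet)
    if len(labels) != 3 or len(set(labels)) != 3:
        raise ValueError(f"need 3 distinct labels, got {labels}")
    seqs = []
    for k, perm in enumerate(itertools.permutations(range(3)), start=1):
        seqs.append(
            TripletSequence(labels=tuple(labels[i] for i in perm), permutation_id=k)
        )
    return seqs


def induced_pair_permutation(perm: Sequence[int]) -> tuple[int, int, int]:
    """Map a channel permutation to its action on the (x, y, z) pairings.

    ``perm`` gives, for each position of the new sequence, the index into
    the old sequence.  The returned triple ``sigma`` satisfies: coordinate
    k of the permuted sequence equals coordinate ``sigma[k]`` of the
    original, at order 1.  Iterating the map yields the action at higher
    orders (the pair permutation itself becomes the series permutation of
    the next order).
    """
    pair_of = {frozenset(p): k for k, p in enumerate(PAIR_INDICES)}
    return tuple(
        pair_of[frozenset((perm[i], perm[j]))] for i, j in PAIR_INDICES
    )  # type: ignore[return-value]


def pattern_coordinate_permutations(perm: Sequence[int], orders: int = 5) -> list[tuple[int, int, int]]:
    """Per-order coordinate permutations induced by a channel permutation.

    Order 1 uses the pair permutation induced directly by ``perm``; each
    subsequent order applies the induced-pair map to the previous order's
    permutation (the order-n series are themselves indexed by pairs).
    """
    sigmas = []
    sigma = induced_pair_permutation(perm)
    for _ in range(orders):
        sigmas.append(sigma)
        sigma = induced_pair_permutation(sigma)
    return sigmas


def count_static_measures(start_nodes: int, orders: int) -> int:
    """Total static pairwise measures generated by the recursion.

    With k starting nodes the first order computes C(k, 2) measures; each
    later order computes all pairings of the previous order's series,
    so c_{n+1} = C(c_n, 2).  Three starting nodes are the fixed point
    (3 per order); four already explode past 1.49e7 by order five.
    """
    if start_nodes < 2:
        raise ValueError("start_nodes must be >= 2")
    if orders < 1:
        raise ValueError("orders must be >= 1")
    total = 0
    c = math.comb(start_nodes, 2)
    for _ in range(orders):
        total += c
        c = math.comb(c, 2)
        if c == 0:
            break
    return total


def naive_rdfc_pattern(tri: np.ndarray, window: int, orders: int = 5) -> np.ndarray:
    """Reference recursion recomputing every window from scratch.

    Independent of the rolling-sum path; intended for validation on short
    signals only (quadratic in length).
    """
    tri = np.asarray(tri, dtype=float)

    def pearson(x: np.ndarray, y: np.ndarray) -> float:
        xc = x - x.mean()
        yc = y - y.mean()
        vx = float(xc @ xc)
        vy = float(yc @ yc)
        if vx <= 1e-12 * float(x @ x) or vy <= 1e-12 * float(y @ y):
            return 0.0
        return float(xc @ yc) / math.sqrt(vx * vy)

    def summary(mat: np.ndarray) -> np.ndarray:
        return np.array([pearson(mat[i], mat[j]) for i, j in PAIR_INDICES])

    points = np.empty((orders, 3))
    series = tri
    points[0] = summary(series)
    for n in range(1, orders):
        length = series.shape[1] - window + 1
        nxt = np.empty((3, length))
        for t in range(length):
            win = series[:, t : t + window]
            nxt[:, t] = summary(win)
        series = nxt
        points[n] = summary(series)
    return np.clip(points, -1.0, 1.0)
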