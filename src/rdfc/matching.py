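"""Pattern matching: direction-cosine similarity of 5-point patterns.

Two patterns are compared by the shapes of their polylines, not their
size or position: each of the four segments joining consecutive points is
normalized to a unit direction, and the score is the sum of the four dot
products between corresponding directions.  The score ranges from -4
(every segment reversed) to +4 (identical shape) and is invariant to
positive scaling and translation of either pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RdfcPattern

__all__ = [
    "ReferenceSet",
    "MatchResult",
    "segment_directions",
    "match_score",
    "best_match",
    "predict_reference",
    "coordinate_gap",
    "DEFAULT_LOWEST_COORDINATE_MAPPING",
]

# Which reference a pattern is expected to match, keyed by the coordinate
# axis (0=x, 1=y, 2=z) holding the lowest first-order coefficient.  Valid
# relative to the package pairing convention and the reference-set
# construction in `synth.generate_reference_set`.
DEFAULT_LOWEST_COORDINATE_MAPPING: dict[int, int] = {0: 3, 1: 2, 2: 1}


@dataclass
class ReferenceSet:
    """Three reference patterns related by coordinate permutations.

    The three references represent one underlying correlation structure:
    at every order their coordinate multisets coincide and only the
    assignment to (x, y, z) differs.  ``mapping`` records which reference
    the lowest first-order coordinate axis points to (it is meaningful
    only together with the pairing convention used to build the set).
    """

    patterns: list[RdfcPattern]
    provenance: str = ""
    mapping: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LOWEST_COORDINATE_MAPPING)
    )

    def __post_init__(self) -> None:
        if len(self.patterns) != 3:
            raise ValueError("a reference set holds exactly 3 patterns")
        rows = {p.points.shape[0] for p in self.patterns}
        if len(rows) != 1:
            raise ValueError("reference patterns must have identical row counts")

    @property
    def orders(self) -> int:
        return self.patterns[0].points.shape[0]

    def __iter__(self):
        return iter(self.patterns)


@dataclass
class MatchResult:
    """Outcome of matching one pattern against a reference set."""

    scores: np.ndarray  # one score per reference, in reference order
    best_id: int  # 1-based reference index (argmax, lowest-index ties)
    best_score: float
    significant: bool
    exclusive: bool
    threshold: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def segment_directions(p: RdfcPattern | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions of the segments joining consecutive pattern points.

    Returns ``(directions, null_mask)`` with one row per segment.  A
    zero-length segment has no direction: its row is zero and flagged in
    ``null_mask`` so it contributes nothing to a match score.
    """
    pts = p.points if isinstance(p, RdfcPattern) else np.asarray(p, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("pattern needs at least 2 points")
    segs = np.diff(pts, axis=0)
    norms = np.linalg.norm(segs, axis=1)
    null_mask = norms == 0.0
    safe = np.where(null_mask, 1.0, norms)
    dirs = segs / safe[:, None]
    dirs[null_mask] = 0.0
    return dirs, null_mask


def match_score(sample: RdfcPattern | np.ndarray, reference: RdfcPattern | np.ndarray) -> float:
    """Sum of dot products of corresponding unit segment directions.

    Bounded by +/- (number of segments); 4 for 5-point patterns.
    Null-flagged (zero-length) segments on either side contribute 0.
    """
    da, ma = segment_directions(sample)
    db, mb = segment_directions(reference)
    if da.shape != db.shape:
        raise ValueError(
            f"patterns have different segment counts: {da.shape[0]} vs {db.shape[0]}"
        )
    return float(np.einsum("ij,ij->", da, db))


def best_match(
    sample: RdfcPattern,
    refs: ReferenceSet,
    threshold: float,
) -> MatchResult:
    """Match a pattern against all three references.

    The highest of the three scores is the pattern's match score; the
    match is significant when it reaches ``threshold`` and exclusive when
    exactly one reference does.
    """
    scores = np.array([match_score(sample, ref) for ref in refs.patterns])
    best_idx = int(np.argmax(scores))  # argmax takes the lowest index on ties
    above = scores >= threshold
    return MatchResult(
        scores=scores,
        best_id=best_idx + 1,
        best_score=float(scores[best_idx]),
        significant=bool(above.any()),
        exclusive=bool(above.sum() == 1),
        threshold=float(threshold),
    )


def predict_reference(
    sample: RdfcPattern,
    mapping: dict[int, int] | None = None,
) -> tuple[int | None, tuple[int, ...]]:
    """Predict the matching reference from the first-order point alone.

    The axis carrying the lowest first-order coefficient determines the
    reference via ``mapping`` (default: x -> 3, y -> 2, z -> 1).  Returns
    ``(reference_id, candidates)``; on an exact tie of the two lowest
    coordinates the id is None and ``candidates`` lists both references.
    """
    mapping = DEFAULT_LOWEST_COORDINATE_MAPPING if mapping is None else mapping
    first = np.asarray(sample.first_order(), dtype=float)
    order = np.argsort(first, kind="stable")
    if first[order[0]] == first[order[1]]:
        cands = tuple(sorted(mapping[int(ax)] for ax in order[:2]))
        return None, cands
    ax = int(order[0])
    return mapping[ax], (mapping[ax],)


def coordinate_gap(sample: RdfcPattern) -> float:
    """Gap between the two lowest first-order coordinates (nonnegative)."""
    first = np.sort(np.asarray(sample.first_order(), dtype=float))
    return float(first[1] - first[0])
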