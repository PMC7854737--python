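"""Cohort batch analysis, temporal tracking and seizure-linked references.

Triplet sets group electrode triples by mutual separation on the scalp
(near / intermediate / far).  Batch runs score every record x triplet x
permutation; temporal courses track the three reference scores over
consecutive 5-minute epochs; the seizure workflow derives a preictal /
interictal reference pair from an annotated onset and follows the two
scores over the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import RdfcPattern, TripletSequence, compute_pattern, enumerate_permutations
from .matching import ReferenceSet, best_match, match_score
from .preprocess import (
    DEFAULT_EPOCH_DURATION,
    EEGEpoch,
    EEGRecord,
    TripletSet,
    bandpass,
    has_flatline,
    notch,
    rereference,
    select_epoch,
)

__all__ = [
    "AnalysisConfig",
    "TemporalCourse",
    "SeizureReferencePair",
    "MONTAGE_16",
    "MONTAGE_POSITIONS",
    "MIRROR_MAP",
    "triplet_sets_default",
    "preprocess_record",
    "batch_patterns",
    "temporal_course",
    "seizure_references",
    "noise_robustness",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline parameters applied uniformly across a batch."""

    band: tuple[float, float] = (0.5, 70.0)
    notch_freq: float | None = 50.0
    reference: str | None = None  # e.g. "average" or "common:Cz"; None keeps as-is
    epoch_index: int = 2
    epoch_duration: float = DEFAULT_EPOCH_DURATION
    window_sec: float = 1.0
    orders: int = 5


@dataclass
class TemporalCourse:
    """Per-epoch reference scores of one fixed permutation over a record."""

    times: np.ndarray
    scores: np.ndarray  # epochs x references, NaN where the epoch was flat
    triplet: tuple[str, str, str]
    permutation_id: int
    threshold: float
    flat: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"score_ref{i+1}" for i in range(self.scores.shape[1])]
        )
        df.insert(0, "epoch_start_s", self.times)
        df["flat"] = self.flat
        return df


@dataclass
class SeizureReferencePair:
    """Preictal / interictal pattern pair around one seizure onset."""

    preictal: RdfcPattern
    interictal: RdfcPattern
    seizure_onset: float
    interictal_offset: float = 14400.0  # 4 h


# A 16-electrode 10-20 montage (no midline), schematic head coordinates
# (x toward the right ear, y toward the nasion, unit head radius).
MONTAGE_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.309, 0.951), "Fp2": (0.309, 0.951),
    "F7": (-0.809, 0.588), "F3": (-0.40, 0.50),
    "F4": (0.40, 0.50), "F8": (0.809, 0.588),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.809, -0.588), "P3": (-0.40, -0.50),
    "P4": (0.40, -0.50), "T6": (0.809, -0.588),
    "O1": (-0.309, -0.951), "O2": (0.309, -0.951),
}
MONTAGE_16: list[str] = list(MONTAGE_POSITIONS)

MIRROR_MAP: dict[str, str] = {
    "Fp1": "Fp2", "F7": "F8", "F3": "F4", "C3": "C4", "T3": "T4",
    "T5": "T6", "P3": "P4", "O1": "O2",
}
MIRROR_MAP.update({v: k for k, v in list(MIRROR_MAP.items())})

_OUTER_RING = ["Fp1", "Fp2", "F7", "F8", "T3", "T4", "T5", "T6", "O1", "O2"]


def _perimeter(tri: tuple[str, str, str], pos: dict[str, tuple[float, float]]) -> float:
    p = [np.asarray(pos[lab]) for lab in tri]
    return float(
        np.linalg.norm(p[0] - p[1]) + np.linalg.norm(p[0] - p[2]) + np.linalg.norm(p[1] - p[2])
    )


def _area(tri: tuple[str, str, str], pos: dict[str, tuple[float, float]]) -> float:
    a, b, c = (np.asarray(pos[lab]) for lab in tri)
    u, v = b - a, c - a
    return 0.5 * abs(float(u[0] * v[1] - u[1] * v[0]))


def triplet_sets_default(
    montage: Sequence[str] | None = None,
    positions: dict[str, tuple[float, float]] | None = None,
) -> tuple[TripletSet, TripletSet, TripletSet]:
    """Default near / intermediate / far triplet sets (32 / 32 / 10).

    Left-hemisphere triples are ranked by compactness (perimeter on the
    schematic scalp): the 16 tightest form the near set, the next 16 the
    intermediate set; the far set takes the 5 largest-area triples of
    the outer electrode ring.  Each left triple is followed by its
    right-hemisphere mirror image, so consecutive odd/even triplets are
    mirror pairs.  The sets are conventions, not measurements — override
    them from config for any specific electrode layout.
    """
    montage = list(montage) if montage is not None else list(MONTAGE_16)
    positions = positions or MONTAGE_POSITIONS
    missing = [m for m in montage if m not in positions]
    if missing:
        raise ValueError(f"montage positions missing for {missing}")
    left = sorted(
        (lab for lab in montage if positions[lab][0] < 0),
    )
    from itertools import combinations

    left_triples = sorted(
        combinations(left, 3), key=lambda t: (_perimeter(t, positions), t)
    )

    def mirrored(tri: tuple[str, str, str]) -> tuple[str, str, str]:
        return tuple(MIRROR_MAP.get(lab, lab) for lab in tri)  # type: ignore[return-value]

    def interleave(triples: list[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
        out: list[tuple[str, str, str]] = []
        for tri in triples:
            out.append(tri)
            out.append(mirrored(tri))
        return out

    near = interleave(list(left_triples[:16]))
    intermediate = interleave(list(left_triples[16:32]))

    ring = [lab for lab in _OUTER_RING if lab in montage]
    far_left = sorted(
        (t for t in combinations(ring, 3) if np.mean([positions[l][0] for l in t]) < 0),
        key=lambda t: (-_area(t, positions), t),
    )
    far: list[tuple[str, str, str]] = []
    seen: set[frozenset] = set()
    for tri in far_left:
        mir = mirrored(tri)
        if frozenset(tri) in seen or frozenset(mir) in seen:
            continue
        far.extend([tri, mir])
        seen.update([frozenset(tri), frozenset(mir)])
        if len(far) == 10:
            break
    return (
        TripletSet("near", near, "adjacent electrodes"),
        TripletSet("intermediate", intermediate, "two-electrode separation"),
        TripletSet("far", far, "outer-ring electrodes"),
    )


def preprocess_record(record: EEGRecord, config: AnalysisConfig) -> EEGRecord:
    """Apply the configured filtering / re-referencing to a whole record."""
    rec = record
    if config.reference:
        rec = rereference(rec, config.reference)
    low, high = config.band
    if high >= 0.5 * rec.rate:  # keep the band realizable at low rates
        high = 0.45 * rec.rate
        log.warning("band-pass high edge clamped to %.1f Hz for rate %.0f Hz", high, rec.rate)
    rec = bandpass(rec, low, high)
    if config.notch_freq and config.notch_freq < 0.5 * rec.rate:
        rec = notch(rec, config.notch_freq)
    return rec


def batch_patterns(
    records: Iterable[EEGRecord | EEGEpoch],
    sets: Sequence[TripletSet] | TripletSet,
    refs: ReferenceSet,
    threshold: float,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every record x triplet x permutation against the references.

    Records are preprocessed and epoch-selected per ``config``; already
    prepared ``EEGEpoch`` inputs are used as-is.  Per-record failures
    (montage, length, flat epochs) are logged and skipped so a batch
    never aborts.  Returns the full match table and a per-(set, triplet)
    summary with mean scores and match percentages.
    """
    config = config or AnalysisConfig()
    if isinstance(sets, TripletSet):
        sets = [sets]
    window = None  # resolved per epoch from its rate
    rows: list[dict] = []
    for rec_no, rec in enumerate(records):
        try:
            if isinstance(rec, EEGEpoch):
                epoch = rec
            else:
                prepped = preprocess_record(rec, config)
                epoch = select_epoch(
                    prepped, index=config.epoch_index, duration=config.epoch_duration
                )
        except Exception as exc:
            log.warning("record %d skipped: %s", rec_no, exc)
            continue
        w = int(round(config.window_sec * epoch.rate))
        for tset in sets:
            for tri_no, tri in enumerate(tset.triplets, start=1):
                if any(lab not in epoch.labels for lab in tri):
                    log.warning("triplet %s absent from record %d; skipped", tri, rec_no)
                    continue
                for seq in enumerate_permutations(tri):
                    pat = compute_pattern(epoch, seq, window=w, orders=config.orders)
                    res = best_match(pat, refs, threshold)
                    rows.append(
                        {
                            "record": rec_no,
                            "set": tset.name,
                            "triplet_no": tri_no,
                            "triplet": "+".join(tri),
                            "permutation_id": seq.permutation_id,
                            "score_ref1": res.scores[0],
                            "score_ref2": res.scores[1],
                            "score_ref3": res.scores[2],
                            "best_id": res.best_id,
                            "best_score": res.best_score,
                            "significant": res.significant,
                            "exclusive": res.exclusive,
                        }
                    )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, table
    summary = (
        table.groupby(["set", "triplet_no", "triplet"])
        .agg(
            mean_score=("best_score", "mean"),
            std_score=("best_score", "std"),
            match_pct=("significant", lambda s: 100.0 * s.mean()),
            n_patterns=("best_score", "size"),
        )
        .reset_index()
    )
    return table, summary


def temporal_course(
    record: EEGRecord,
    seq: TripletSequence,
    refs: ReferenceSet,
    threshold: float,
    epoch_len: float = DEFAULT_EPOCH_DURATION,
    config: AnalysisConfig | None = None,
) -> TemporalCourse:
    """Reference scores of one fixed permutation over consecutive epochs.

    The record is filtered once, then every disjoint ``epoch_len`` epoch
    is scored against every reference.  Flat epochs are flagged and
    their scores recorded as missing (NaN), never interpolated.
    """
    config = config or AnalysisConfig(epoch_duration=epoch_len)
    n_per = int(round(epoch_len * record.rate))
    n_epochs = record.n_samples // n_per
    if n_epochs < 1:
        raise ValueError("record shorter than one epoch")
    prepped = preprocess_record(record, config)
    w = int(round(config.window_sec * record.rate))
    chan_idx = [record.labels.index(lab) for lab in seq.labels]
    times = np.arange(n_epochs) * epoch_len
    scores = np.full((n_epochs, len(refs.patterns)), np.nan)
    flat = np.zeros(n_epochs, dtype=bool)
    for k in range(n_epochs):
        seg = prepped.samples[chan_idx, k * n_per : (k + 1) * n_per]
        raw_seg = record.samples[chan_idx, k * n_per : (k + 1) * n_per]
        if any(has_flatline(raw_seg[i], record.rate) for i in range(3)):
            flat[k] = True
            continue
        epoch = EEGEpoch(
            samples=seg,
            rate=record.rate,
            labels=list(seq.labels),
            start_time=times[k],
            duration=epoch_len,
        )
        pat = compute_pattern(epoch, seq, window=w, orders=config.orders)
        scores[k] = [match_score(pat, ref) for ref in refs.patterns]
    return TemporalCourse(
        times=times,
        scores=scores,
        triplet=seq.labels,
        permutation_id=seq.permutation_id,
        threshold=threshold,
        flat=flat,
    )


def seizure_references(
    record: EEGRecord,
    seq: TripletSequence,
    onset: float,
    offset: float = 14400.0,
    epoch_len: float = DEFAULT_EPOCH_DURATION,
    config: AnalysisConfig | None = None,
) -> SeizureReferencePair:
    """Derive a preictal / interictal reference pair around one seizure.

    The preictal pattern comes from the epoch ending at ``onset``; the
    interictal pattern from the epoch starting ``offset`` seconds (4 h by
    default) before onset.  Insufficient interictal history raises a
    coverage error reporting the largest achievable offset.
    """
    config = config or AnalysisConfig(epoch_duration=epoch_len)
    if onset - offset < 0:
        raise ValueError(
            f"record history before onset ({onset:.0f}s) shorter than the requested "
            f"interictal offset ({offset:.0f}s); maximal achievable offset is "
            f"{max(onset - epoch_len, 0):.0f}s"
        )
    if onset > record.duration:
        raise ValueError("seizure onset beyond the end of the record")
    prepped = preprocess_record(record, config)
    w = int(round(config.window_sec * record.rate))
    chan_idx = [record.labels.index(lab) for lab in seq.labels]

    def cut(start: float) -> EEGEpoch:
        i0 = int(round(start * record.rate))
        i1 = i0 + int(round(epoch_len * record.rate))
        return EEGEpoch(
            samples=prepped.samples[chan_idx, i0:i1],
            rate=record.rate,
            labels=list(seq.labels),
            start_time=start,
            duration=epoch_len,
        )

    pre = compute_pattern(cut(onset - epoch_len), seq, window=w, orders=config.orders)
    inter = compute_pattern(cut(onset - offset), seq, window=w, orders=config.orders)
    return SeizureReferencePair(
        preictal=pre, interictal=inter, seizure_onset=onset, interictal_offset=offset
    )


def burst_schedule(
    n_samples: int, rate: float, burst_duration: float = 2.0, burst_interval: float = 30.0
) -> list[tuple[int, int]]:
    """Sample index ranges of the periodic noise bursts (2 s every 30 s)."""
    burst_n = int(round(burst_duration * rate))
    starts = [
        int(round(k * burst_interval * rate))
        for k in range(int(np.ceil(n_samples / (burst_interval * rate))))
    ]
    return [(s, s + burst_n) for s in starts if s + burst_n <= n_samples]


def inject_noise_bursts(
    samples: np.ndarray,
    rate: float,
    relative_power: float,
    seed: int = 0,
    burst_duration: float = 2.0,
    burst_interval: float = 30.0,
) -> np.ndarray:
    """Copy of ``samples`` with white Gaussian bursts added periodically.

    Burst variance is ``relative_power`` times the mean power of
    ``samples``; samples outside the burst windows are untouched.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    out = samples.copy()
    if relative_power <= 0:
        return out
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(relative_power * np.mean(samples**2)))
    for i0, i1 in burst_schedule(samples.shape[1], rate, burst_duration, burst_interval):
        out[:, i0:i1] += sd * rng.standard_normal((samples.shape[0], i1 - i0))
    return out


def noise_robustness(
    epoch: EEGEpoch,
    seq: TripletSequence,
    ref: RdfcPattern,
    noise_powers: Sequence[float],
    seed: int = 0,
    burst_duration: float = 2.0,
    burst_interval: float = 30.0,
    window: int | None = None,
    orders: int = 5,
) -> pd.DataFrame:
    """Match score under periodic artefact-like noise bursts.

    White Gaussian bursts of ``burst_duration`` seconds are injected
    every ``burst_interval`` seconds; ``noise_powers`` are burst powers
    relative to the epoch's mean channel power (1.0 means noise power
    equal to signal power).  One burst realization is drawn and rescaled
    across power levels (common random numbers), so the score-vs-power
    curve is a paired comparison.  Returns a score-vs-power table; a
    zero entry reproduces the clean score exactly.
    """
    rng = np.random.default_rng(seed)
    chan_idx = [epoch.labels.index(lab) for lab in seq.labels]
    base = np.asarray(epoch.samples, dtype=float)[chan_idx]
    sig_power = float(np.mean(base**2))
    schedule = burst_schedule(base.shape[1], epoch.rate, burst_duration, burst_interval)
    bursts = rng.standard_normal((len(schedule), 3, schedule[0][1] - schedule[0][0]))
    rows = []
    for power in noise_powers:
        noisy = base.copy()
        if power > 0:
            sd = float(np.sqrt(power * sig_power))
            for (i0, i1), burst in zip(schedule, bursts):
                noisy[:, i0:i1] += sd * burst
        ep = EEGEpoch(
            samples=noisy,
            rate=epoch.rate,
            labels=list(seq.labels),
            start_time=epoch.start_time,
            duration=epoch.duration,
        )
        pat = compute_pattern(ep, seq, window=window, orders=orders)
        rows.append({"relative_noise_power": power, "match_score": match_score(pat, ref)})
    return pd.DataFrame(rows)
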