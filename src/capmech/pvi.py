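"""Plaque vulnerability indices (PVIs): scoring, calibration, outcomes.

Five ordinal indices grade a slice from 1 (least vulnerable) to 4 (most
vulnerable).  The cap-thickness index (C) is the reference: thin fibrous
caps are the classic vulnerability marker, so *lower* values map to
*higher* categories.  Four mechanical indices (MaxS, MeanS, MaxSn, MeanSn)
grade peak/mean cap stress (kPa) and strain; there *higher* values are more
vulnerable.  Intervals are right-closed as printed in the source threshold
table, e.g. for C: (0.36, 2) -> 1, (0.26, 0.36] -> 2, (0.20, 0.26] -> 3,
(0.0, 0.20] -> 4.

Stress/strain cut points can be re-derived from data: the calibrator
searches all ordered cut triples (midpoints of consecutive sorted unique
values) for the best exact-agreement rate with the C-PVI labels.

Outcome of a matched pair: delta = followup - baseline category, binarized
to +1 (progression toward vulnerability) when delta > 0, else -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PviThresholds",
    "PviRecord",
    "DEFAULT_THRESHOLDS",
    "score_pvi",
    "calibrate_thresholds",
    "delta_binary",
]

INDEX_NAMES = ("C", "MaxS", "MeanS", "MaxSn", "MeanSn")
C_UPPER_SANITY = 2.0  # mm; thicker caps are scored 1 with a warning


@dataclass(frozen=True)
class PviThresholds:
    """Three ascending cuts plus vulnerability orientation for one index."""

    index_name: str
    cuts: tuple[float, float, float]
    match_rate: float | None = None  # filled by the calibrator

    def __post_init__(self):
        if self.index_name not in INDEX_NAMES:
            raise ValueError(f"unknown index {self.index_name!r}")
        if not (self.cuts[0] < self.cuts[1] < self.cuts[2]):
            raise ValueError("cuts must be strictly ascending")

    @property
    def orientation(self) -> str:
        return "lower_is_vulnerable" if self.index_name == "C" else "higher_is_vulnerable"


DEFAULT_THRESHOLDS: dict[str, PviThresholds] = {
    "C": PviThresholds("C", (0.20, 0.26, 0.36)),  # mm
    "MaxS": PviThresholds("MaxS", (80.0, 101.0, 110.0)),  # kPa
    "MeanS": PviThresholds("MeanS", (70.0, 88.0, 93.0)),  # kPa
    "MaxSn": PviThresholds("MaxSn", (0.17, 0.18, 0.20)),
    "MeanSn": PviThresholds("MeanSn", (0.18, 0.20, 0.21)),
}


def score_pvi(value: float, thresholds: PviThresholds) -> int:
    """Score one measurement into category 1-4 (4 = most vulnerable).

    Intervals are right-closed: a cap thickness of exactly 0.36 mm falls in
    (0.26, 0.36] and scores C-PVI 2.
    """
    if not np.isfinite(value):
        raise ValueError("non-finite measurement")
    c1, c2, c3 = thresholds.cuts
    if thresholds.orientation == "lower_is_vulnerable":
        if value <= 0:
            raise ValueError("cap thickness must be positive")
        if value >= C_UPPER_SANITY:
            warnings.warn(
                f"cap thickness {value:.3g} mm above sanity bound "
                f"{C_UPPER_SANITY} mm; scored 1",
                stacklevel=2,
            )
            return 1
        if value > c3:
            return 1
        if value > c2:
            return 2
        if value > c1:
            return 3
        return 4
    # higher_is_vulnerable: (.., c1] -> 1, (c1, c2] -> 2, (c2, c3] -> 3, > c3 -> 4
    if value <= c1:
        return 1
    if value <= c2:
        return 2
    if value <= c3:
        return 3
    return 4


def _label_prefix_counts(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Prefix label counts along the sorted value order, for fast cut search."""
    lab = labels[np.argsort(values, kind="stable")]
    prefix = np.zeros((5, len(lab) + 1), dtype=int)
    for cat in range(1, 5):
        prefix[cat, 1:] = np.cumsum(lab == cat)
    return prefix


def calibrate_thresholds(
    values, c_pvi_labels, index_name: str = "MaxS"
) -> PviThresholds:
    """Find the cut triple best matching the cap-based categories.

    Candidate cuts are midpoints of consecutive sorted unique values; every
    ordered triple is scored by exact agreement with ``c_pvi_labels``.
    Ties prefer (a) larger minimum category occupancy, then (b) the
    lexicographically smallest cut vector.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(c_pvi_labels, dtype=int)
    if len(values) < 4:
        raise ValueError("need at least 4 slices")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct C-PVI categories")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("all measurements identical; cannot calibrate")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    reverse = index_name == "C"  # thin caps are the vulnerable end
    n = len(values)
    # position of each midpoint in the sorted value order
    svals = np.sort(values)
    pos = np.searchsorted(svals, mids)  # values below cut
    prefix = _label_prefix_counts(values, labels)

    cats = (4, 3, 2, 1) if reverse else (1, 2, 3, 4)
    m = len(mids)
    best = None
    # matches(i,j,k) = P[cat1][i] + (P[cat2][j]-P[cat2][i]) + ... computed
    # with broadcasting over the ordered triples
    p1 = prefix[cats[0]][pos]
    for a in range(m - 2):
        j = np.arange(a + 1, m - 1)
        p2 = prefix[cats[1]][pos[j]] - prefix[cats[1]][pos[a]]
        for jj, b in enumerate(j):
            kk = np.arange(b + 1, m)
            p3 = prefix[cats[2]][pos[kk]] - prefix[cats[2]][pos[b]]
            p4 = prefix[cats[3]][n] - prefix[cats[3]][pos[kk]]
            total = p1[a] + p2[jj] + p3 + p4
            occ_counts = np.stack(
                [
                    np.full_like(kk, pos[a]),
                    np.full_like(kk, pos[b] - pos[a]),
                    pos[kk] - pos[b],
                    n - pos[kk],
                ]
            )
            min_occ = occ_counts.min(axis=0)
            # best k in this (a, b) row: max matches, then max occupancy,
            # then smallest cut (first index, since mids ascend)
            cand = total == total.max()
            occ = np.where(cand, min_occ, -1)
            t = int(np.argmax(occ == occ.max()))
            key = (
                int(total[t]),
                int(min_occ[t]),
                (-mids[a], -mids[b], -mids[kk[t]]),
            )
            if best is None or key > best[0]:
                best = (key, (float(mids[a]), float(mids[b]), float(mids[kk[t]])))
    assert best is not None
    cuts = best[1]
    rate = best[0][0] / n
    return PviThresholds(index_name, cuts, match_rate=rate)


@dataclass(frozen=True)
class PviRecord:
    """Categories and outcome of one matched baseline/follow-up slice pair."""

    slice_id: str
    index_name: str
    baseline: int
    followup: int

    def __post_init__(self):
        for v in (self.baseline, self.followup):
            if v not in (1, 2, 3, 4):
                raise ValueError("PVI categories are 1..4")

    @property
    def delta(self) -> int:
        return self.followup - self.baseline

    @property
    def binary(self) -> int:
        return 1 if self.delta > 0 else -1


def delta_binary(baseline: int, followup: int) -> tuple[int, int]:
    """(delta, binary outcome) of a matched pair; +1 iff the category rose."""
    rec = PviRecord("_", "C", baseline, followup)
    return rec.delta, rec.binary
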