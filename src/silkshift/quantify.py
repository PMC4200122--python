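"""Library-size normalization and silk-gland-specific transcript (SST) calling.

Expected counts per transcript per library (silk, venom, cephalothorax) are
normalized to eCPM (expected counts per million aligned reads).  A transcript
is silk-specific when it is either expressed exclusively in silk glands
(>1 eCPM in silk, 0 in both other tissues) or its silk:venom AND
silk:cephalothorax eCPM fold changes both fall in the extreme upper tail of
the observed fold-change distributions (strict tail 0.5%; an extended 2.5%
tail admits further candidates for gene-family analyses).

Fold-change thresholds are order statistics of the dataset at hand, never
fixed constants: the cutoffs reported for any particular study are
data-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

LIBRARIES = ("silk", "venom", "cephalothorax")

# specificity classes
BELOW_FLOOR = "below-floor"
EXCLUSIVE = "exclusive"
FOLD_SST = "fold-SST"
EXTENDED_SST = "extended-SST"
NON_SST = "non-SST"
CLASSES = (BELOW_FLOOR, EXCLUSIVE, FOLD_SST, EXTENDED_SST, NON_SST)

#: classes counted as silk-specific at the strict tail
SST_CLASSES = frozenset({EXCLUSIVE, FOLD_SST})
#: classes counted as silk-specific at the extended tail
EXTENDED_SET = frozenset({EXCLUSIVE, FOLD_SST, EXTENDED_SST})


@dataclass
class ExpressionMatrix:
    """Expected counts, transcripts x libraries, with transcript lengths in nt."""

    counts: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("expected counts must be non-negative")
        missing = [c for c in LIBRARIES if c not in self.counts.columns]
        if missing:
            raise ValueError(f"missing libraries: {missing}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if (self.lengths < 1).any():
                raise ValueError("transcript lengths must be >= 1")


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    unit: str  # "eCPM" or "FPKM"


def compute_ecpm(m: ExpressionMatrix) -> NormalizedMatrix:
    """eCPM: count / per-library total expected counts x 1e6."""
    totals = m.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"library with all-zero counts: {list(zero.index)}")
    return NormalizedMatrix(values=m.counts / totals * 1e6, unit="eCPM")


def compute_fpkm(m: ExpressionMatrix) -> NormalizedMatrix:
    """FPKM: count / (length in kb) / (per-library total in millions)."""
    if m.lengths is None:
        raise ValueError("FPKM requires transcript lengths")
    if (m.lengths <= 0).any():
        raise ValueError("zero or negative transcript length")
    totals = m.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"library with all-zero counts: {list(zero.index)}")
    per_kb = m.counts.div(m.lengths / 1e3, axis=0)
    return NormalizedMatrix(values=per_kb / (totals / 1e6), unit="FPKM")


def expression_floor(norm: NormalizedMatrix, floor: float = 1.0) -> pd.Index:
    """Transcripts retained by the floor filter: eCPM >= floor in at least one library.

    Equivalently, a transcript is dropped only when it is below the floor in
    every library ("less than one" is strict).
    """
    if norm.unit != "eCPM":
        raise ValueError("expression floor is defined on eCPM")
    below_everywhere = (norm.values[list(LIBRARIES)] < floor).all(axis=1)
    return norm.values.index[~below_everywhere]


def fold_changes(norm: NormalizedMatrix, focal: str = "silk") -> pd.DataFrame:
    """Per-transcript focal:other eCPM ratios.

    Zero denominators with a positive numerator give +inf; 0/0 gives 0.
    Returns columns ``ratio_vs_venom`` and ``ratio_vs_ceph``.
    """
    others = [lib for lib in LIBRARIES if lib != focal]
    out = {}
    focal_vals = norm.values[focal].to_numpy(float)
    for lib, col in zip(others, ("ratio_vs_venom", "ratio_vs_ceph")):
        denom = norm.values[lib].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                denom > 0, focal_vals / np.where(denom > 0, denom, 1.0),
                np.where(focal_vals > 0, np.inf, 0.0),
            )
        out[col] = ratio
    return pd.DataFrame(out, index=norm.values.index)


def quantile_threshold(values, tail: float) -> float:
    """Nearest-rank upper-tail cutoff; a value qualifies iff strictly greater.

    The cutoff is the order statistic of rank ``ceil((1 - tail) * n)``
    (1-based, ascending; +inf sorts last).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("quantile_threshold needs at least one value")
    if not 0.0 < tail < 1.0:
        raise ValueError("tail must be in (0, 1)")
    arr = np.sort(arr)  # NaN-free input assumed; +inf sorts last
    rank = math.ceil((1.0 - tail) * arr.size)
    rank = min(max(rank, 1), arr.size)
    return float(arr[rank - 1])


@dataclass
class SpecificityThresholds:
    tail: float
    cutoff_vs_venom: float
    cutoff_vs_ceph: float


def call_ssts(
    norm: NormalizedMatrix,
    tail_strict: float = 0.005,
    tail_extended: float = 0.025,
    floor: float = 1.0,
) -> tuple[pd.DataFrame, SpecificityThresholds, SpecificityThresholds]:
    """Classify every transcript by silk specificity.

    Classes partition the input:

    - ``below-floor``: eCPM < floor in all libraries;
    - ``exclusive``: silk eCPM > 1 and 0 eCPM in venom and cephalothorax;
    - ``fold-SST``: both fold changes strictly exceed the strict-tail cutoffs;
    - ``extended-SST``: both exceed the extended-tail cutoffs but not both
      strict ones (and not exclusive);
    - ``non-SST``: everything else above the floor.

    Thresholds are nearest-rank order statistics over all floor-passing
    transcripts, computed separately for each contrast; +inf ratios (silk-only
    expression) always qualify.
    """
    if norm.unit != "eCPM":
        raise ValueError("call_ssts requires eCPM")
    if "silk" not in norm.values.columns:
        raise ValueError("missing silk library")
    if tail_extended < tail_strict:
        raise ValueError("extended tail must be >= strict tail")

    retained = expression_floor(norm, floor=floor)
    ratios = fold_changes(norm).loc[retained]

    thr_strict = SpecificityThresholds(
        tail=tail_strict,
        cutoff_vs_venom=quantile_threshold(ratios["ratio_vs_venom"], tail_strict),
        cutoff_vs_ceph=quantile_threshold(ratios["ratio_vs_ceph"], tail_strict),
    )
    thr_ext = SpecificityThresholds(
        tail=tail_extended,
        cutoff_vs_venom=quantile_threshold(ratios["ratio_vs_venom"], tail_extended),
        cutoff_vs_ceph=quantile_threshold(ratios["ratio_vs_ceph"], tail_extended),
    )

    vals = norm.values
    classes = pd.Series(NON_SST, index=vals.index, dtype=object)
    classes.loc[~vals.index.isin(retained)] = BELOW_FLOOR

    exclusive = (
        (vals["silk"] > 1.0) & (vals["venom"] == 0.0) & (vals["cephalothorax"] == 0.0)
    )
    def _qualifies(col: str, cutoff: float) -> pd.Series:
        # +inf ratios (silk-only expression) always qualify, even when the
        # cutoff itself is +inf
        return (ratios[col] > cutoff) | np.isinf(ratios[col])

    strict_q = _qualifies("ratio_vs_venom", thr_strict.cutoff_vs_venom) & _qualifies(
        "ratio_vs_ceph", thr_strict.cutoff_vs_ceph
    )
    ext_q = _qualifies("ratio_vs_venom", thr_ext.cutoff_vs_venom) & _qualifies(
        "ratio_vs_ceph", thr_ext.cutoff_vs_ceph
    )

    retained_mask = vals.index.isin(retained)
    excl_idx = vals.index[retained_mask & exclusive.reindex(vals.index, fill_value=False)]
    classes.loc[excl_idx] = EXCLUSIVE
    fold_idx = ratios.index[strict_q & ~classes.loc[ratios.index].eq(EXCLUSIVE)]
    classes.loc[fold_idx] = FOLD_SST
    ext_idx = ratios.index[
        ext_q & ~strict_q & ~classes.loc[ratios.index].isin([EXCLUSIVE, FOLD_SST])
    ]
    classes.loc[ext_idx] = EXTENDED_SST

    calls = pd.DataFrame(
        {
            "class": classes,
            "ratio_vs_venom": fold_changes(norm)["ratio_vs_venom"],
            "ratio_vs_ceph": fold_changes(norm)["ratio_vs_ceph"],
        },
        index=vals.index,
    )
    return calls, thr_strict, thr_ext
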