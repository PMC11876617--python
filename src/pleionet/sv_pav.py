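"""Structural-variant presence/absence from binned read depth.

A target region is split into equal-width bins; each line's per-bin read
count is converted to the ratio of the bin count over the line's total
reads in the region.  Lines lacking the region show depleted ratios (or
negligible totals); calls are present / absent / ambiguous.  Trait
differences between PAV groups are tested with a one-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionBins",
    "bin_region",
    "bin_ratios",
    "PAVCaller",
    "call_pav",
    "pav_group_test",
]


@dataclass
class RegionBins:
    chrom: str
    start: int  # 1-based inclusive as printed
    end: int
    bins: list[tuple[int, int]]  # 1-based inclusive per-bin intervals
    widths: list[int]
    remainder: bool  # last bin absorbed an integer-division remainder

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def bin_region(start: int, end: int, n_bins: int = 5, chrom: str = "1") -> RegionBins:
    """Split a 1-based inclusive printed interval into equal bins.

    The region length is computed end-exclusive (end - start), the
    convention that makes chr1:286721317-286726162 five 969-bp bins; any
    integer-division remainder goes to the last bin and is flagged.
    """
    length = end - start
    if length <= 0:
        raise ValueError("region length must be positive")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    width = length // n_bins
    if width < 1:
        raise ValueError("more bins than base pairs")
    remainder = length - width * n_bins
    bins, widths = [], []
    lo = start
    for b in range(n_bins):
        w = width + (remainder if b == n_bins - 1 else 0)
        bins.append((lo, lo + w - 1))
        widths.append(w)
        lo += w
    return RegionBins(
        chrom=chrom, start=start, end=end, bins=bins, widths=widths,
        remainder=remainder > 0,
    )


def bin_ratios(depth_row: np.ndarray | pd.Series) -> np.ndarray:
    """Per-bin read share of the region total; NaN when the total is zero."""
    counts = np.asarray(depth_row, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative read counts")
    total = counts.sum()
    if total == 0:
        return np.full(counts.shape, np.nan)
    return counts / total


class PAVCaller:
    """Rule-based presence/absence calls from binned read-depth ratios.

    A bin is depleted when its ratio falls below depletion_factor times
    the uniform share 1/n_bins.  A line is called absent when at least
    ceil(n_bins / 2) bins are depleted, present when at most one is, and
    ambiguous otherwise.  A line whose region total falls below
    ``min_total`` is called absent outright: when the variant spans the
    whole binned region, a uniformly negligible read total -- not a skewed
    ratio profile -- is the absence signal, and ratios on a handful of
    mismapped reads carry no information.  ``min_total`` should scale with
    the expected carrier coverage (half the expected per-bin carrier depth
    is a reasonable floor).  Above the floor, calls depend only on ratios,
    so scaling a line's counts leaves them unchanged.
    """

    def __init__(self, depletion_factor: float = 0.5, min_total: int = 20):
        self.depletion_factor = depletion_factor
        self.min_total = min_total

    def get_params(self, deep: bool = True) -> dict:
        return {"depletion_factor": self.depletion_factor, "min_total": self.min_total}

    def set_params(self, **params) -> "PAVCaller":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def predict(self, depth: pd.DataFrame) -> pd.DataFrame:
        """Call each line of a per-bin count table (bin columns only)."""
        bin_cols = [c for c in depth.columns if c != "total"]
        n_bins = len(bin_cols)
        cutoff = self.depletion_factor / n_bins
        need_absent = int(np.ceil(n_bins / 2))
        rows = []
        for line, rec in depth[bin_cols].iterrows():
            counts = rec.to_numpy(dtype=float)
            total = counts.sum()
            ratios = bin_ratios(counts)
            depleted = int(np.sum(ratios < cutoff)) if total > 0 else n_bins
            if total < self.min_total:
                call = "absent"
            elif depleted >= need_absent:
                call = "absent"
            elif depleted <= 1:
                call = "present"
            else:
                call = "ambiguous"
            rows.append([line, total, depleted, call, *ratios.tolist()])
        return pd.DataFrame(
            rows,
            columns=["line", "total", "depleted_bins", "call", *[f"ratio_{c}" for c in bin_cols]],
        ).set_index("line")


def call_pav(
    depth: pd.DataFrame, depletion_factor: float = 0.5, min_total: int = 20
) -> pd.DataFrame:
    """Functional wrapper over :class:`PAVCaller`."""
    return PAVCaller(depletion_factor=depletion_factor, min_total=min_total).predict(depth)


def pav_group_test(
    trait_values: pd.Series,
    pav_calls: pd.Series,
    direction: str = "absent_greater",
) -> dict:
    """One-sided Wilcoxon rank-sum test of trait by PAV group.

    ``direction`` names the alternative: 'absent_greater' tests whether
    lines lacking the region show larger trait values.  Ambiguous calls
    are excluded; exact p for small groups, normal approximation with
    continuity correction otherwise (scipy's default policy).
    """
    calls = pav_calls.reindex(trait_values.index)
    present = trait_values[calls == "present"].dropna()
    absent = trait_values[calls == "absent"].dropna()
    if len(present) < 2 or len(absent) < 2:
        raise ValueError("need >= 2 lines per PAV group")
    alternative = {"absent_greater": "greater", "present_greater": "less"}.get(direction)
    if alternative is None:
        raise ValueError("direction must be 'absent_greater' or 'present_greater'")
    res = stats.mannwhitneyu(absent, present, alternative=alternative)
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "n_absent": len(absent),
        "n_present": len(present),
        "direction": direction,
    }
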