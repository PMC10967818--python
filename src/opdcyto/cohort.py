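"""Cohort-level analysis: gating, H-cell fractions and group tests.

Per-sample cell feature tables are first gated on perimeter (cells outside
the 5th-95th percentile band of a *reference* perimeter distribution — the
sorted-cell table — are excluded as probable non-neutrophils), each cell is
classified H or L, and the pooled per-group H fractions are compared with a
two-sided two-proportion z test. Per-feature group differences use the
two-sample t test (Welch by default). Significance level alpha = 0.05; no
multiple-testing correction is applied (single planned comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from opdcyto.classify import LogisticModel, ThresholdModel, features_to_frame


@dataclass
class CohortSample:
    """One donor's gated cell table."""

    sample_id: str
    group: str  # "BBD" or "MDS"
    cells: pd.DataFrame
    n_before_gate: int
    n_after_gate: int

    def __post_init__(self) -> None:
        if self.n_after_gate > self.n_before_gate:
            raise ValueError("gating cannot add cells")


@dataclass
class GroupComparison:
    """Result of a two-group H-fraction comparison."""

    per_sample: pd.DataFrame  # sample_id, group, n, n_h, h_fraction
    group_counts: dict  # group -> (n_h, n)
    group_fractions: dict  # group -> pooled H fraction
    statistic: float
    test_name: str
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def perimeter_gate(
    cells,
    reference_perimeters: Sequence[float],
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> pd.DataFrame:
    """Keep cells whose perimeter lies inside the reference percentile band.

    Percentiles use linear interpolation between order statistics; bounds
    are inclusive, so a degenerate single-value reference keeps cells at
    exactly that value.
    """
    ref = np.asarray(reference_perimeters, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference perimeter list")
    lo, hi = np.percentile(ref, [lo_pct, hi_pct], method="linear")
    df = features_to_frame(cells)
    keep = (df["perimeter_um"] >= lo) & (df["perimeter_um"] <= hi)
    return df.loc[keep].reset_index(drop=True)


def h_fraction(cells, model: ThresholdModel | LogisticModel) -> tuple[float, int, int]:
    """Fraction of cells classified H; returns (fraction, n_h, n)."""
    df = features_to_frame(cells)
    if len(df) == 0:
        raise ValueError("empty cell list")
    pred = model.predict(df)
    n_h = int((pred == "H").sum())
    return n_h / len(df), n_h, len(df)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], pooled: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t test (Welch by default, pooled optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.array_equal(np.sort(a), np.sort(b)) or a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-sample independent proportions z test (pooled variance).

    ``z = (p1 - p2) / sqrt(p*(1-p)*(1/n1 + 1/n2))`` with ``p`` the pooled
    proportion; p-value from the standard normal.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError(f"invalid counts x={x}, n={n}")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0  # both arms all-failures or all-successes
    z = (p1 - p2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def make_cohort_sample(
    sample_id: str,
    group: str,
    cells,
    reference_perimeters: Sequence[float],
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> CohortSample:
    """Gate one donor's cells against the reference perimeter band."""
    df = features_to_frame(cells)
    gated = perimeter_gate(df, reference_perimeters, lo_pct, hi_pct)
    return CohortSample(sample_id, group, gated, len(df), len(gated))


def compare_groups(
    samples: Sequence[CohortSample],
    model: ThresholdModel | LogisticModel,
    alpha: float = 0.05,
) -> GroupComparison:
    """Classify gated cells and compare pooled per-group H fractions.

    Pooled counts across a group's samples feed the two-proportion z test
    (the pooled fraction equals the cell-count-weighted mean of per-sample
    fractions); per-sample fractions are reported for transparency.
    """
    groups = sorted({s.group for s in samples})
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    rows = []
    counts = {g: [0, 0] for g in groups}
    for s in samples:
        frac, n_h, n = h_fraction(s.cells, model)
        rows.append({"sample_id": s.sample_id, "group": s.group,
                     "n": n, "n_h": n_h, "h_fraction": frac})
        counts[s.group][0] += n_h
        counts[s.group][1] += n
    g1, g2 = groups
    z, p = two_proportion_test(counts[g1][0], counts[g1][1],
                               counts[g2][0], counts[g2][1])
    return GroupComparison(
        per_sample=pd.DataFrame(rows),
        group_counts={g: tuple(c) for g, c in counts.items()},
        group_fractions={g: c[0] / c[1] for g, c in counts.items()},
        statistic=z,
        test_name="two_proportion",
        p_value=p,
        alpha=alpha,
    )
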