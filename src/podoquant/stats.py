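"""Numerical post-processing: group tests, qPCR ratios, stretch-membrane
strain geometry, volcano-threshold filtering, and intensity summaries.

Group comparison follows the conventions of the underlying experiments:
two groups are compared by a two-sided unpaired t test (pooled variance
by default, Welch optional); more than two groups by one-way ANOVA
followed by all pairwise t tests with Benjamini–Hochberg adjustment
across the pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "MembraneGeometry",
    "compare_groups",
    "bh_adjust",
    "pfaffl_ratio",
    "membrane_strain",
    "strain_from_area",
    "area_from_strain",
    "volcano_filter",
    "mean_intensity_in_mask",
]


@dataclass
class GroupComparison:
    """Summary statistics and test results for a set of sample groups."""

    labels: list[str]
    n: list[int]
    means: list[float]
    sd: list[float]
    sem: list[float]
    test: str
    statistic: float | None = None       # t (two groups) or ANOVA F
    p: float | None = None               # t-test p or ANOVA p
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class MembraneGeometry:
    """Spherical-cap geometry of a center-deflected circular membrane."""

    cap_height_mm: float
    membrane_radius_mm: float
    area_increase: float  # ΔA/A
    linear_strain: float  # √(1+ΔA/A) − 1


def _ttest(a, b, welch: bool) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    welch: bool = False,
) -> GroupComparison:
    """Two groups: unpaired two-sided t test.  More: ANOVA + BH pairwise.

    Every group needs n ≥ 2 and finite values.  For multi-group designs
    the ANOVA F and p are reported, followed by all pairwise unpaired
    t tests with Benjamini–Hochberg adjustment across the pairs.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(samples))]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lab!r} has n < 2")
        if not np.all(np.isfinite(s)):
            raise ValueError(f"group {lab!r} contains non-finite values")

    ns = [len(s) for s in samples]
    means = [float(np.mean(s)) for s in samples]
    sds = [float(np.std(s, ddof=1)) for s in samples]
    sems = [sd / np.sqrt(n) for sd, n in zip(sds, ns)]

    if len(samples) == 2:
        t, p = _ttest(samples[0], samples[1], welch)
        return GroupComparison(labels=labels, n=ns, means=means, sd=sds,
                               sem=sems, test="welch t" if welch else "student t",
                               statistic=t, p=p)

    f, p_anova = sps.f_oneway(*samples)
    rows = []
    for (i, j) in combinations(range(len(samples)), 2):
        t, p = _ttest(samples[i], samples[j], welch)
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "t": t, "p": p})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = bh_adjust(pw["p"].to_numpy())
    return GroupComparison(labels=labels, n=ns, means=means, sd=sds, sem=sems,
                           test="anova + pairwise t (BH)",
                           statistic=float(f), p=float(p_anova), pairwise=pw)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pfaffl_ratio(
    e_target: float, dct_target: float,
    e_ref: float, dct_ref: float,
) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = E_target^ΔCt(target) / E_ref^ΔCt(ref), with
    ΔCt = Ct(control) − Ct(sample) and amplification efficiencies E in
    [1, 2.2] (2 = perfect doubling per cycle).
    """
    for name, e in (("target", e_target), ("reference", e_ref)):
        if not (1.0 <= e <= 2.2):
            raise ValueError(f"{name} efficiency {e} outside [1, 2.2]")
    return float(e_target ** dct_target / e_ref ** dct_ref)


def strain_from_area(area_increase: float) -> float:
    """Mean linear strain from a relative membrane-area increase ΔA/A."""
    if area_increase < 0:
        raise ValueError("area increase must be >= 0")
    return float(np.sqrt(1.0 + area_increase) - 1.0)


def area_from_strain(strain: float) -> float:
    """Relative area increase ΔA/A from a mean linear strain."""
    if strain < 0:
        raise ValueError("strain must be >= 0")
    return float((1.0 + strain) ** 2 - 1.0)


def membrane_strain(cap_height_mm: float, membrane_radius_mm: float) -> MembraneGeometry:
    """Spherical-cap stretch geometry of a circular elastic membrane.

    A membrane of radius a deflected at its center by height h bulges
    into a spherical cap whose relative area increase is (h/a)²; the
    corresponding mean linear strain is √(1 + ΔA/A) − 1.
    """
    if membrane_radius_mm <= 0:
        raise ValueError("membrane radius must be > 0")
    if cap_height_mm < 0:
        raise ValueError("cap height must be >= 0")
    da = (cap_height_mm / membrane_radius_mm) ** 2
    return MembraneGeometry(
        cap_height_mm=cap_height_mm,
        membrane_radius_mm=membrane_radius_mm,
        area_increase=da,
        linear_strain=strain_from_area(da),
    )


def volcano_filter(
    table: pd.DataFrame,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    log2_fc: bool = False,
) -> tuple[int, int, pd.DataFrame]:
    """Classify differential-abundance records by joint thresholds.

    Up: fold change ≥ ``fc_min`` and p ≤ ``p_max``; down: fold change
    ≤ 1/``fc_min`` and p ≤ ``p_max`` (thresholds inclusive, reciprocal
    on the linear scale); everything else ns.  ``log2_fc=True`` declares
    the fold-change column as log2 values.
    """
    df = table.copy()
    fc_col = "log2fc" if log2_fc and "log2fc" in df else "fold_change"
    fc = df[fc_col].astype(float).to_numpy()
    if log2_fc:
        fc = 2.0 ** fc
    bad = ~(fc > 0) | ~np.isfinite(fc)
    if bad.any():
        idx = np.flatnonzero(bad)[0]
        raise ValueError(f"non-positive fold change in row {idx} "
                         f"(id {df.iloc[idx, 0]!r})")
    p = df["p_value"].astype(float).to_numpy()
    up = (fc >= fc_min) & (p <= p_max)
    down = (fc <= 1.0 / fc_min) & (p <= p_max)
    df["fold_change_linear"] = fc
    df["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return int(up.sum()), int(down.sum()), df


def mean_intensity_in_mask(channel: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a channel over the pixels of a binary mask."""
    img = np.asarray(channel, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError(f"mask shape {m.shape} != channel shape {img.shape}")
    if not m.any():
        raise ValueError("mask is empty")
    return float(img[m].mean())
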