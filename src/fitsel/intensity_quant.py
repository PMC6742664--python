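"""Background-corrected cell-intensity quantification and level statistics.

Corrected intensity of a marker-positive cell is its raw integrated
density per unit area minus the mean density-per-area of the
marker-negative control cells of the same section. Sections, not cells,
are the replicate unit for genotype summaries. Levels are split into
High/Low at the cohort mean (ties go High), matching the mean-split
classification used for Poisson-like receptor-level distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def background_corrected_intensity(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-cell corrected intensity for marker-positive cells.

    Expects columns: cell_id, section_id, marker_positive, raw_int_density,
    area. Negative corrected intensities are retained (clipping would bias
    section means) but flagged for QC.
    """
    df = measurements.copy()
    if (df["area"] <= 0).any():
        raise ValueError("all areas must be positive")
    df["density"] = df["raw_int_density"] / df["area"]
    ctrl = df[~df["marker_positive"].astype(bool)]
    ctrl_means = ctrl.groupby("section_id")["density"].mean()
    exp = df[df["marker_positive"].astype(bool)].copy()
    missing = sorted(set(exp["section_id"]) - set(ctrl_means.index))
    if missing:
        raise ValueError(f"no control (marker-negative) cells in section(s): {missing}")
    exp["corrected_intensity"] = (exp["density"]
                                  - exp["section_id"].map(ctrl_means).astype(float))
    exp["negative_flag"] = exp["corrected_intensity"] < 0
    return exp.drop(columns=["density"])


def section_average(results: pd.DataFrame, value: str = "corrected_intensity",
                    condition: str = "condition") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean per section, then per-condition mean of section means."""
    per_section = (results.groupby([condition, "section_id"])[value]
                   .mean().reset_index(name="section_mean"))
    per_condition = (per_section.groupby(condition)["section_mean"]
                     .agg(["mean", "sem", "count"]).reset_index())
    return per_section, per_condition


@dataclass
class HighLowResult:
    labels: np.ndarray          # "High"/"Low" per cell
    threshold: float            # cohort mean
    degenerate: bool            # all levels identical


def classify_high_low(levels) -> HighLowResult:
    """Mean-split High/Low classification; level >= mean counts as High."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("need at least one level")
    threshold = float(levels.mean())
    labels = np.where(levels >= threshold, "High", "Low")
    return HighLowResult(labels=labels, threshold=threshold,
                         degenerate=bool(np.all(levels == levels[0])))


def poisson_high_fraction(lam: float) -> float:
    """Exact P(X >= lambda) for Poisson(lambda) — the expected High share."""
    return float(stats.poisson.sf(np.ceil(lam) - 1, lam))


def fraction_above_mean(levels, mask=None) -> float:
    """Fraction of masked cells strictly above the full-cohort mean."""
    levels = np.asarray(levels, dtype=float)
    mask = np.ones(levels.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no cells")
    return float((levels[mask] > levels.mean()).mean())


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def correlate_levels(x, y) -> CorrelationResult:
    """Pearson (default readout) and Spearman correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(float(pr.statistic), float(pr.pvalue),
                             float(sr.statistic), float(sr.pvalue), len(x))


def variance_spread_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided F test of variance equality (larger variance on top)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return float(f), p


def compare_groups(*groups) -> dict:
    """Routine reporting utilities: Welch t (two groups) or one-way ANOVA
    with Sidak-corrected pairwise t tests (more than two)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return {"test": "welch_t", "statistic": float(t), "p": float(p)}
    f, p = stats.f_oneway(*arrays)
    m = len(arrays) * (len(arrays) - 1) // 2
    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            _, pij = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            pairwise.append({"pair": (i, j), "p_raw": float(pij),
                             "p_sidak": float(1 - (1 - pij) ** m)})
    return {"test": "anova_sidak", "statistic": float(f), "p": float(p),
            "pairwise": pairwise}
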