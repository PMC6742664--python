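"""Stochastic simulator of fitness-biased neuronal survival.

The model chains four mechanisms observed in developing proprioceptive
sensory neurons (PSNs):

1. retinoic acid induces the transcription factor RUNX3 dose-dependently
   (Hill response);
2. RUNX3 sets the NT3-receptor (TRKC) level linearly with noise;
3. an inducible CreER tracer recombines with probability increasing in
   receptor level (p_i = min(1, c * level_i**k)); at low inducer dose the
   labeled subset is biased toward high-level cells, and the scale c (and
   optionally the exponent k) is calibrated by bisection against target
   labeled fractions;
4. competition for a limited trophic supply kills a fixed share of the
   population in one discrete step between the pre- and post-death
   censuses: exactly round(S*N) survivors are drawn without replacement
   with weights level**m ("quota" law). m = 0 is neutral survival, the
   m -> infinity limit is the deterministic top-S-by-level rule. A
   per-cell logistic alternative is available behind ``survival_law``.

Genetic/experimental modes: ``bax_null`` blocks death entirely,
``null_tracer`` labels independently of level (k = 0),
``post_death_labeling`` labels only survivors, ``sirna`` knocks down the
receptor in a small labeled subset, ``runx3_null`` collapses levels to the
Low-category distribution, ``raldh_deficient`` zeroes RUNX3 induction in a
fraction of cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic_data import ConfigError, _rng_streams, gamma_poisson

MODES = ("wildtype", "bax_null", "null_tracer", "post_death_labeling",
         "sirna", "runx3_null", "raldh_deficient")


@dataclass
class SelectionConfig:
    n_neurons: int = 10_000
    level_mean: float = 20.0
    level_dispersion: float = 0.15
    survival_fraction: float = 0.5          # ~50% of wild-type PSNs survive
    selection_strength: float = 6.0         # m: weight ~ level**m
    labeling_exponent: float = 4.0          # k: recombination ~ level**k
    labeling_target: float = 0.11           # 11% of PSNs recombined
    mode: str = "wildtype"
    sirna_fraction: float = 0.07            # ~7% of PSNs electroporated
    sirna_knockdown: float = 0.2            # receptor level multiplier
    raldh_fail_fraction: float = 0.29       # share failing RUNX3 induction
    survival_law: str = "quota"             # "quota" | "logistic"
    deterministic_selection: bool = False   # m -> infinity limit
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.survival_fraction <= 1.0:
            raise ConfigError("survival_fraction must be in (0, 1]")
        for name in ("labeling_target", "sirna_fraction", "raldh_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 < self.sirna_knockdown <= 1.0:
            raise ConfigError("sirna_knockdown must be in (0, 1]")
        if self.selection_strength < 0 or self.labeling_exponent < 0:
            raise ConfigError("exponents must be >= 0")
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.survival_law not in ("quota", "logistic"):
            raise ConfigError("survival_law must be 'quota' or 'logistic'")


@dataclass
class DoseResponseParams:
    """Hill-type NT3 survival response anchored at EC50 = 1 ng/ml for a
    reference-level (wild-type average) cell; saturating dose ~ 50 ng/ml."""

    ec50: float = 1.0
    hill_n: float = 1.5
    max_survival: float = 0.8
    baseline: float = 0.05
    trkc_sensitivity: float = 1.0
    reference_level: float = 20.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill_n <= 0:
            raise ConfigError("ec50 and hill_n must be positive")
        if not 0 <= self.baseline <= self.max_survival <= 1:
            raise ConfigError("need baseline <= max_survival <= 1")


@dataclass
class TraceSummary:
    pre_labeled_fraction: float
    post_labeled_fraction: float
    enrichment_ratio: float
    labeled_above_mean_fraction: float
    survivor_count: int
    survivor_level_histogram: tuple[np.ndarray, np.ndarray]


# ---------------------------------------------------------------------------
# upstream induction
# ---------------------------------------------------------------------------

def ra_to_runx3(ra_conc, max_level: float = 40.0, K: float = 100.0,
                hill_n: float = 2.0, raldh_deficient: bool = False,
                raldh_fail_fraction: float = 0.29,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Hill-type RUNX3 induction by retinoic acid (no basal expression).

    ``raldh_deficient`` zeroes induction in a random ``raldh_fail_fraction``
    of cells, emulating loss of the RA-synthesizing enzyme.
    """
    conc = np.atleast_1d(np.asarray(ra_conc, dtype=float))
    if (conc < 0).any():
        raise ConfigError("RA concentration must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        level = max_level * conc ** hill_n / (K ** hill_n + conc ** hill_n)
    level = np.where(conc == 0, 0.0, level)
    if raldh_deficient:
        rng = np.random.default_rng(0) if rng is None else rng
        level = level * (rng.random(level.shape) >= raldh_fail_fraction)
    return level


def assign_trkc(runx3: np.ndarray, slope: float = 1.5, noise_sd: float = 6.0,
                mode: str = "wildtype", config: SelectionConfig | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """TRKC levels from RUNX3; returns (levels, labeled_flags).

    ``runx3_null`` resamples every cell from the wild-type Low-category
    (below-mean) level distribution; ``sirna`` multiplies a random
    ``sirna_fraction`` of cells by ``sirna_knockdown`` and marks them as
    labeled (they carry the GFP tracer).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    runx3 = np.asarray(runx3, dtype=float)
    n = len(runx3)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    trkc = np.clip(slope * runx3 + noise, 0.0, None)
    labeled = np.zeros(n, dtype=bool)
    if mode == "runx3_null":
        low = trkc[trkc < trkc.mean()]
        if len(low) == 0:
            raise ConfigError("degenerate population: no below-mean levels")
        trkc = rng.choice(low, size=n, replace=True)
    elif mode == "sirna":
        cfg = config if config is not None else SelectionConfig()
        labeled = rng.random(n) < cfg.sirna_fraction
        trkc = np.where(labeled, trkc * cfg.sirna_knockdown, trkc)
    return trkc, labeled


# ---------------------------------------------------------------------------
# labeling (CreER recombination)
# ---------------------------------------------------------------------------

def labeling_probabilities(levels: np.ndarray, c: float, k: float) -> np.ndarray:
    levels = np.asarray(levels, dtype=float)
    with np.errstate(divide="ignore"):
        w = np.where(levels > 0, levels ** k, 0.0 if k > 0 else 1.0)
    return np.minimum(1.0, c * w)


def calibrate_labeling_scale(levels: np.ndarray, k: float, target: float,
                             tol: float = 1e-6, max_iter: int = 200) -> float:
    """Bisection on c so that E[labeled fraction] = target."""
    levels = np.asarray(levels, dtype=float)
    if target == 0:
        return 0.0
    hi = 1.0
    while labeling_probabilities(levels, hi, k).mean() < target:
        hi *= 2.0
        if hi > 1e18:
            raise ConfigError("labeling target unreachable (all probabilities "
                              "saturate below target)")
    lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if labeling_probabilities(levels, mid, k).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * hi:       # relative: c may be arbitrarily small
            break
    return 0.5 * (lo + hi)


def expected_labeled_above_mean(levels: np.ndarray, c: float, k: float) -> float:
    """E[share of labeled cells with level strictly above the cohort mean]."""
    p = labeling_probabilities(levels, c, k)
    total = p.sum()
    if total == 0:
        return np.nan
    return float(p[levels > levels.mean()].sum() / total)


def calibrate_labeling(levels: np.ndarray, target_fraction: float = 0.11,
                       target_above_mean: float = 0.75, tol: float = 1e-3,
                       max_iter: int = 60) -> tuple[float, float]:
    """Nested bisection for (c, k) against the two labeling constraints:
    overall labeled fraction and labeled-above-mean share."""
    levels = np.asarray(levels, dtype=float)
    k_lo, k_hi = 0.0, 1.0
    def above(k: float) -> float:
        c = calibrate_labeling_scale(levels, k, target_fraction)
        return expected_labeled_above_mean(levels, c, k)
    base = above(0.0)
    if target_above_mean < base:
        raise ConfigError("target_above_mean below the neutral-labeling share")
    for _ in range(60):
        if above(k_hi) >= target_above_mean:
            break
        k_hi *= 2.0
        if k_hi > 512:
            raise ConfigError("target_above_mean unreachable for this "
                              "level distribution at the given target fraction")
    for _ in range(max_iter):
        k_mid = 0.5 * (k_lo + k_hi)
        if above(k_mid) < target_above_mean:
            k_lo = k_mid
        else:
            k_hi = k_mid
        if k_hi - k_lo < tol:
            break
    k = 0.5 * (k_lo + k_hi)
    return calibrate_labeling_scale(levels, k, target_fraction), k


def recombine(levels: np.ndarray, config: SelectionConfig,
              rng: np.random.Generator, c: float | None = None) -> np.ndarray:
    """Draw labeled flags; ``null_tracer`` forces level-independent labeling."""
    k = 0.0 if config.mode == "null_tracer" else config.labeling_exponent
    if c is None:
        c = calibrate_labeling_scale(levels, k, config.labeling_target)
    p = labeling_probabilities(levels, c, k)
    return rng.random(len(levels)) < p


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def survive(levels: np.ndarray, config: SelectionConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Alive flags after the competition step.

    Quota law: exactly round(S*N) survivors, sampled without replacement
    with weights level**m (Gumbel top-k). Deterministic mode keeps the top
    S share by level, ties broken by lower cell index. ``bax_null`` blocks
    death entirely. Survival is independent of labeled status given level.
    """
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    if config.mode == "bax_null":
        return np.ones(n, dtype=bool)
    n_surv = int(round(config.survival_fraction * n))
    if n_surv < 1:
        warnings.warn("survival quota rounds to zero survivors", stacklevel=2)
        return np.zeros(n, dtype=bool)

    if config.survival_law == "logistic":
        return _survive_logistic(levels, config, rng)

    alive = np.zeros(n, dtype=bool)
    if config.deterministic_selection:
        order = np.lexsort((np.arange(n), -levels))
        alive[order[:n_surv]] = True
        return alive
    m = config.selection_strength
    if m == 0:
        logw = np.zeros(n)
    else:
        with np.errstate(divide="ignore"):
            logl = np.log(levels, out=np.full(n, -np.inf), where=levels > 0)
        logw = m * logl
    keys = logw + rng.gumbel(size=n)
    finite = np.isfinite(keys)
    if finite.sum() >= n_surv:
        idx = np.argpartition(-keys, n_surv - 1)[:n_surv]
    else:  # not enough positive-weight cells: all of them plus random fill
        idx = np.flatnonzero(finite)
        rest = np.flatnonzero(~finite)
        extra = rng.choice(rest, size=n_surv - len(idx), replace=False)
        idx = np.concatenate([idx, extra])
    alive[idx] = True
    return alive


def _survive_logistic(levels: np.ndarray, config: SelectionConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-cell logistic survival, threshold tuned so E[alive] = S."""
    m = config.selection_strength
    with np.errstate(divide="ignore"):
        z = m * np.log(np.maximum(levels, 1e-12))
    lo, hi = z.min() - 50.0, z.max() + 50.0
    for _ in range(200):
        theta = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(theta - z))).mean() > config.survival_fraction:
            lo = theta
        else:
            hi = theta
    p = 1.0 / (1.0 + np.exp(0.5 * (lo + hi) - z))
    return rng.random(len(levels)) < p


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _population_levels(config: SelectionConfig, rng: np.random.Generator) -> np.ndarray:
    return gamma_poisson(rng, config.level_mean, config.level_dispersion,
                         config.n_neurons).astype(float)


def run_tracing_experiment(config: SelectionConfig,
                           calibration: tuple[float, float] | None = None
                           ) -> TraceSummary:
    """Label, kill, census: the in-silico temporal fate-mapping experiment.

    ``calibration`` optionally supplies (c, k) from :func:`calibrate_labeling`;
    otherwise c is calibrated for the configured exponent and target.
    """
    rng_pop, rng_label, rng_surv = _rng_streams(config.seed, 3)
    levels = _population_levels(config, rng_pop)
    cfg = config
    if calibration is not None:
        c, k = calibration
        cfg = replace(config, labeling_exponent=k)
    else:
        c = None

    if config.mode == "post_death_labeling":
        alive = survive(levels, cfg, rng_surv)
        labeled = np.zeros(len(levels), dtype=bool)
        surv_levels = levels[alive]
        c_post = (c if c is not None else
                  calibrate_labeling_scale(surv_levels, cfg.labeling_exponent,
                                           cfg.labeling_target))
        p = labeling_probabilities(surv_levels, c_post, cfg.labeling_exponent)
        labeled[np.flatnonzero(alive)] = rng_label.random(len(surv_levels)) < p
        pre = post = float(labeled[alive].mean())
    else:
        labeled = recombine(levels, cfg, rng_label, c=c)
        alive = survive(levels, cfg, rng_surv)
        pre = float(labeled.mean())
        post = float(labeled[alive].mean()) if alive.any() else np.nan

    above = (fractions_above_mean(levels, labeled)
             if labeled.any() else np.nan)
    hist = np.histogram(levels[alive], bins=30)
    return TraceSummary(
        pre_labeled_fraction=pre,
        post_labeled_fraction=post,
        enrichment_ratio=post / pre if pre > 0 else np.nan,
        labeled_above_mean_fraction=above,
        survivor_count=int(alive.sum()),
        survivor_level_histogram=hist,
    )


def fractions_above_mean(levels: np.ndarray, mask: np.ndarray) -> float:
    return float((levels[mask] > levels.mean()).mean())


def closed_form_enrichment(levels: np.ndarray, labeled_p: np.ndarray,
                           survival_fraction: float) -> float:
    """Deterministic-selection-limit enrichment ratio.

    With survivors exactly the top-S share by level, the post/pre labeled
    ratio is (expected labeled mass in the survivor set) / (S * expected
    total labeled mass).
    """
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    n_surv = int(round(survival_fraction * n))
    order = np.lexsort((np.arange(n), -levels))
    surv = np.zeros(n, dtype=bool)
    surv[order[:n_surv]] = True
    total = labeled_p.sum()
    if total == 0:
        return np.nan
    return float(labeled_p[surv].sum() / ((n_surv / n) * total))


@dataclass
class BaxResult:
    fold_change: float
    low_fraction_bax: float
    low_fraction_wt_survivors: float
    wt_survivor_levels: np.ndarray
    bax_levels: np.ndarray


def run_bax_experiment(config: SelectionConfig) -> BaxResult:
    """Matched wild-type vs death-blocked (Bax-null) censuses, same population.

    The fold change of total counts is exactly 1/S by construction of the
    quota law; with any positive selection strength the death-blocked
    population is enriched for below-mean ("Low") cells relative to the
    wild-type survivors.
    """
    rng_pop, _, rng_surv = _rng_streams(config.seed, 3)
    levels = _population_levels(config, rng_pop)
    wt_alive = survive(levels, replace(config, mode="wildtype"), rng_surv)
    thr = levels.mean()
    wt_levels = levels[wt_alive]
    return BaxResult(
        fold_change=len(levels) / int(wt_alive.sum()),
        low_fraction_bax=float((levels < thr).mean()),
        low_fraction_wt_survivors=float((wt_levels < thr).mean()),
        wt_survivor_levels=wt_levels,
        bax_levels=levels,
    )


@dataclass
class SirnaResult:
    pre_labeled_knockdown: int
    pre_labeled_control: int
    post_labeled_knockdown: int
    post_labeled_control: int
    labeled_loss: float         # 1 - post_kd / post_ctrl


def run_sirna_experiment(config: SelectionConfig) -> SirnaResult:
    """Receptor knockdown in a small labeled subset vs control tracer.

    Both arms share the population and the electroporated (labeled) cells;
    the knockdown arm multiplies labeled cells' levels by
    ``sirna_knockdown`` before the survival step. Death only occurs at the
    survival step, so pre-death labeled counts are identical by
    construction.
    """
    rng_pop, rng_label, rng_surv = _rng_streams(config.seed, 3)
    levels = _population_levels(config, rng_pop)
    labeled = rng_label.random(len(levels)) < config.sirna_fraction
    levels_kd = np.where(labeled, levels * config.sirna_knockdown, levels)
    state = rng_surv.bit_generator.state
    alive_ctrl = survive(levels, replace(config, mode="wildtype"), rng_surv)
    rng_surv.bit_generator.state = state     # paired draws across arms
    alive_kd = survive(levels_kd, replace(config, mode="wildtype"), rng_surv)
    post_ctrl = int((labeled & alive_ctrl).sum())
    post_kd = int((labeled & alive_kd).sum())
    return SirnaResult(
        pre_labeled_knockdown=int(labeled.sum()),
        pre_labeled_control=int(labeled.sum()),
        post_labeled_knockdown=post_kd,
        post_labeled_control=post_ctrl,
        labeled_loss=1.0 - post_kd / post_ctrl if post_ctrl else np.nan,
    )


def calibrate_selection_strength(config: SelectionConfig,
                                 target_loss: float = 0.80,
                                 n_reps: int = 6, tol: float = 0.02,
                                 m_max: float = 64.0) -> float:
    """Bisection on the selection strength m so the siRNA labeled-cell loss
    matches the observed target (loss is monotone increasing in m)."""
    def mean_loss(m: float) -> float:
        losses = []
        for r in range(n_reps):
            cfg = replace(config, mode="sirna", selection_strength=m,
                          seed=config.seed + 1000 + r)
            losses.append(run_sirna_experiment(cfg).labeled_loss)
        return float(np.mean(losses))

    lo, hi = 0.0, 1.0
    while mean_loss(hi) < target_loss:
        hi *= 2.0
        if hi > m_max:
            raise ConfigError("target loss unreachable below m_max")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        loss = mean_loss(mid)
        if abs(loss - target_loss) < tol:
            return mid
        if loss < target_loss:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def nt3_dose_response(levels, conc: float, params: DoseResponseParams) -> np.ndarray:
    """Per-cell survival probability under an NT3 dose.

    The effective dose scales with relative receptor level:
    d = conc * (level / reference)**trkc_sensitivity; a reference-level
    cell at conc = ec50 sits exactly at (baseline + max_survival) / 2.
    """
    if conc < 0:
        raise ConfigError("NT3 concentration must be >= 0")
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    rel = np.maximum(levels / params.reference_level, 0.0)
    d = conc * rel ** params.trkc_sensitivity
    frac = d ** params.hill_n / (params.ec50 ** params.hill_n + d ** params.hill_n)
    frac = np.where(d == 0, 0.0, frac)
    return params.baseline + (params.max_survival - params.baseline) * frac
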