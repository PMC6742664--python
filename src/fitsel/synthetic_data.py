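"""Synthetic inputs with ground truth for every pipeline stage.

The generators emulate the statistical structure of the biological system:

* per-neuron TRKC receptor levels follow an overdispersed ("Poisson-like")
  count distribution, realized as a gamma-Poisson mixture whose pure-Poisson
  limit is ``level_dispersion -> 0``;
* RUNX3 drives TRKC linearly with additive noise, so the RUNX3-TRKC
  correlation is tunable through the noise standard deviation;
* two-channel smFISH scenes render a pan-transcript channel and a
  full-length-isoform channel whose ground-truth spots are a per-cell
  binomial thinning of the pan spots (FL transcripts are physically a
  subset of all transcripts);
* gene x cell count matrices contain two sensory-neuron clusters with
  planted markers, non-sensory contaminants, low-complexity wells and
  hemoglobin-dominated red blood cells, with a per-cell mitochondrial
  fraction covariate.

All generators are bit-reproducible under a fixed seed, and every emitted
object carries enough truth to score downstream stages directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent, named-by-position random streams derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# neuron populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Parameters of the simulated brachial-DRG neuron population.

    ``level_mean``/``level_dispersion`` parameterize the gamma-Poisson
    receptor-level model: variance = mean * (1 + dispersion * mean), so the
    dispersion -> 0 limit is pure Poisson. ``frac_high_subgroup`` is the
    share of neurons in the more mature, higher-expressing subgroup;
    ``subgroup_mean_ratio`` is its mean level relative to the low subgroup.
    """

    n_neurons: int = 10_000
    level_mean: float = 20.0
    level_dispersion: float = 0.15
    frac_high_subgroup: float = 0.5
    runx3_trkc_slope: float = 1.5
    runx3_trkc_noise_sd: float = 6.0
    subgroup_mean_ratio: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ConfigError("n_neurons must be >= 0")
        if self.level_mean <= 0:
            raise ConfigError("level_mean must be positive")
        if self.level_dispersion < 0:
            raise ConfigError("level_dispersion must be >= 0")
        if not 0.0 <= self.frac_high_subgroup <= 1.0:
            raise ConfigError("frac_high_subgroup must be in [0, 1]")
        if self.runx3_trkc_noise_sd < 0:
            raise ConfigError("runx3_trkc_noise_sd must be >= 0")


def gamma_poisson(rng: np.random.Generator, mean: float, dispersion: float,
                  size: int) -> np.ndarray:
    """Sample a gamma-Poisson (negative binomial) vector.

    Parameterized so that variance = mean + dispersion * mean**2; at
    dispersion == 0 the draw is exactly Poisson(mean).
    """
    if mean <= 0:
        raise ConfigError("gamma-Poisson mean must be positive")
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam).astype(np.int64)


def gen_trkc_levels(config: PopulationConfig) -> np.ndarray:
    """Per-neuron receptor levels under the Poisson-like level model."""
    rng = np.random.default_rng(config.seed)
    return gamma_poisson(rng, config.level_mean, config.level_dispersion,
                         config.n_neurons)


def gen_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate a neuron population table.

    Columns: ``neuron_id``, ``subgroup`` ("high"/"low"), ``runx3``, ``trkc``,
    ``labeled`` (False), ``alive`` (True). RUNX3 levels are gamma-Poisson per
    subgroup and TRKC = slope * RUNX3 + N(0, noise_sd), truncated at zero.
    """
    rng_sub, rng_runx3, rng_noise = _rng_streams(config.seed, 3)
    n = config.n_neurons
    high = rng_sub.random(n) < config.frac_high_subgroup
    runx3 = np.zeros(n, dtype=float)
    n_high = int(high.sum())
    if n_high:
        runx3[high] = gamma_poisson(
            rng_runx3, config.level_mean * config.subgroup_mean_ratio,
            config.level_dispersion, n_high)
    if n - n_high:
        runx3[~high] = gamma_poisson(
            rng_runx3, config.level_mean, config.level_dispersion, n - n_high)
    noise = (rng_noise.normal(0.0, config.runx3_trkc_noise_sd, size=n)
             if config.runx3_trkc_noise_sd > 0 else np.zeros(n))
    trkc = np.clip(config.runx3_trkc_slope * runx3 + noise, 0.0, None)
    return pd.DataFrame({
        "neuron_id": np.arange(n),
        "subgroup": np.where(high, "high", "low"),
        "runx3": runx3,
        "trkc": trkc,
        "labeled": np.zeros(n, dtype=bool),
        "alive": np.ones(n, dtype=bool),
    })


def expected_population_correlation(runx3: np.ndarray, slope: float,
                                    noise_sd: float) -> float:
    """Closed-form RUNX3-TRKC Pearson r for the linear-plus-noise model."""
    sd_r = float(np.std(runx3))
    return slope * sd_r / np.sqrt(slope ** 2 * sd_r ** 2 + noise_sd ** 2)


# ---------------------------------------------------------------------------
# smFISH scenes
# ---------------------------------------------------------------------------

@dataclass
class SmfishSceneConfig:
    """Two-channel single-molecule FISH scene.

    Diffraction-limited transcripts are isotropic Gaussians of scale
    ``spot_sigma`` over a smooth background (low-frequency Gaussian random
    field of scale ``background_sigma``) plus i.i.d. read noise. The
    full-length (FL) channel carries a per-cell binomial subset of the pan
    spots with expected share ``fl_fraction``; the default 0.68 mirrors the
    FL share measured in vivo.
    """

    image_shape: tuple[int, int, int] = (1500, 1500, 4)  # (y, x, z)
    n_cells: int = 200
    spots_per_cell_mean: float = 6.0
    fl_fraction: float = 0.68
    spot_sigma: float = 1.1
    spot_amplitude: float = 8.0
    background_amplitude: float = 2.0
    background_sigma: float = 40.0
    noise_sd: float = 1.0
    cell_radius: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fl_fraction <= 1.0:
            raise ConfigError("fl_fraction must be in [0, 1]")
        if self.spot_sigma <= 0:
            raise ConfigError("spot_sigma must be positive")
        if any(d < 1 for d in self.image_shape):
            raise ConfigError("all image dimensions must be >= 1")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")


@dataclass
class SmfishScene:
    """Rendered scene: z-stacks as (z, y, x) arrays plus ground truth."""

    pan: np.ndarray
    fl: np.ndarray
    truth: pd.DataFrame            # columns: cell, channel, y, x, z
    rois: list[dict]               # GeoJSON Feature dicts (pixel coordinates)
    centers: np.ndarray            # (n_cells, 2) array of (y, x)
    config: SmfishSceneConfig


def _cell_centers(cfg: SmfishSceneConfig, rng: np.random.Generator) -> np.ndarray:
    ny, nx, _ = cfg.image_shape
    pitch = 2.4 * cfg.cell_radius
    margin = cfg.cell_radius + 3.0
    ys = np.arange(margin, ny - margin, pitch)
    xs = np.arange(margin, nx - margin, pitch)
    grid = np.array([(y, x) for y in ys for x in xs])
    if len(grid) < cfg.n_cells:
        raise ConfigError(
            f"image {cfg.image_shape[:2]} fits at most {len(grid)} cells of "
            f"radius {cfg.cell_radius}, requested {cfg.n_cells}")
    idx = rng.choice(len(grid), size=cfg.n_cells, replace=False)
    jitter = rng.uniform(-0.3 * cfg.cell_radius, 0.3 * cfg.cell_radius,
                         size=(cfg.n_cells, 2))
    return grid[np.sort(idx)] + jitter


def _stamp_spots(stack: np.ndarray, spots: pd.DataFrame, sigma: float,
                 amplitude: float) -> None:
    """Add an isotropic Gaussian of peak height `amplitude` per spot, in place."""
    half = max(2, int(np.ceil(4 * sigma)))
    ax = np.arange(-half, half + 1)
    _, ny, nx = stack.shape
    for y, x, z in zip(spots["y"].to_numpy(), spots["x"].to_numpy(),
                       spots["z"].to_numpy()):
        iy, ix = int(round(y)), int(round(x))
        gy = np.exp(-((iy + ax - y) ** 2) / (2 * sigma ** 2))
        gx = np.exp(-((ix + ax - x) ** 2) / (2 * sigma ** 2))
        patch = amplitude * np.outer(gy, gx)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
        stack[int(z), y0:y1, x0:x1] += patch[y0 - (iy - half): patch.shape[0] - ((iy + half + 1) - y1),
                                             x0 - (ix - half): patch.shape[1] - ((ix + half + 1) - x1)]


def _smooth_background(shape: tuple[int, int], sigma: float, amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Low-frequency Gaussian random field with a positive baseline."""
    raw = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    sd = raw.std()
    if sd > 0:
        raw = raw / sd
    return amplitude * raw + 2.0 * amplitude


def _circle_roi(center_yx: np.ndarray, radius: float, roi_id: int,
                n_vertices: int = 32) -> dict:
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    ring = [[float(center_yx[1] + radius * np.cos(t)),
             float(center_yx[0] + radius * np.sin(t))] for t in theta]
    ring.append(ring[0])
    return {"type": "Feature",
            "properties": {"roi_id": int(roi_id)},
            "geometry": {"type": "Polygon", "coordinates": [ring]}}


def render_smfish_scene(config: SmfishSceneConfig) -> SmfishScene:
    """Render pan and FL channels with ground-truth spot tables and ROIs."""
    rng_place, rng_counts, rng_pos, rng_thin, rng_img = _rng_streams(config.seed, 5)
    ny, nx, nz = config.image_shape
    centers = (_cell_centers(config, rng_place)
               if config.n_cells else np.zeros((0, 2)))

    resolvable = np.pi * config.cell_radius ** 2 / (np.pi * (2 * config.spot_sigma) ** 2)
    if config.spots_per_cell_mean > resolvable:
        warnings.warn("expected spot density exceeds the resolvable density "
                      "for this spot_sigma; nearby spots will merge",
                      stacklevel=2)

    rows = []
    r_spot = 0.85 * config.cell_radius
    for cell, (cy, cx) in enumerate(centers):
        k = rng_counts.poisson(config.spots_per_cell_mean)
        radius = r_spot * np.sqrt(rng_pos.random(k))
        angle = rng_pos.uniform(0, 2 * np.pi, size=k)
        sy = np.clip(cy + radius * np.sin(angle), 0, ny - 1)
        sx = np.clip(cx + radius * np.cos(angle), 0, nx - 1)
        sz = rng_pos.integers(0, nz, size=k)
        is_fl = rng_thin.random(k) < config.fl_fraction
        for y, x, z, fl in zip(sy, sx, sz, is_fl):
            rows.append((cell, "pan", y, x, int(z)))
            if fl:
                rows.append((cell, "fl", y, x, int(z)))
    truth = pd.DataFrame(rows, columns=["cell", "channel", "y", "x", "z"])

    stacks = {}
    for channel in ("pan", "fl"):
        stack = np.zeros((nz, ny, nx), dtype=float)
        sub = truth[truth["channel"] == channel]
        _stamp_spots(stack, sub, config.spot_sigma, config.spot_amplitude)
        bg = _smooth_background((ny, nx), config.background_sigma,
                                config.background_amplitude, rng_img)
        stack += bg[None, :, :]
        if config.noise_sd > 0:
            stack += rng_img.normal(0.0, config.noise_sd, size=stack.shape)
        stacks[channel] = np.clip(stack, 0.0, None)

    rois = [_circle_roi(c, config.cell_radius + 1.5, i)
            for i, c in enumerate(centers)]
    return SmfishScene(pan=stacks["pan"], fl=stacks["fl"], truth=truth,
                       rois=rois, centers=centers, config=config)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

HEMOGLOBIN_GENES = ("Hba-a1", "Hba-a2", "Hbb-bs", "Hbb-bt")
MITO_GENES = tuple(f"mt-Nd{i}" for i in range(1, 7)) + (
    "mt-Co1", "mt-Co2", "mt-Co3", "mt-Atp6", "mt-Atp8", "mt-Cytb")

# Default planted marker programs for the two sensory-neuron clusters. The
# named genes distinguish the more mature (cluster1) from the less mature
# (cluster2) proprioceptor subgroup; generic Marker* genes pad each program
# to a realistic width of ~20 differential genes per cluster.
DEFAULT_MARKERS: dict[str, dict[str, float]] = {
    "cluster1": {g: 8.0 for g in
                 ["Hmx1", "Fxyd7", "Fam19a4", "Scn3b", "Scn7a", "Scn9a",
                  "Piezo2"] + [f"MarkerA{i:02d}" for i in range(13)]},
    "cluster2": {g: 8.0 for g in
                 ["Sst", "Pou2f2", "Tbx3"] + [f"MarkerB{i:02d}" for i in range(17)]},
}
# Runx3/Ntrk3 are graded, not on/off, between the two clusters.
DEFAULT_GRADED = {"Runx3": 3.0, "Ntrk3": 3.0}


@dataclass
class SyntheticCountsConfig:
    """Gene x cell count matrix with planted structure.

    ``cells_per_cluster`` keys: cluster1, cluster2 (sensory neurons,
    Pou4f1-high, high complexity), contaminant (Pou4f1-negative),
    low_quality (tiny library, < 4000 detected genes), rbc (hemoglobin
    dominates the library). Defaults total 350 cells, matching the size of
    the sorted-plate experiment being emulated.
    """

    n_genes: int = 6000
    cells_per_cluster: dict[str, int] = field(default_factory=lambda: {
        "cluster1": 120, "cluster2": 110, "contaminant": 50,
        "low_quality": 40, "rbc": 30})
    marker_genes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKERS.items()})
    pou4f1_high_rate: float = 60.0
    hemoglobin_high_rate: float = 250_000.0
    mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    library_size_mean: float = 300_000.0
    low_quality_library_mean: float = 5_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or any(v < 0 for v in self.cells_per_cluster.values()):
            raise ConfigError("counts must be >= 0")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("mito_fraction_range must be within [0, 1]")
        seen: set[str] = set()
        for genes in self.marker_genes.values():
            dup = seen.intersection(genes)
            if dup:
                raise ConfigError(f"marker gene(s) named in two clusters: {sorted(dup)}")
            seen.update(genes)


@dataclass
class CountMatrix:
    """Sparse gene x cell integer counts plus gene and cell metadata."""

    X: sparse.csr_matrix            # genes x cells
    genes: pd.DataFrame             # column: gene
    cells: pd.DataFrame             # cell_id, truth_cluster, total_reads,
                                    # percent_mito, hemoglobin_counts

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def gene_index(self, name: str) -> int:
        hits = np.flatnonzero((self.genes["gene"] == name).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"gene {name!r} not present")
        return int(hits[0])


def _gene_names(config: SyntheticCountsConfig) -> list[str]:
    special = (["Pou4f1"] + list(HEMOGLOBIN_GENES) + list(MITO_GENES)
               + list(DEFAULT_GRADED))
    for genes in config.marker_genes.values():
        special.extend(genes)
    if len(special) > config.n_genes:
        raise ConfigError("n_genes too small for the named special genes")
    fillers = [f"Gene{i:05d}" for i in range(config.n_genes - len(special))]
    return special + fillers


def gen_count_matrix(config: SyntheticCountsConfig) -> CountMatrix:
    """Generate the planted-structure count matrix with truth labels."""
    rng_base, rng_mito, rng_lib, rng_draw = _rng_streams(config.seed, 4)
    names = _gene_names(config)
    n_genes = len(names)
    index = {g: i for i, g in enumerate(names)}

    base = rng_base.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    base[[index[g] for g in MITO_GENES]] = 0.0          # mito handled per cell
    base[[index[g] for g in HEMOGLOBIN_GENES]] *= 0.2   # modest outside rbc
    mito_profile = np.zeros(n_genes)
    mito_profile[[index[g] for g in MITO_GENES]] = rng_base.lognormal(
        0.0, 0.4, size=len(MITO_GENES))
    mito_profile /= mito_profile.sum()

    def cluster_rates(cluster: str) -> np.ndarray:
        r = base.copy()
        if cluster in ("cluster1", "cluster2", "low_quality"):
            r[index["Pou4f1"]] = (config.pou4f1_high_rate
                                  / config.library_size_mean * base.sum())
        else:
            r[index["Pou4f1"]] = 0.0
        key = "cluster1" if cluster == "low_quality" else cluster
        for gene, fold in config.marker_genes.get(key, {}).items():
            r[index[gene]] *= fold
        if key == "cluster1":
            for gene, fold in DEFAULT_GRADED.items():
                r[index[gene]] *= fold
        if cluster == "rbc":
            hb_share = min(config.hemoglobin_high_rate / config.library_size_mean, 0.95)
            r /= r.sum()
            r *= (1.0 - hb_share)
            hb = [index[g] for g in HEMOGLOBIN_GENES]
            r[hb] = hb_share * rng_base.dirichlet(np.ones(len(hb)))
        return r / r.sum()

    cols, meta = [], []
    order = ["cluster1", "cluster2", "contaminant", "low_quality", "rbc"]
    cell_id = 0
    lo, hi = config.mito_fraction_range
    for cluster in order:
        n_cells = config.cells_per_cluster.get(cluster, 0)
        if n_cells == 0:
            continue
        rates = cluster_rates(cluster)
        lib_mean = (config.low_quality_library_mean if cluster == "low_quality"
                    else config.library_size_mean)
        for _ in range(n_cells):
            mf = rng_mito.uniform(lo, hi)
            p = (1.0 - mf) * rates + mf * mito_profile
            total = max(int(rng_lib.poisson(lib_mean)), 1)
            counts = rng_draw.multinomial(total, p / p.sum())
            cols.append(sparse.csr_matrix(counts[:, None]))
            meta.append((f"cell{cell_id:04d}", cluster, int(counts.sum()), mf))
            cell_id += 1

    if cols:
        X = sparse.hstack(cols, format="csr")
    else:
        X = sparse.csr_matrix((n_genes, 0), dtype=np.int64)
    genes = pd.DataFrame({"gene": names})
    cells = pd.DataFrame(meta, columns=["cell_id", "truth_cluster",
                                        "total_reads", "mito_draw"])
    hb_idx = [index[g] for g in HEMOGLOBIN_GENES]
    mt_idx = [index[g] for g in MITO_GENES]
    if X.shape[1]:
        totals = np.asarray(X.sum(axis=0)).ravel()
        cells["hemoglobin_counts"] = np.asarray(X[hb_idx].sum(axis=0)).ravel()
        cells["percent_mito"] = (np.asarray(X[mt_idx].sum(axis=0)).ravel()
                                 / np.maximum(totals, 1))
    else:
        cells["hemoglobin_counts"] = pd.Series(dtype=np.int64)
        cells["percent_mito"] = pd.Series(dtype=float)
    return CountMatrix(X=X.astype(np.int64), genes=genes,
                       cells=cells.drop(columns=["mito_draw"]))


# ---------------------------------------------------------------------------
# embryo cohorts (per-section labeled/total counts)
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Per-embryo, per-section labeled-cell counting experiment."""

    n_embryos: int = 6
    sections_per_embryo: int = 8
    cells_per_section_mean: float = 100.0
    true_proportions: dict[str, float] = field(
        default_factory=lambda: {"pre": 0.116, "post": 0.209})
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.true_proportions.values()):
            raise ConfigError("proportions must be in [0, 1]")


def gen_cohort(config: CohortConfig) -> pd.DataFrame:
    """Binomial per-section labeled/total counts around true proportions."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for condition, p in config.true_proportions.items():
        for embryo in range(config.n_embryos):
            for section in range(config.sections_per_embryo):
                n = max(int(rng.poisson(config.cells_per_section_mean)), 1)
                labeled = int(rng.binomial(n, p))
                rows.append((condition, embryo, section, n, labeled))
    return pd.DataFrame(rows, columns=["condition", "embryo", "section",
                                       "n_cells", "n_labeled"])


# ---------------------------------------------------------------------------
# measurement tables (intensity-quantification stage input)
# ---------------------------------------------------------------------------

def gen_measurement_table(population: pd.DataFrame, n_sections: int = 6,
                          controls_per_section: int = 8,
                          background_level: float = 5.0,
                          background_jitter: float = 1.0,
                          area_mean: float = 100.0,
                          seed: int = 0) -> pd.DataFrame:
    """Turn a neuron population into a raw per-cell measurement table.

    Each section gets its own additive background density (what the
    marker-negative control cells measure); marker-positive cells report
    background plus their true level, times their area. This is plumbing
    that lets the intensity-quantification stage be scored against the
    population truth.
    """
    rng = np.random.default_rng(seed)
    n = len(population)
    section = rng.integers(0, n_sections, size=n)
    bg = background_level + background_jitter * rng.standard_normal(n_sections)
    area = rng.normal(area_mean, 0.1 * area_mean, size=n).clip(area_mean * 0.5)
    rows = []
    for i, (sec, lvl, a) in enumerate(zip(section, population["trkc"], area)):
        density = bg[sec] + lvl
        rows.append((f"cell{i:05d}", f"sec{sec}", "wildtype", True,
                     density * a, a, float(lvl)))
    for sec in range(n_sections):
        for j in range(controls_per_section):
            a = float(rng.normal(area_mean, 0.1 * area_mean))
            rows.append((f"ctrl{sec}_{j}", f"sec{sec}", "wildtype", False,
                         bg[sec] * a, a, np.nan))
    return pd.DataFrame(rows, columns=["cell_id", "section_id", "condition",
                                       "marker_positive", "raw_int_density",
                                       "area", "true_level"])
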