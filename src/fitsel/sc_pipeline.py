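"""Single-cell RNA-seq preprocessing, clustering, markers and enrichment.

Implements the exact rule set used for the sensory-neuron plates:

* QC gates: cells kept iff the sensory gate gene (Pou4f1) has count > 5
  and >= 4000 unique genes are detected; genes expressed in fewer than
  three retained cells are dropped (gene filter after cell filter);
* global scaling normalization y = ln(1 + x/Z * 1e4);
* variable genes by dispersion (variance/mean of the back-transformed
  normalized expression), z-scored within 20 equal-frequency mean bins,
  kept iff mean >= 0.0125 and dispersion z >= 0.5 (a raw-dispersion mode
  is available behind a flag);
* per-gene OLS regression of a covariate (percent mitochondrial reads)
  followed by centering/unit-scaling;
* PCA with JackStraw permutation significance;
* union-symmetrized kNN graph + Louvain community detection;
* cluster markers by a bimodal (point mass at zero + log-normal)
  likelihood-ratio test with min.pct/log-fold gates, Wilcoxon rank-sum
  as the alternative;
* molecule-count prefilters and CV^2-vs-mean noise-model feature ranking
  for the velocity-style analysis;
* one-sided hypergeometric term enrichment with BH FDR and a Jaccard
  similarity network over the kept terms.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CountMatrix, HEMOGLOBIN_GENES


@dataclass
class ScParams:
    pou4f1_min: int = 5                 # strict: count must exceed this
    gate_gene: str = "Pou4f1"
    min_genes_per_cell: int = 4000
    min_cells_per_gene: int = 3
    mean_cutoff: float = 0.0125
    dispersion_cutoff: float = 0.5
    dispersion_bins: int = 20
    n_pcs: int = 20
    marker_min_pct: float = 0.25
    marker_logfc_thresh: float = 0.1
    # velocity-style prefilters
    min_total_reads: int = 150_000
    gene_total_min: int = 38
    gene_single_cell_min: int = 18
    hemoglobin_share_max: float = 0.10
    n_top_genes: int = 1400
    n_pcs_graph: int = 6
    knn_k: int = 20
    louvain_resolution: float = 0.5
    # enrichment network
    term_p: float = 0.001
    fdr_q: float = 0.05
    jaccard_min: float = 0.25


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def qc_filter(cm: CountMatrix, params: ScParams | None = None) -> CountMatrix:
    """Sensory-neuron QC: gate-gene count > 5, >= 4000 detected genes, then
    drop genes expressed in fewer than 3 retained cells."""
    params = params or ScParams()
    gi = cm.gene_index(params.gate_gene)  # raises KeyError if absent
    X = cm.X.tocsc()
    gate_counts = np.asarray(X[gi].todense()).ravel()
    genes_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_cells = (gate_counts > params.pou4f1_min) & \
                 (genes_detected >= params.min_genes_per_cell)
    Xc = X[:, keep_cells].tocsr()
    cells_per_gene = np.asarray((Xc > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    return CountMatrix(
        X=Xc[keep_genes].tocsr(),
        genes=cm.genes.loc[keep_genes].reset_index(drop=True),
        cells=cm.cells.loc[keep_cells].reset_index(drop=True),
    )


def velocity_prefilter(cm: CountMatrix, params: ScParams | None = None) -> CountMatrix:
    """Molecule-count prefilters: drop shallow cells (< 150,000 reads) and
    hemoglobin-dominated red blood cells; keep genes with >= 38 total reads
    and >= 18 reads in at least one cell."""
    params = params or ScParams()
    X = cm.X.tocsc()
    totals = np.asarray(X.sum(axis=0)).ravel()
    hb_rows = [i for i, g in enumerate(cm.genes["gene"])
               if g in HEMOGLOBIN_GENES]
    hb = (np.asarray(X[hb_rows].sum(axis=0)).ravel() if hb_rows
          else np.zeros(cm.n_cells))
    with np.errstate(invalid="ignore", divide="ignore"):
        hb_share = np.where(totals > 0, hb / totals, 0.0)
    keep_cells = (totals >= params.min_total_reads) & \
                 (hb_share <= params.hemoglobin_share_max)
    Xc = X[:, keep_cells].tocsr()
    gene_tot = np.asarray(Xc.sum(axis=1)).ravel()
    gene_max = Xc.max(axis=1).toarray().ravel() if Xc.shape[1] else \
        np.zeros(cm.n_genes)
    keep_genes = (gene_tot >= params.gene_total_min) & \
                 (gene_max >= params.gene_single_cell_min)
    return CountMatrix(
        X=Xc[keep_genes].tocsr(),
        genes=cm.genes.loc[keep_genes].reset_index(drop=True),
        cells=cm.cells.loc[keep_cells].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# normalization and feature selection
# ---------------------------------------------------------------------------

def log_normalize(cm: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """y = ln(1 + x/Z * scale) as a dense genes x cells array.

    The log1p convention keeps zeros at zero, making the transform defined
    for the sparse bulk of the matrix.
    """
    totals = np.asarray(cm.X.sum(axis=0)).ravel()
    if (totals <= 0).any():
        raise ValueError("zero-total cell encountered; run QC first")
    Y = cm.X.toarray().astype(float) / totals[None, :] * scale
    return np.log1p(Y)


def gene_dispersion(norm: np.ndarray) -> pd.DataFrame:
    """Per-gene mean and dispersion of back-transformed expression.

    Dispersion = variance / mean of expm1(y), the variance-to-mean ratio
    on the scaled-count scale.
    """
    raw = np.expm1(norm)
    mean = raw.mean(axis=1)
    var = raw.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    return pd.DataFrame({"mean": mean, "dispersion": disp})


def select_variable_genes(norm: np.ndarray, params: ScParams | None = None,
                          z_scored: bool = True) -> np.ndarray:
    """Boolean mask of variable genes.

    Default mode z-scores log-dispersions within equal-frequency mean bins
    and keeps genes with mean >= mean_cutoff and z >= dispersion_cutoff;
    the raw mode applies the cutoff to the unbinned dispersion directly.
    """
    params = params or ScParams()
    df = gene_dispersion(norm)
    mean, disp = df["mean"].to_numpy(), df["dispersion"].to_numpy()
    ok = np.isfinite(disp) & (mean > 0)
    if not z_scored:
        return ok & (mean >= params.mean_cutoff) & (disp >= params.dispersion_cutoff)

    z = np.full(len(mean), np.nan)
    n_ok = int(ok.sum())
    n_bins = params.dispersion_bins if n_ok >= params.dispersion_bins else 1
    if n_ok:
        ranks = stats.rankdata(mean[ok], method="average")
        bins = np.minimum((ranks - 1) / len(ranks) * n_bins, n_bins - 1).astype(int)
        logd = np.log(disp[ok])
        zz = np.empty(n_ok)
        for b in np.unique(bins):
            sel = bins == b
            mu, sd = logd[sel].mean(), logd[sel].std()
            zz[sel] = 0.0 if sd == 0 else (logd[sel] - mu) / sd
        z[ok] = zz
    with np.errstate(invalid="ignore"):
        return ok & (mean >= params.mean_cutoff) & (z >= params.dispersion_cutoff)


def variable_gene_benchmark(cm: CountMatrix, params: ScParams | None = None
                            ) -> dict[str, int]:
    """Apply the stated QC + normalization + dispersion cutoffs and report
    the variable-gene count under both dispersion interpretations.

    Intended to be pointed at any local MTX bundle (e.g. a downloaded
    accession) as well as synthetic matrices.
    """
    params = params or ScParams()
    filtered = qc_filter(cm, params)
    norm = log_normalize(filtered)
    return {
        "n_cells_pass_qc": filtered.n_cells,
        "n_genes_pass_qc": filtered.n_genes,
        "n_variable_z_scored": int(select_variable_genes(norm, params).sum()),
        "n_variable_raw": int(select_variable_genes(norm, params,
                                                    z_scored=False).sum()),
    }


def regress_covariate(norm: np.ndarray, covariate) -> np.ndarray:
    """Per-gene OLS of expression on one covariate; residuals centered and
    unit-scaled per gene (constant genes become zero rows)."""
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != norm.shape[1]:
        raise ValueError("covariate length must equal the number of cells")
    c = cov - cov.mean()
    denom = (c ** 2).sum()
    Y = norm - norm.mean(axis=1, keepdims=True)
    if denom == 0:
        warnings.warn("constant covariate: centering/scaling only", stacklevel=2)
        resid = Y
    else:
        slope = Y @ c / denom
        resid = Y - slope[:, None] * c[None, :]
    sd = resid.std(axis=1)
    out = np.zeros_like(resid)
    # rows whose residual is numerically zero (constant or exactly linear
    # in the covariate) stay zero instead of amplifying float noise
    floor = 1e-10 * max(float(np.abs(norm).max()), 1.0)
    nz = sd > floor
    out[nz] = resid[nz] / sd[nz, None]
    return out


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    embedding: np.ndarray        # cells x n_pcs scores
    loadings: np.ndarray         # genes x n_pcs
    variance_explained: np.ndarray


def pca_embed(scaled: np.ndarray, n_pcs: int = 20) -> PcaResult:
    """PCA of the gene-scaled matrix (genes x cells); embeds cells.

    Sign convention: the largest-magnitude loading of each component is
    positive. Degenerate rank truncates with a warning.
    """
    X = np.asarray(scaled, dtype=float).T            # cells x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size else 0
    if n_pcs > rank:
        warnings.warn(f"requested {n_pcs} PCs but rank is {rank}; truncating",
                      stacklevel=2)
        n_pcs = rank
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    for j in range(n_pcs):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s ** 2 / max(X.shape[0] - 1, 1)
    return PcaResult(embedding=U * s, loadings=Vt.T, variance_explained=var)


def jackstraw_significance(scaled: np.ndarray, n_pcs: int = 20,
                           n_reps: int = 100, frac_permuted: float = 0.01,
                           alpha: float = 0.05, pc_alpha: float = 0.01,
                           seed: int = 0) -> np.ndarray:
    """Permutation test of PC significance.

    Each replicate permutes a random fraction of genes across cells and
    records their null loading magnitudes; a gene's empirical p per PC is
    the null exceedance of its observed |loading|. A PC is significant
    when the share of genes with p < ``alpha`` exceeds ``alpha`` by a
    calibrated margin: the proportion's variance includes both the
    binomial term (1/n_genes) and the shared-null quantile-estimation
    term (1/n_null), and the resulting z is Bonferroni-thresholded across
    the tested PCs at familywise level ``pc_alpha``. alpha >= 1 marks
    every PC significant.
    """
    rng = np.random.default_rng(seed)
    obs = np.abs(pca_embed(scaled, n_pcs).loadings)
    n_pcs = obs.shape[1]
    if alpha >= 1.0:
        return np.arange(n_pcs)
    n_genes = scaled.shape[0]
    n_perm = max(1, int(round(frac_permuted * n_genes)))
    null = [[] for _ in range(n_pcs)]
    for _ in range(n_reps):
        Xp = scaled.copy()
        genes = rng.choice(n_genes, size=n_perm, replace=False)
        for g in genes:
            Xp[g] = rng.permutation(Xp[g])
        lp = np.abs(pca_embed(Xp, n_pcs).loadings)
        for j in range(n_pcs):
            null[j].extend(lp[genes, j])
    z_crit = stats.norm.isf(pc_alpha / n_pcs)
    significant = []
    for j in range(n_pcs):
        nj = np.sort(np.asarray(null[j]))
        exceed = len(nj) - np.searchsorted(nj, obs[:, j], side="right")
        pvals = (exceed + 1) / (len(nj) + 1)
        phat = float((pvals < alpha).mean())
        sd = np.sqrt(alpha * (1 - alpha) * (1 / n_genes + 1 / len(nj)))
        if (phat - alpha) / sd > z_crit:
            significant.append(j)
    return np.asarray(significant, dtype=int)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def knn_louvain(embedding: np.ndarray, k: int = 20, n_dims: int | None = None,
                resolution: float = 0.5, seed: int = 0) -> np.ndarray:
    """Louvain communities of the union-symmetrized Euclidean kNN graph.

    Cluster labels are renumbered by decreasing size.
    """
    X = np.asarray(embedding, dtype=float)
    if n_dims is not None:
        X = X[:, :n_dims]
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than n_cells = {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx)
             for j in row[1:]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    labels = np.asarray(part.membership)
    order = np.argsort([-np.sum(labels == c) for c in range(labels.max() + 1)],
                       kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return np.asarray([remap[int(c)] for c in labels])


def modularity(embedding: np.ndarray, labels: np.ndarray, k: int = 20,
               n_dims: int | None = None) -> float:
    """Newman modularity of a labeling on the same kNN graph."""
    X = np.asarray(embedding, dtype=float)
    if n_dims is not None:
        X = X[:, :n_dims]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx)
             for j in row[1:]}
    g = ig.Graph(n=X.shape[0], edges=sorted(edges), directed=False)
    return float(g.modularity(list(labels)))


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def _bimod_loglik(x: np.ndarray) -> float:
    """Log-likelihood of the point-mass-at-zero + log-normal mixture at its
    MLE (pi = detection rate; normal fit on the positive log values)."""
    n = len(x)
    pos = x[x > 0]
    k = len(pos)
    ll = 0.0
    if 0 < k < n:
        pi = k / n
        ll += (n - k) * np.log(1 - pi) + k * np.log(pi)
    if k > 0:
        sd = max(pos.std(), 1e-3)
        ll += float(np.sum(stats.norm.logpdf(pos, pos.mean(), sd)))
    return ll


def bimod_lr_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-group bimodal likelihood-ratio test p-value (chi2, df = 3)."""
    pooled = np.concatenate([a, b])
    lr = 2.0 * (_bimod_loglik(a) + _bimod_loglik(b) - _bimod_loglik(pooled))
    return float(stats.chi2.sf(max(lr, 0.0), df=3))


def find_markers(norm: np.ndarray, genes: pd.DataFrame, clusters: np.ndarray,
                 params: ScParams | None = None,
                 test: str = "bimod") -> pd.DataFrame:
    """Per-cluster marker table (one-vs-rest).

    Candidates must be detected in more than ``marker_min_pct`` of the
    target cluster's cells and show a mean normalized-expression difference
    above ``marker_logfc_thresh``. ``test`` is "bimod" (likelihood-ratio)
    or "wilcoxon". Rows are sorted by p-value ascending within cluster.
    """
    params = params or ScParams()
    clusters = np.asarray(clusters)
    rows = []
    for c in np.unique(clusters):
        in_c = clusters == c
        if in_c.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped",
                          stacklevel=2)
            continue
        A, B = norm[:, in_c], norm[:, ~in_c]
        pct_in = (A > 0).mean(axis=1)
        pct_out = (B > 0).mean(axis=1)
        diff = A.mean(axis=1) - B.mean(axis=1)
        cand = np.flatnonzero((pct_in > params.marker_min_pct) &
                              (diff > params.marker_logfc_thresh))
        for gidx in cand:
            if test == "bimod":
                p = bimod_lr_test(A[gidx], B[gidx])
            elif test == "wilcoxon":
                p = float(stats.mannwhitneyu(A[gidx], B[gidx],
                                             alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append((genes["gene"].iloc[gidx], int(c), p,
                         float(pct_in[gidx]), float(pct_out[gidx]),
                         float(diff[gidx])))
    table = pd.DataFrame(rows, columns=["gene", "cluster", "p", "pct_in",
                                        "pct_out", "log_fc"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table = (table.sort_values(["cluster", "p"], kind="stable")
                 .reset_index(drop=True))
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table


# ---------------------------------------------------------------------------
# noise-model feature selection
# ---------------------------------------------------------------------------

def feature_select_noise_model(cm: CountMatrix, n_top: int) -> pd.DataFrame:
    """Rank genes by positive residual of a log-log CV^2 vs mean fit.

    Genes whose squared coefficient of variation exceeds the global
    mean-variance trend carry signal beyond sampling noise; the top
    ``n_top`` are returned (all genes, with a warning, if n_top exceeds
    the gene count).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    X = cm.X.toarray().astype(float)
    mean = X.mean(axis=1)
    var = X.var(axis=1)
    ok = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(ok, var / mean ** 2, np.nan)
    usable = ok & (cv2 > 0)
    coef = np.polyfit(np.log(mean[usable]), np.log(cv2[usable]), deg=1)
    resid = np.full(len(mean), -np.inf)
    resid[usable] = np.log(cv2[usable]) - np.polyval(coef, np.log(mean[usable]))
    if n_top > len(mean):
        warnings.warn("n_top exceeds the number of genes; returning all",
                      stacklevel=2)
        n_top = len(mean)
    order = np.argsort(-resid, kind="stable")[:n_top]
    return pd.DataFrame({"gene": cm.genes["gene"].iloc[order].to_numpy(),
                         "residual": resid[order]})


# ---------------------------------------------------------------------------
# enrichment network
# ---------------------------------------------------------------------------

def enrichment_network(query: set[str], annotation: dict[str, set[str]],
                       universe: set[str], params: ScParams | None = None
                       ) -> tuple[pd.DataFrame, nx.Graph]:
    """Hypergeometric term enrichment plus a Jaccard similarity network.

    For each term: one-sided hypergeometric p of |query & term| given the
    universe; Benjamini-Hochberg FDR across terms; terms kept iff
    p < term_p and Q < fdr_q; edges between kept terms iff the Jaccard
    index of their (universe-restricted) gene sets >= jaccard_min.
    """
    params = params or ScParams()
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    M, N = len(universe), len(query)
    rows, term_sets = [], {}
    for term, genes in annotation.items():
        tg = set(genes) & universe
        term_sets[term] = tg
        k = len(query & tg)
        p = float(stats.hypergeom.sf(k - 1, M, len(tg), N)) if tg else 1.0
        rows.append((term, len(tg), k, p))
    table = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    table["q"] = multipletests(table["p"], method="fdr_bh")[1] if len(table) else []
    table["kept"] = (table["p"] < params.term_p) & (table["q"] < params.fdr_q)
    kept = table[table["kept"]]["term"].tolist()
    graph = nx.Graph()
    graph.add_nodes_from(kept)
    for i, t1 in enumerate(kept):
        for t2 in kept[i + 1:]:
            u = term_sets[t1] | term_sets[t2]
            if u:
                jac = len(term_sets[t1] & term_sets[t2]) / len(u)
                if jac >= params.jaccard_min:
                    graph.add_edge(t1, t2, jaccard=jac)
    return table.sort_values("p", kind="stable").reset_index(drop=True), graph
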