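"""Single-cell expression pipeline.

QC filtering, median-library normalization, permutation-calibrated PC
selection, silhouette-optimized kNN/Louvain clustering, presence-absence
binomial marker detection, a simplified negative-binomial Wald test for
differential expression between genotypes within a cluster, and the
length-binned fold-change statistic that exposes long-gene-biased
downregulation.

The cell x gene container throughout is an :class:`anndata.AnnData` with
integer counts in ``X`` and gene annotation (``length`` in bp, boolean
``mito``) in ``var``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "ClusterAssignment",
    "DEResult",
    "qc_filter",
    "normalize",
    "select_pcs",
    "cluster",
    "marker_genes",
    "differential_expression",
    "length_bin_curve",
    "long_gene_summary",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series            # cell id -> cluster label (int)
    k_neighbors: int             # chosen neighbor count
    n_pcs: int                   # PCs the graph was built on
    silhouette: float
    silhouette_by_k: dict = field(default_factory=dict)


@dataclass
class DEResult:
    """Per-gene differential expression (cKO vs WT) within one cluster."""

    table: pd.DataFrame          # index gene; log2fc, p, p_adj, mu_wt, mu_cko
    excluded: list = field(default_factory=list)  # all-zero genes not tested

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 300,
    max_mito_frac: float = 0.10,
    min_cells: int = 3,
) -> ad.AnnData:
    """Remove low-complexity / high-mitochondrial cells, then rare genes.

    A cell is kept when it expresses at least ``min_genes`` distinct genes
    and its mitochondrial UMI fraction is at most ``max_mito_frac``; genes
    are then kept when detected in at least ``min_cells`` of the surviving
    cells.  Raises if everything is filtered rather than returning an
    empty matrix.
    """
    if "mito" not in adata.var:
        raise ValueError("gene annotation must carry a 'mito' flag")
    X = _counts(adata)
    detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    mito_counts = X[:, adata.var["mito"].to_numpy()].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    keep_cells = (detected >= min_genes) & (mito_frac <= max_mito_frac)
    if not keep_cells.any():
        raise ValueError("all cells removed by QC filter")
    sub = adata[keep_cells].copy()
    Xs = _counts(sub)
    keep_genes = (Xs > 0).sum(axis=0) >= min_cells
    if not keep_genes.any():
        raise ValueError("all genes removed by QC filter")
    return sub[:, keep_genes].copy()


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Scale each cell to the median library size, then log(1 + x).

    Zeros map to zeros and within-cell rank order is preserved.  The
    normalized matrix is returned in ``X`` with the raw counts kept in
    ``layers['counts']``.
    """
    X = _counts(adata).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = list(adata.obs_names[totals == 0])
        raise ValueError(f"cells with zero total count: {bad}")
    target = np.median(totals)
    norm = np.log1p(X * (target / totals)[:, None])
    out = adata.copy()
    out.layers["counts"] = _counts(adata)
    out.X = norm
    out.uns["normalization"] = {"target_sum": float(target), "log": "log1p"}
    return out


def select_pcs(
    adata_or_matrix,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    max_rank: int = 50,
) -> dict:
    """Choose the number of principal components by column permutation.

    Eigenvalues of the (column-centered) data are compared rank-by-rank
    with the chosen quantile of eigenvalues from matrices whose columns
    were independently permuted (which destroys inter-gene covariance but
    keeps marginals).  The retained count is the largest prefix of ranks
    whose observed eigenvalue exceeds its permutation quantile.  Returns
    a dict with ``n_pcs``, the observed/threshold spectra, and the
    parameters used.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _counts(adata_or_matrix) if isinstance(adata_or_matrix, ad.AnnData) \
        else np.asarray(adata_or_matrix, dtype=float)
    n, g = X.shape
    rank_cap = min(max_rank, n - 1, g)
    Xc = X - X.mean(axis=0)

    def spectrum(M):
        s = np.linalg.svd(M, compute_uv=False)
        ev = s**2 / (n - 1)
        return ev[:rank_cap]

    obs = spectrum(Xc)
    rng = np.random.default_rng(seed)
    perm_ev = np.empty((n_perm, rank_cap))
    for i in range(n_perm):
        P = np.empty_like(Xc)
        for j in range(g):
            P[:, j] = Xc[rng.permutation(n), j]
        perm_ev[i] = spectrum(P - P.mean(axis=0))
    thresh = np.quantile(perm_ev, quantile, axis=0)
    above = obs > thresh
    n_pcs = int(np.argmin(above)) if not above.all() else int(rank_cap)
    return {
        "n_pcs": n_pcs,
        "observed": obs,
        "threshold": thresh,
        "n_perm": n_perm,
        "quantile": quantile,
        "seed": seed,
    }


def _pca_coords(X: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    n_pcs = max(1, min(n_pcs, min(X.shape) - 1))
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(X)


def cluster(
    adata: ad.AnnData,
    n_pcs: int,
    k_grid=(10, 15, 20, 30, 50, 67),
    seed: int = 0,
    resolution: float = 1.0,
) -> ClusterAssignment:
    """Louvain clustering on a kNN graph with silhouette-chosen k.

    For each k in ``k_grid`` a symmetric Euclidean kNN graph is built in
    PC space, Louvain community detection is run (fixed seed), and the
    mean silhouette of the labels in PC space is computed; the labels for
    the silhouette-maximizing k are returned (smallest k on ties).
    """
    import networkx as nx
    from sklearn.metrics import silhouette_score
    from sklearn.neighbors import kneighbors_graph

    if len(k_grid) == 0:
        raise ValueError("k_grid is empty")
    X = _counts(adata)
    n = X.shape[0]
    if any(k >= n for k in k_grid):
        raise ValueError("every k must be smaller than the number of cells")
    coords = _pca_coords(X, n_pcs, seed)

    best = None
    sil_by_k: dict[int, float] = {}
    for k in sorted(k_grid):
        A = kneighbors_graph(coords, n_neighbors=k, mode="connectivity")
        A = A.maximum(A.T)
        G = nx.from_scipy_sparse_array(A)
        comms = nx.community.louvain_communities(
            G, resolution=resolution, seed=seed
        )
        labels = np.empty(n, dtype=int)
        for ci, comm in enumerate(sorted(comms, key=min)):
            labels[list(comm)] = ci
        if len(set(labels)) < 2:
            sil = -1.0
        else:
            sil = float(silhouette_score(coords, labels))
        sil_by_k[k] = sil
        if best is None or sil > best[0]:
            best = (sil, k, labels)
    sil, k, labels = best
    return ClusterAssignment(
        labels=pd.Series(labels, index=adata.obs_names, name="cluster"),
        k_neighbors=int(k),
        n_pcs=int(n_pcs),
        silhouette=float(sil),
        silhouette_by_k=sil_by_k,
    )


def marker_genes(
    adata: ad.AnnData,
    clusters: pd.Series,
    min_log2fc: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Presence-absence binomial marker test per cluster.

    For each gene and cluster, the number of in-cluster cells detecting
    the gene is compared with the out-of-cluster detection rate via a
    one-sided (enrichment) binomial tail, p = P(X >= d_in) with
    X ~ Binomial(n_in, max(f_out, 1/n_out)); the pseudorate floor avoids
    degenerate p-values when the gene is absent outside.  Genes with
    p < alpha and mean log2 fold change (normalized expression,
    pseudocount 1) > ``min_log2fc`` are reported.
    """
    labels = clusters.loc[adata.obs_names].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    X = _counts(adata).astype(float)
    detected = X > 0
    rows = []
    for cl in uniq:
        inside = labels == cl
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in == 0 or n_out == 0:
            raise ValueError(f"cluster {cl} is empty or covers all cells")
        d_in = detected[inside].sum(axis=0)
        d_out = detected[~inside].sum(axis=0)
        rate = np.maximum(d_out / n_out, 1.0 / n_out)
        p = sps.binom.sf(d_in - 1, n_in, rate)
        mean_in = np.log2(X[inside].mean(axis=0) + 1.0)
        mean_out = np.log2(X[~inside].mean(axis=0) + 1.0)
        log2fc = mean_in - mean_out
        flag = (p < alpha) & (log2fc > min_log2fc)
        for gi in np.flatnonzero(flag):
            rows.append((cl, adata.var_names[gi], float(log2fc[gi]), float(p[gi]),
                         int(d_in[gi]), n_in, float(rate[gi])))
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "log2fc", "p", "detected_in", "n_in",
                       "rate_out"]
    ).sort_values(["cluster", "p"]).reset_index(drop=True)


def differential_expression(
    adata: ad.AnnData,
    genotype: str | pd.Series = "genotype",
    cells=None,
    pseudocount: float = 1e-2,
    min_cells: int = 3,
) -> DEResult:
    """Simplified negative-binomial Wald test, cKO vs WT, on raw counts.

    Per gene, group means are fitted per genotype; a common dispersion is
    estimated by method of moments (variance = mu + alpha mu^2); the Wald
    statistic is the log-mean difference over its delta-method standard
    error, Var(log mu_hat) ~ (1/n)(1/mu + alpha).  P-values are two-sided
    normal and BH-adjusted across tested genes.  Genes with all-zero
    counts in both groups are excluded and recorded.
    """
    if cells is not None:
        adata = adata[cells]
    geno = (adata.obs[genotype] if isinstance(genotype, str)
            else genotype.loc[adata.obs_names])
    X = (adata.layers["counts"] if "counts" in adata.layers else _counts(adata))
    X = np.asarray(X, dtype=float)
    wt = geno.to_numpy() == "WT"
    cko = geno.to_numpy() == "cKO"
    if wt.sum() < min_cells or cko.sum() < min_cells:
        raise ValueError("need >= %d cells of each genotype" % min_cells)

    mu_w, mu_k = X[wt].mean(axis=0), X[cko].mean(axis=0)
    var_w, var_k = X[wt].var(axis=0, ddof=1), X[cko].var(axis=0, ddof=1)
    tested = (mu_w > 0) | (mu_k > 0)
    excluded = list(adata.var_names[~tested])

    # pooled method-of-moments dispersion alpha = (s^2 - mu) / mu^2, floored
    with np.errstate(invalid="ignore", divide="ignore"):
        a_w = (var_w - mu_w) / np.maximum(mu_w, 1e-12) ** 2
        a_k = (var_k - mu_k) / np.maximum(mu_k, 1e-12) ** 2
    alpha_mom = np.clip(np.nanmean(np.vstack([a_w, a_k]), axis=0), 1e-8, 100.0)

    mw = np.maximum(mu_w, pseudocount)
    mk = np.maximum(mu_k, pseudocount)
    se2 = (1 / mw + alpha_mom) / wt.sum() + (1 / mk + alpha_mom) / cko.sum()
    z = (np.log(mk) - np.log(mw)) / np.sqrt(se2)
    p = 2 * sps.norm.sf(np.abs(z))
    log2fc = np.log2((mu_k + pseudocount) / (mu_w + pseudocount))

    tbl = pd.DataFrame(
        {
            "log2fc": log2fc[tested],
            "p": p[tested],
            "mu_wt": mu_w[tested],
            "mu_cko": mu_k[tested],
            "z": z[tested],
        },
        index=adata.var_names[tested],
    )
    tbl["p_adj"] = bh_adjust(tbl["p"].to_numpy())
    return DEResult(table=tbl, excluded=excluded)


def length_bin_curve(
    de: DEResult, annot: pd.DataFrame, bin_size: int = 200
) -> pd.DataFrame:
    """Mean log2 fold change in consecutive bins of genes ordered by length.

    Genes are stably sorted by annotated length (ascending) and grouped
    into bins of ``bin_size`` (the last bin may be smaller); each bin
    reports its mean gene length, mean log2FC, and gene count.
    """
    genes = de.table.index
    if not genes.isin(annot.index).all():
        missing = genes[~genes.isin(annot.index)]
        raise ValueError(f"genes without length annotation: {list(missing[:5])}")
    lengths = annot.loc[genes, "length"]
    order = np.argsort(lengths.to_numpy(), kind="stable")
    L = lengths.to_numpy()[order]
    fc = de.table["log2fc"].to_numpy()[order]
    rows = []
    for start in range(0, len(L), bin_size):
        sl = slice(start, start + bin_size)
        rows.append((float(L[sl].mean()), float(fc[sl].mean()), int(len(L[sl]))))
    return pd.DataFrame(rows, columns=["mean_length", "mean_log2fc", "n_genes"])


def long_gene_summary(de: DEResult, annot: pd.DataFrame, alpha: float = 0.05):
    """Mean length of significantly downregulated genes vs all tested genes.

    Returns ``(mean_down_bp, mean_all_bp, ratio)``; ratio is NaN (flagged)
    when no gene is significantly downregulated.
    """
    lengths = annot.loc[de.table.index, "length"]
    down = de.table[(de.table["p_adj"] < alpha) & (de.table["log2fc"] < 0)]
    mean_all = float(lengths.mean())
    if len(down) == 0:
        return float("nan"), mean_all, float("nan")
    mean_down = float(annot.loc[down.index, "length"].mean())
    return mean_down, mean_all, mean_down / mean_all
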