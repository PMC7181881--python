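"""Single-neuron copy-number pipeline.

Binned read counts are normalized to copy-number estimates (autosome-wide
mean 2 per cell), segmented per chromosome by circular binary segmentation
(CBS) with a permutation test on the arc statistic, and thresholded into
deletion/duplication calls using cut-points derived from a Gaussian
mixture fitted to the pooled, bin-count-weighted segment means.  Two
post-filters guard against amplification artifacts: recurrently-called
"hotspot" regions (>= 6 overlapping calls) and a minimum event size
(5 Mb).  Prevalence per group is compared with Fisher's exact test.

Coordinates are 0-based half-open bp internally (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import fisher_exact

__all__ = [
    "MixtureFit",
    "normalize_bins",
    "cbs_segment",
    "best_arc",
    "fit_threshold_mixture",
    "mixture_thresholds",
    "qc_cells",
    "call_cnvs",
    "hotspot_filter",
    "size_filter",
    "prevalence",
]

SEGMENT_COLUMNS = ["cell", "chrom", "start_bin", "end_bin", "start", "end",
                   "mean_cn", "n_bins"]
CALL_COLUMNS = ["cell", "chrom", "start", "end", "type", "mean_cn", "n_bins"]


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def normalize_bins(
    counts: pd.DataFrame, bins: pd.DataFrame, bias_correct: bool = False
) -> pd.DataFrame:
    """Normalize binned read counts to copy-number estimates.

    Per cell, CN_b = 2 * count_b / mean(counts); the autosome-wide mean of
    every profile is exactly 2.  With ``bias_correct`` the cohort median
    profile is divided out first (recurrent per-bin amplification bias),
    then the profile is rescaled back to mean 2.
    """
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = list(counts.index[totals <= 0])
        raise ValueError(f"cells with zero total count: {bad}")
    cn = 2.0 * X / X.mean(axis=1, keepdims=True)
    if bias_correct:
        med = np.median(cn, axis=0)
        med = np.where(med > 0, med, 1.0)
        cn = cn / med * 2.0
        cn = 2.0 * cn / cn.mean(axis=1, keepdims=True)
    return pd.DataFrame(cn, index=counts.index, columns=counts.columns)


# ----------------------------------------------------------------------
# circular binary segmentation
# ----------------------------------------------------------------------

def _arc_indices(n: int, min_width: int):
    """Valid arcs (i, j), 0 <= i < j <= n, for a segment of n bins.

    The arc [i, j) must span >= min_width bins, its circular complement
    >= min_width bins, and any nonempty linear flank ([0,i) or [j,n))
    must also be >= min_width so every resulting segment obeys the
    minimum width.
    """
    i_all, j_all = [], []
    for i in range(n + 1):
        if i != 0 and i < min_width:
            continue
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            if j != n and n - j < min_width:
                continue
            i_all.append(i)
            j_all.append(j)
    return np.asarray(i_all, dtype=np.intp), np.asarray(j_all, dtype=np.intp)


def _arc_stats(cumsum: np.ndarray, n: int, i_idx, j_idx, sd: float):
    """|t|-like arc statistic for all valid arcs given cumulative sums.

    cumsum may be (n+1,) or (batch, n+1); returns matching shape of arc
    statistics.
    """
    total = cumsum[..., -1:]
    A = cumsum[..., j_idx] - cumsum[..., i_idx]
    k = (j_idx - i_idx).astype(float)
    mean_in = A / k
    mean_out = (total - A) / (n - k)
    denom = sd * np.sqrt(1.0 / k + 1.0 / (n - k))
    return np.abs(mean_in - mean_out) / denom


def best_arc(x: np.ndarray, min_width: int = 5):
    """Arg-max arc of the CBS statistic on one segment.

    Returns ``(i, j, stat)`` or ``None`` when no valid arc exists or the
    segment is constant.  Ties break to the smallest (i, j) in
    lexicographic order.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    i_idx, j_idx = _arc_indices(n, min_width)
    if i_idx.size == 0:
        return None
    sd = x.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        return None
    S = np.concatenate([[0.0], np.cumsum(x)])
    stats = _arc_stats(S, n, i_idx, j_idx, sd)
    m = stats.max()
    # an arc and its complement give the same statistic up to rounding:
    # break ties (within numerical noise) to the smallest (i, j)
    a = int(np.flatnonzero(stats >= m - 1e-9 * (1.0 + m))[0])
    return int(i_idx[a]), int(j_idx[a]), float(stats[a])


def _split_segment(x, alpha, min_width, n_perm, rng, batch=50):
    """Test one segment for a split; returns (i, j) breakpoints or None.

    Permutation p-value (1 + #{perm max >= observed max}) / (1 + n_perm)
    with sequential early stopping: permutation batches are abandoned as
    soon as the p-value can no longer drop below alpha.
    """
    res = best_arc(x, min_width)
    if res is None:
        return None
    i_star, j_star, obs = res
    n = x.size
    i_idx, j_idx = _arc_indices(n, min_width)
    sd = x.std(ddof=1)
    exceed, done = 0, 0
    max_exceed = alpha * (n_perm + 1) - 1  # beyond this p >= alpha
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        S = np.concatenate(
            [np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1
        )
        stats = _arc_stats(S, n, i_idx, j_idx, sd)
        exceed += int((stats.max(axis=1) >= obs - 1e-12).sum())
        done += b
        if exceed > max_exceed:
            return None
    p = (1 + exceed) / (1 + n_perm)
    if p >= alpha:
        return None
    return i_star, j_star


def _segment_chromosome(x, alpha, min_width, n_perm, rng):
    """Recursive CBS on one chromosome; returns sorted breakpoint list."""
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        res = _split_segment(x[lo:hi], alpha, min_width, n_perm, rng)
        if res is None:
            return
        i, j = res
        cuts = [c for c in (lo + i, lo + j) if lo < c < hi]
        breaks.extend(cuts)
        edges = sorted({lo, *cuts, hi})
        for a, b in zip(edges, edges[1:]):
            recurse(a, b)

    recurse(0, x.size)
    return sorted(set(breaks))


def cbs_segment(
    profiles: pd.DataFrame,
    bins: pd.DataFrame,
    alpha: float = 0.001,
    min_width: int = 5,
    undo_sd: float = 0.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Circular binary segmentation of every cell's profile, per chromosome.

    Recursively finds the arc maximizing the two-sample t-like statistic
    between inside/outside means and accepts the split when the
    permutation p-value is below ``alpha``; ``min_width`` is the minimum
    segment width in bins, ``undo_sd = 0`` disables merge-back (a value
    > 0 re-merges neighbours whose means differ by less than
    undo_sd * residual SD).  Returns a segment table (one row per cell
    per segment) with bin-index and bp coordinates and arithmetic segment
    means.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    chroms = bins["chrom"].to_numpy()
    rows = []
    for cell in profiles.index:
        prof = profiles.loc[cell].to_numpy(dtype=float)
        for chrom in pd.unique(chroms):
            sel = np.flatnonzero(chroms == chrom)
            x = prof[sel]
            breaks = _segment_chromosome(x, alpha, min_width, n_perm, rng)
            edges = [0, *breaks, x.size]
            if undo_sd > 0 and len(edges) > 2:
                edges = _undo_splits(x, edges, undo_sd)
            for a, b in zip(edges, edges[1:]):
                g0, g1 = sel[a], sel[b - 1]
                rows.append(
                    (cell, chrom, int(g0), int(g1),
                     int(bins["start"].iloc[g0]), int(bins["end"].iloc[g1]),
                     float(x[a:b].mean()), int(b - a))
                )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _undo_splits(x, edges, undo_sd):
    """Merge adjacent segments whose means differ by < undo_sd * resid SD."""
    while len(edges) > 2:
        means = [x[a:b].mean() for a, b in zip(edges, edges[1:])]
        resid = np.concatenate(
            [x[a:b] - m for (a, b), m in zip(zip(edges, edges[1:]), means)]
        )
        sd = resid.std(ddof=1) if resid.size > 1 else 0.0
        diffs = np.abs(np.diff(means))
        if sd == 0 or diffs.size == 0 or diffs.min() >= undo_sd * sd:
            break
        k = int(np.argmin(diffs))
        edges = edges[: k + 1] + edges[k + 2:]
    return edges


# ----------------------------------------------------------------------
# mixture thresholds
# ----------------------------------------------------------------------

@dataclass
class MixtureFit:
    """1-D Gaussian mixture over pooled segment means, with CNV thresholds.

    ``del_thr`` / ``dup_thr`` are the density-intersection points between
    the neutral (mean nearest 2) component and its lower / upper flanking
    components; when a flank is absent the fallback is neutral mean
    -/+ 2.5 neutral SD.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    del_thr: float = field(init=False)
    dup_thr: float = field(init=False)
    neutral: int = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        self.neutral = int(np.argmin(np.abs(self.means - 2.0)))
        self.del_thr, self.dup_thr = mixture_thresholds(
            self.weights, self.means, self.sds, self.neutral
        )


def _gaussian_intersection(w1, m1, s1, w2, m2, s2):
    """Point between m1 < m2 where the two weighted densities are equal."""
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return None
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            return None
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                          (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > min(m1, m2)) & (roots < max(m1, m2))]
    return float(inside[0]) if inside.size else None


def mixture_thresholds(weights, means, sds, neutral: int | None = None,
                       min_separation: float = 0.5):
    """Deletion/duplication cut-points from mixture parameters.

    A flanking component counts only when its mean is separated from the
    neutral mean by at least ``min_separation`` copies (default 0.5: a
    genuine flank is nearer the adjacent integer copy state than the
    neutral one; this guards against the mixture splitting the neutral
    mass when no CNVs of that sign exist).
    When a flank is absent the fallback is the pooled neutral mean -/+
    2.5 pooled neutral SD, where "pooled" merges every component within
    the separation window of the neutral mean -- using a single split
    component's narrowed SD would understate the neutral spread.
    """
    weights = np.asarray(weights, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if neutral is None:
        neutral = int(np.argmin(np.abs(means - 2.0)))
    m0, s0, w0 = means[neutral], sds[neutral], weights[neutral]

    near = np.abs(means - m0) < min_separation
    w_n = weights[near]
    m_pool = float(np.sum(w_n * means[near]) / w_n.sum())
    v_pool = float(np.sum(w_n * (sds[near] ** 2 + means[near] ** 2))
                   / w_n.sum() - m_pool**2)
    s_pool = np.sqrt(max(v_pool, 0.0))

    def flank_threshold(side: int):
        if side < 0:
            cand = np.flatnonzero(means < m0 - min_separation)
        else:
            cand = np.flatnonzero(means > m0 + min_separation)
        if cand.size == 0:
            return m_pool + side * 2.5 * s_pool
        j = cand[int(np.argmin(np.abs(means[cand] - m0)))]
        x = _gaussian_intersection(
            *((weights[j], means[j], sds[j], w0, m0, s0) if side < 0
              else (w0, m0, s0, weights[j], means[j], sds[j]))
        )
        return x if x is not None else m_pool + side * 2.5 * s_pool
    return float(flank_threshold(-1)), float(flank_threshold(+1))


def fit_threshold_mixture(
    segments: pd.DataFrame, K: int = 3, seed: int = 0
) -> MixtureFit:
    """EM fit of a K-component Gaussian mixture to pooled segment means.

    Segment means are replicated by their bin counts (length weighting)
    before fitting (k-means init, 10 restarts, tol 1e-8, <= 500
    iterations).  The neutral component is the one with mean nearest 2;
    thresholds come from :func:`mixture_thresholds`.
    """
    from sklearn.mixture import GaussianMixture

    if len(segments) < 10:
        raise ValueError(
            "fewer than 10 pooled segments; use fixed thresholds instead"
        )
    data = np.repeat(
        segments["mean_cn"].to_numpy(dtype=float),
        segments["n_bins"].to_numpy(dtype=int),
    )[:, None]
    K = min(K, len(np.unique(data)))
    gm = GaussianMixture(
        n_components=K, n_init=10, init_params="kmeans",
        tol=1e-8, max_iter=500, reg_covar=1e-6, random_state=seed,
    ).fit(data)
    return MixtureFit(
        weights=gm.weights_,
        means=gm.means_.ravel(),
        sds=np.sqrt(gm.covariances_.ravel()),
    )


# ----------------------------------------------------------------------
# per-cell QC
# ----------------------------------------------------------------------

def qc_cells(
    profiles: pd.DataFrame, segments: pd.DataFrame, cutoff: float = -1.5
):
    """BIC-based amplification-quality score; keep cells scoring > cutoff.

    Each cell is compared against a "clean" reference model: bins are
    Gaussian around the integer-rounded copy state of their segment with
    the cohort-typical noise variance (median per-cell residual
    variance).  The score is the per-bin BIC difference between that
    reference model and the cell's own continuous segment-mean Gaussian,

        score = 1 + ln(v_cell / v_ref) - SS_int / (n v_ref),

    which is ~0 for a well-behaved integer-copy cell, and strongly
    negative when the cell's noise exceeds the cohort's or its segment
    means sit away from integer states.  Returns ``(kept cell index,
    score Series)``.
    """
    resid_cont: dict = {}
    resid_int: dict = {}
    for cell, seg in segments.groupby("cell", sort=False):
        prof = profiles.loc[cell].to_numpy(dtype=float)
        rc, ri = [], []
        for _, row in seg.iterrows():
            x = prof[int(row["start_bin"]): int(row["end_bin"]) + 1]
            m = row["mean_cn"]
            rc.append(x - m)
            ri.append(x - max(0.0, round(m)))
        resid_cont[cell] = np.concatenate(rc)
        resid_int[cell] = np.concatenate(ri)
    v_ref = max(float(np.median([r.var() for r in resid_cont.values()])),
                1e-12)
    scores = {}
    for cell in resid_cont:
        v_c = max(resid_cont[cell].var(), 1e-12)
        ss_i = float((resid_int[cell] ** 2).mean())
        scores[cell] = float(1.0 + np.log(v_c / v_ref) - ss_i / v_ref)
    score = pd.Series(scores, name="qc_score")
    kept = score.index[score > cutoff]
    return kept, score


# ----------------------------------------------------------------------
# calling and filters
# ----------------------------------------------------------------------

def call_cnvs(segments: pd.DataFrame, mixture: MixtureFit | tuple) -> pd.DataFrame:
    """Threshold segment means into deletion/duplication calls.

    ``mixture`` may be a :class:`MixtureFit` or an explicit
    ``(del_thr, dup_thr)`` pair (e.g. the study's empirical 1.22 / 2.82).
    Abutting same-type segments within a cell (CBS occasionally splits
    one event) are merged into a single call with a bin-weighted mean.
    """
    if isinstance(mixture, MixtureFit):
        del_thr, dup_thr = mixture.del_thr, mixture.dup_thr
    else:
        del_thr, dup_thr = mixture
    rows = []
    for _, s in segments.iterrows():
        if s["mean_cn"] < del_thr:
            kind = "deletion"
        elif s["mean_cn"] > dup_thr:
            kind = "duplication"
        else:
            continue
        rows.append([s["cell"], s["chrom"], int(s["start"]), int(s["end"]),
                     kind, float(s["mean_cn"]), int(s["n_bins"])])
    merged: list[list] = []
    for row in rows:
        if merged:
            prev = merged[-1]
            if (prev[0], prev[1], prev[4]) == (row[0], row[1], row[4]) \
                    and prev[3] == row[2]:
                w1, w2 = prev[6], row[6]
                prev[3] = row[3]
                prev[5] = (prev[5] * w1 + row[5] * w2) / (w1 + w2)
                prev[6] = w1 + w2
                continue
        merged.append(row)
    return pd.DataFrame(merged, columns=CALL_COLUMNS)


def hotspot_filter(calls: pd.DataFrame, min_cnv_count: int = 6):
    """Drop calls lying entirely within recurrently-called hotspot regions.

    A hotspot is a maximal genomic interval formed by the union of
    overlapping call footprints that is overlapped by >= ``min_cnv_count``
    calls (pooled across all cells and both call types).  Returns
    ``(filtered calls, hotspot table)``.
    """
    if len(calls) == 0:
        return calls.copy(), pd.DataFrame(columns=["chrom", "start", "end", "n_calls"])
    hotspots = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        ivals = grp[["start", "end"]].sort_values("start").to_numpy()
        cur_s, cur_e, n = int(ivals[0, 0]), int(ivals[0, 1]), 1
        merged = []
        for s, e in ivals[1:]:
            if s < cur_e:
                cur_e, n = max(cur_e, int(e)), n + 1
            else:
                merged.append((cur_s, cur_e, n))
                cur_s, cur_e, n = int(s), int(e), 1
        merged.append((cur_s, cur_e, n))
        for s, e, n in merged:
            if n >= min_cnv_count:
                hotspots.append((chrom, s, e, n))
    hot_df = pd.DataFrame(hotspots, columns=["chrom", "start", "end", "n_calls"])
    keep = np.ones(len(calls), dtype=bool)
    for _, h in hot_df.iterrows():
        inside = (
            (calls["chrom"] == h["chrom"])
            & (calls["start"] >= h["start"])
            & (calls["end"] <= h["end"])
        )
        keep &= ~inside.to_numpy()
    return calls[keep].reset_index(drop=True), hot_df


def size_filter(calls: pd.DataFrame, min_length: int = 5_000_000) -> pd.DataFrame:
    """Keep calls at least ``min_length`` bp long (default 5 Mb)."""
    if len(calls) == 0:
        return calls.copy()
    keep = (calls["end"] - calls["start"]) >= min_length
    return calls[keep].reset_index(drop=True)


def prevalence(calls: pd.DataFrame, cells_by_group: dict):
    """Per-group fraction of cells carrying >= 1 CNV, plus Fisher's test.

    ``cells_by_group`` maps group label -> full list of cell ids in that
    group (carriers are counted against these totals).  Returns
    ``(DataFrame group/carriers/total/fraction, TestResult)`` with a
    two-sided Fisher exact p for the 2x2 carrier table when there are
    exactly two groups (p is NaN otherwise).
    """
    carriers = set(calls["cell"]) if len(calls) else set()
    rows = []
    for group, cells in cells_by_group.items():
        if len(cells) == 0:
            raise ValueError(f"group {group!r} is empty")
        k = sum(c in carriers for c in cells)
        rows.append((group, k, len(cells), k / len(cells)))
    df = pd.DataFrame(rows, columns=["group", "carriers", "total", "fraction"])
    test = None
    if len(df) == 2:
        tab = [
            [int(df["carriers"][0]), int(df["total"][0] - df["carriers"][0])],
            [int(df["carriers"][1]), int(df["total"][1] - df["carriers"][1])],
        ]
        test = fisher_exact(tab)
    return df, test
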