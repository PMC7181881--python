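"""smFISH object quantification.

Detects fluorescent objects in single-channel images (threshold +
connected components, optional distance-transform watershed splitting),
separates single transcripts from area-defined clusters with a
per-section size threshold, assigns spots to their nearest cell, gates
excitatory cells on >= 5 Neurod6 transcripts, and evaluates the
transcripts-per-cell formula:

    transcripts / cell = singles / cell + cluster area / mean single area

(the cluster term estimates how many transcripts a cluster holds by area
equivalents).  Per-layer genotype comparisons use two-sided t-tests over
per-section means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TestResult, ttest_raw

__all__ = [
    "detect_objects",
    "split_singles_clusters",
    "assign_to_cells",
    "quantify_cells",
    "gate_neurod6",
    "ptprd_per_cell_section",
    "layer_compare",
]


def detect_objects(
    image: np.ndarray,
    channel: str,
    intensity_threshold: float,
    section: str = "sec0",
    split_touching: bool = False,
) -> pd.DataFrame:
    """Detect objects as connected components above an intensity threshold.

    Returns a spot table (spot_id, channel, x, y, area, section).  With
    ``split_touching`` a distance-transform watershed separates touching
    objects.  The threshold must lie within the image dynamic range.
    """
    from scipy import ndimage as ndi
    from skimage.measure import label, regionprops

    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    lo, hi = float(img.min()), float(img.max())
    if not (lo <= intensity_threshold <= hi):
        raise ValueError(
            f"threshold {intensity_threshold} outside image range [{lo}, {hi}]"
        )
    mask = img > intensity_threshold
    if split_touching and mask.any():
        from skimage.feature import peak_local_max
        from skimage.segmentation import watershed

        dist = ndi.distance_transform_edt(mask)
        coords = peak_local_max(dist, labels=mask, min_distance=2)
        markers = np.zeros_like(img, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        lab = watershed(-dist, markers, mask=mask)
    else:
        lab = label(mask, connectivity=2)
    rows = []
    for i, rp in enumerate(regionprops(lab)):
        cy, cx = rp.centroid
        rows.append((f"{section}_obj{i:05d}", channel, float(cx), float(cy),
                     float(rp.area), section))
    return pd.DataFrame(rows, columns=["spot_id", "channel", "x", "y", "area",
                                       "section"])


def split_singles_clusters(
    spots: pd.DataFrame, size_factor: float = 1.5
):
    """Flag each Ptprd spot as a single transcript or a cluster.

    A spot is a single iff its area <= ``size_factor`` x the median spot
    area of its section; larger objects are clusters.  Returns the
    annotated table (new boolean column ``is_single``) and the
    per-section mean area of the flagged singles.
    """
    if len(spots) == 0:
        raise ValueError("no spots to classify")
    out = spots.copy()
    out["is_single"] = False
    mean_single_area = {}
    for section, grp in out.groupby("section", sort=False):
        med = grp["area"].median()
        single = grp["area"] <= size_factor * med
        out.loc[grp.index[single], "is_single"] = True
        mean_single_area[section] = float(grp.loc[single, "area"].mean()) \
            if single.any() else float("nan")
    return out, pd.Series(mean_single_area, name="mean_single_area")


def assign_to_cells(
    spots: pd.DataFrame, cells: pd.DataFrame, max_radius: float
) -> pd.DataFrame:
    """Assign each spot to the nearest cell centroid within ``max_radius``.

    Ties in distance break deterministically to the smallest cell id.
    Returns the spot table with an ``assigned_cell`` column (None when no
    cell is close enough).  Spots and cells are matched within sections.
    """
    out = spots.copy()
    out["assigned_cell"] = None
    for section, sgrp in out.groupby("section", sort=False):
        cgrp = cells[cells["section"] == section]
        if len(cgrp) == 0:
            continue
        # sort candidate cells by id so np.argmin's first-match = smallest id
        cgrp = cgrp.sort_values("cell_id")
        cx = cgrp["x"].to_numpy()
        cy = cgrp["y"].to_numpy()
        ids = cgrp["cell_id"].to_numpy()
        d2 = (
            (sgrp["x"].to_numpy()[:, None] - cx[None, :]) ** 2
            + (sgrp["y"].to_numpy()[:, None] - cy[None, :]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(len(sgrp)), nearest])
        assigned = np.where(dist <= max_radius, ids[nearest], None)
        out.loc[sgrp.index, "assigned_cell"] = assigned
    return out


def quantify_cells(spots: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cell quantification from assigned, single/cluster-annotated spots.

    Returns one row per cell: neurod6_count, ptprd_singles,
    ptprd_clusters, ptprd_cluster_area, with section and layer carried
    over from the cell table.
    """
    q = cells[["cell_id", "section", "layer"]].copy()
    assigned = spots[spots["assigned_cell"].notna()]
    nd6 = assigned[assigned["channel"] == "Neurod6"].groupby("assigned_cell").size()
    pt = assigned[assigned["channel"] == "Ptprd"]
    singles = pt[pt["is_single"]].groupby("assigned_cell").size()
    clusters = pt[~pt["is_single"]].groupby("assigned_cell").size()
    carea = pt[~pt["is_single"]].groupby("assigned_cell")["area"].sum()
    q["neurod6_count"] = q["cell_id"].map(nd6).fillna(0).astype(int)
    q["ptprd_singles"] = q["cell_id"].map(singles).fillna(0).astype(int)
    q["ptprd_clusters"] = q["cell_id"].map(clusters).fillna(0).astype(int)
    q["ptprd_cluster_area"] = q["cell_id"].map(carea).fillna(0.0)
    return q


def gate_neurod6(cellquants: pd.DataFrame, min_transcripts: int = 5) -> pd.DataFrame:
    """Keep Neurod6+ cells: at least ``min_transcripts`` Neurod6 spots."""
    return cellquants[cellquants["neurod6_count"] >= min_transcripts].copy()


def ptprd_per_cell_section(
    cellquants: pd.DataFrame,
    mean_single_area: float,
    literal: bool = False,
):
    """Transcripts per Neurod6+ cell for one section.

    Per gated cell: singles + cluster area / mean single-spot area of the
    section (area-equivalents estimate of transcripts per cluster).  With
    ``literal=True`` the cluster term is instead the cluster COUNT divided
    by the mean single area, the formula's literal (dimensionally odd)
    reading, kept for comparison.  Returns ``(per-cell Series, section
    mean)``; the mean is NaN when the section has no single spots (the
    cluster term is then undefined and the section must be excluded).
    """
    if not np.isfinite(mean_single_area) or mean_single_area <= 0:
        return None, float("nan")
    q = cellquants
    if literal:
        cluster_term = q["ptprd_clusters"] / mean_single_area
    else:
        cluster_term = q["ptprd_cluster_area"] / mean_single_area
    per_cell = q["ptprd_singles"] + cluster_term
    per_cell.index = q["cell_id"].to_numpy()
    return per_cell, float(per_cell.mean()) if len(per_cell) else float("nan")


def layer_compare(
    section_values: pd.DataFrame,
    value_col: str = "value",
    variant: str = "pooled",
) -> pd.DataFrame:
    """Per-layer two-sided t-test of per-section means between genotypes.

    ``section_values`` has one row per (section, layer) with columns
    section, layer, genotype and ``value_col``.  Requires >= 2 sections
    per genotype per layer.  Returns a table with per-layer group means,
    t, df and p.
    """
    rows = []
    for layer, grp in section_values.groupby("layer", sort=False):
        wt = grp.loc[grp["genotype"] == "WT", value_col].to_numpy()
        ko = grp.loc[grp["genotype"] == "cKO", value_col].to_numpy()
        if len(wt) < 2 or len(ko) < 2:
            raise ValueError(f"layer {layer}: need >= 2 sections per genotype")
        res: TestResult = ttest_raw(wt, ko, variant=variant)
        rows.append((layer, float(wt.mean()), float(ko.mean()),
                     res.statistic, res.df, res.p))
    return pd.DataFrame(
        rows, columns=["layer", "mean_wt", "mean_cko", "t", "df", "p"]
    )
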