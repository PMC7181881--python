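"""Readers/writers for the pipeline's on-disk formats.

Count matrices travel as MatrixMarket (.mtx) plus row/column id TSVs,
gene annotation as a TSV (gene, length, mito), genomic bins as BED
(0-based half-open), spot/cell/survival tables as CSV, images as TIFF,
and every generated dataset can carry a JSON sidecar recording the
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write a cells x genes (or bins) count matrix as MTX + id TSVs."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix) + ".mtx", csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(str(prefix) + ".rows.tsv",
                                   sep="\t", index=False, header=False)
    pd.Series(counts.columns.astype(str)).to_csv(
        str(prefix) + ".cols.tsv", sep="\t", index=False, header=False)


def read_counts_mtx(prefix) -> pd.DataFrame:
    from scipy.io import mmread

    prefix = str(prefix)
    X = np.asarray(mmread(prefix + ".mtx").todense())
    rows = pd.read_csv(prefix + ".rows.tsv", sep="\t", header=None)[0]
    cols = pd.read_csv(prefix + ".cols.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(X, index=rows, columns=cols)


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_bed(bins: pd.DataFrame, path) -> None:
    """BED (0-based half-open) for the bin table (chrom, start, end)."""
    bins[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False,
                                           header=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end"])


def write_calls(calls: pd.DataFrame, path, one_based: bool = False) -> None:
    """CNV call TSV; ``one_based`` shifts to 1-based inclusive coordinates."""
    out = calls.copy()
    if one_based:
        out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def write_tiff(image: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, image)


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_sidecar(config, path, **extra) -> None:
    """JSON sidecar capturing the generating config (dataclass) + extras."""
    payload = dataclasses.asdict(config) if dataclasses.is_dataclass(config) \
        else dict(config)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
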