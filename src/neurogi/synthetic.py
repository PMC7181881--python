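"""Seeded synthetic-data generators.

Every downstream stage in this package (expression QC/clustering/DE, the
CNV caller, smFISH and foci quantification, survival comparison) can be
exercised end-to-end on data drawn here, with truth tables sufficient to
score sensitivity and false-call rates.  The generators emulate the
structure of the study inputs:

* a cortical single-cell UMI matrix with three cell classes (excitatory /
  inhibitory neurons, glia) x two genotypes, negative-binomial counts, and
  a gene-length-dependent downregulation confined to excitatory knockout
  cells (plus one designated "Top1" gene knocked down >=4-fold there);
* per-neuron genomic bin read counts with implanted megabase-scale CNVs
  under shared-per-(cell,bin) lognormal amplification bias;
* smFISH sections with single diffraction-limited spots and area-defined
  clusters, and nuclei images with punctate DNA-damage foci;
* two-group Weibull survival times.

All randomness flows from ``SimConfig.seed`` through independent
``numpy.random.default_rng`` streams, so a fixed seed gives bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "generate_sc_dataset",
    "generate_cnv_cells",
    "generate_fish_section",
    "generate_foci_image",
    "generate_foci_experiment",
    "generate_survival_data",
    "cnv_prevalence_preset",
    "survival_preset",
]

CELL_CLASSES = ("excitatory", "inhibitory", "glia")
GENOTYPES = ("WT", "cKO")
MARKER_GENES = {"excitatory": "Neurod6", "inhibitory": "Gad1", "glia": "Aqp4"}
FISH_LAYERS = ("L2-4", "L5", "L6")


@dataclass
class SimConfig:
    """Study-condition parameters for all generators.

    Expression block: ``n_cells_per_class`` is cells per (class, genotype)
    combination (default 170 -> 1,020 cells total); ``length_effect_beta``
    is the log2 fold reduction per decade of gene length above
    ``long_gene_cutoff`` applied to excitatory knockout cells;
    ``nb_dispersion`` is the NB size parameter (variance mu + mu^2/theta).

    Genome block: ``n_bins`` uniform bins of ``bin_size`` bp split evenly
    over ``n_chromosomes`` autosomes; ``cnv_events`` are (chrom, start bp,
    end bp, copy in {1,3}, carrier fraction) tuples; ``amp_noise_sd`` is the
    lognormal sigma of the per-(cell,bin) amplification bias.

    Imaging block: ``spot_density`` is the expected number of single Ptprd
    transcripts per gated cell; ``cluster_fraction`` the expected fraction
    of cells' clusters relative to density; ``psf_sigma`` the Gaussian blob
    sigma in pixels.
    """

    seed: int = 0
    # single-cell expression
    n_cells_per_class: int = 170
    n_genes: int = 2000
    length_effect_beta: float = 0.5
    long_gene_cutoff: float = 100_000.0
    nb_dispersion: float = 2.0
    top1_log2fc: float = -2.0
    min_gene_length: float = 1_000.0
    max_gene_length: float = 2_500_000.0
    n_program_genes: int = 100
    # genome / CNV
    n_chromosomes: int = 19
    n_bins: int = 5000
    bin_size: int = 500_000
    cnv_events: list = field(default_factory=list)
    amp_noise_sd: float = 0.15
    n_cnv_cells: int = 100
    reads_per_bin: float = 100.0
    cnv_exact_carriers: int | None = None
    # smFISH
    spot_density: float = 8.0
    cluster_fraction: float = 0.2
    psf_sigma: float = 1.5
    fish_cells_per_layer: int = 30
    fish_depletion: float = 0.5
    single_spot_area: float = 4.0
    # foci
    foci_rate: float = 0.3
    foci_image_size: int = 256
    nucleus_radius: int = 10
    foci_poisson_noise: bool = False
    # survival
    survival_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.length_effect_beta < 0:
            raise ValueError("length_effect_beta must be >= 0")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        for ev in self.cnv_events:
            chrom, start, end, copy, frac = ev
            if end - start < self.bin_size:
                raise ValueError(f"event {ev} shorter than one bin")
            if copy not in (1, 3):
                raise ValueError(f"copy state must be 1 or 3, got {copy}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError("carrier fraction must lie in [0, 1]")

    # -- genome helpers -------------------------------------------------
    @property
    def bins_per_chrom(self) -> int:
        return self.n_bins // self.n_chromosomes

    @property
    def chrom_length(self) -> int:
        return self.bins_per_chrom * self.bin_size

    def bin_table(self) -> pd.DataFrame:
        """BED-like table (0-based half-open) of the synthetic autosomes."""
        rows = []
        for c in range(1, self.n_chromosomes + 1):
            for b in range(self.bins_per_chrom):
                rows.append((f"chr{c}", b * self.bin_size, (b + 1) * self.bin_size))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ----------------------------------------------------------------------
# single-cell expression
# ----------------------------------------------------------------------

def _gene_annotation(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    lengths = 10 ** rng.uniform(
        np.log10(cfg.min_gene_length), np.log10(cfg.max_gene_length), size=n
    )
    names = [f"gene{i:05d}" for i in range(n)]
    mito = np.zeros(n, dtype=bool)
    # 13 protein-coding mitochondrial genes, short, as in a mammalian mt genome
    mito[:13] = True
    for i in range(13):
        names[i] = f"mt-gene{i:02d}"
        lengths[i] = rng.uniform(300, 1800)
    # designated marker and Top1 genes (moderate lengths so the long-gene
    # effect does not confound the marker/knockdown structure)
    specials = list(MARKER_GENES.values()) + ["Top1"]
    for j, name in enumerate(specials):
        idx = 13 + j
        names[idx] = name
        lengths[idx] = rng.uniform(20_000, 90_000)
    return pd.DataFrame({"length": lengths, "mito": mito}, index=pd.Index(names, name="gene"))


def generate_sc_dataset(config: SimConfig) -> ad.AnnData:
    """Simulate a cell x gene UMI matrix with a long-gene knockdown.

    Counts are negative binomial around class-specific means.  In
    excitatory knockout cells each gene's mean is scaled by
    ``2**(-beta * max(0, log10 L - log10 L0))`` and the designated Top1
    gene is additionally reduced 4-fold.  Returns an AnnData with
    ``obs['cell_class']``, ``obs['genotype']``, ``var['length']``,
    ``var['mito']`` and the applied per-gene log2 fold change (excitatory
    cKO vs WT) in ``var['truth_log2fc']``.
    """
    rng = np.random.default_rng(config.seed)
    annot = _gene_annotation(config, rng)
    n_genes = config.n_genes

    base_mean = rng.lognormal(mean=np.log(0.3), sigma=1.0, size=n_genes)
    base_mean = np.clip(base_mean, 1e-3, 50.0)

    gene_index = {g: i for i, g in enumerate(annot.index)}
    class_factor = np.ones((len(CELL_CLASSES), n_genes))
    free = np.arange(13 + 4, n_genes)  # skip mito + special genes
    for ci, cls in enumerate(CELL_CLASSES):
        # canonical marker: high in own class, near-absent elsewhere
        mi = gene_index[MARKER_GENES[cls]]
        class_factor[:, mi] = 0.02
        class_factor[ci, mi] = 1.0
        base_mean[mi] = 5.0
        # a class program of moderately elevated genes for separability
        prog = rng.choice(free, size=config.n_program_genes, replace=False)
        class_factor[ci, prog] *= 3.0
    ti = gene_index["Top1"]
    base_mean[ti] = 3.0

    # truth effect (excitatory cKO vs WT), per gene
    L = annot["length"].to_numpy()
    decades = np.maximum(0.0, np.log10(L) - np.log10(config.long_gene_cutoff))
    truth_log2fc = -config.length_effect_beta * decades
    truth_log2fc[ti] += config.top1_log2fc  # designated Top1 knockdown
    effect = 2.0 ** truth_log2fc

    n = config.n_cells_per_class
    blocks, obs_class, obs_geno = [], [], []
    theta = config.nb_dispersion
    for ci, cls in enumerate(CELL_CLASSES):
        for geno in GENOTYPES:
            mu = base_mean * class_factor[ci]
            if cls == "excitatory" and geno == "cKO":
                mu = mu * effect
            mu_cells = np.broadcast_to(mu, (n, n_genes))
            p = theta / (theta + mu_cells)
            blocks.append(rng.negative_binomial(theta, p))
            obs_class += [cls] * n
            obs_geno += [geno] * n
    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(
        {"cell_class": obs_class, "genotype": obs_geno},
        index=pd.Index([f"cell{i:05d}" for i in range(X.shape[0])], name="cell"),
    )
    var = annot.copy()
    var["truth_log2fc"] = truth_log2fc
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["sim"] = {"seed": config.seed, "beta": config.length_effect_beta,
                        "long_gene_cutoff": config.long_gene_cutoff}
    return adata


# ----------------------------------------------------------------------
# CNV bin counts
# ----------------------------------------------------------------------

def _validate_events(cfg: SimConfig) -> None:
    by_chrom: dict[str, list] = {}
    for ev in cfg.cnv_events:
        chrom, start, end = ev[0], ev[1], ev[2]
        if not (0 <= start < end <= cfg.chrom_length):
            raise ValueError(f"event {ev} outside genome bounds")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping events on {chrom}")


def generate_cnv_cells(config: SimConfig):
    """Simulate per-cell genomic bin read counts with implanted CNVs.

    Each bin's expected count is base depth x copy/2 x a lognormal
    amplification bias shared per (cell, bin); counts are Poisson draws.
    Carrier cells are Bernoulli(carrier fraction) per event unless
    ``cnv_exact_carriers`` is set, in which case exactly that many cells
    (chosen at random) each carry one event, round-robin over the event
    list.  Returns ``(counts DataFrame cells x bins, bin table, truth
    DataFrame with one row per implanted event per carrier)``.
    """
    _validate_events(config)
    rng = np.random.default_rng(config.seed)
    bins = config.bin_table()
    n_cells, n_bins = config.n_cnv_cells, len(bins)
    cell_ids = [f"cnvcell{i:04d}" for i in range(n_cells)]

    copy = np.full((n_cells, n_bins), 2.0)
    truth_rows = []

    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()

    def bin_mask(chrom, start, end):
        return (chroms == chrom) & (starts >= start) & (ends <= end)

    if config.cnv_exact_carriers is not None and config.cnv_events:
        k = config.cnv_exact_carriers
        carriers = rng.choice(n_cells, size=k, replace=False)
        for j, ci in enumerate(sorted(carriers)):
            ev = config.cnv_events[j % len(config.cnv_events)]
            chrom, start, end, cp, _ = ev
            copy[ci, bin_mask(chrom, start, end)] = cp
            truth_rows.append((cell_ids[ci], chrom, start, end, cp))
    else:
        for ev in config.cnv_events:
            chrom, start, end, cp, frac = ev
            m = bin_mask(chrom, start, end)
            carrier = rng.random(n_cells) < frac
            for ci in np.flatnonzero(carrier):
                copy[ci, m] = cp
                truth_rows.append((cell_ids[ci], chrom, start, end, cp))

    lam = config.reads_per_bin * copy / 2.0
    if config.amp_noise_sd > 0:
        lam = lam * rng.lognormal(0.0, config.amp_noise_sd, size=lam.shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell"))
    truth = pd.DataFrame(
        truth_rows, columns=["cell", "chrom", "start", "end", "copy"]
    )
    return counts_df, bins, truth


def cnv_prevalence_preset(genotype: str, seed: int = 0) -> SimConfig:
    """Preset mirroring the study's CNV prevalence (24/123 WT, 60/169 cKO).

    Returns a config whose generated cohort has exactly 24 (WT) or 60 (cKO)
    carrier cells, each with one implanted >=10 Mb event.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    n_cells, n_carriers = (123, 24) if genotype == "WT" else (169, 60)
    cfg = SimConfig(
        seed=seed,
        n_cnv_cells=n_cells,
        cnv_exact_carriers=n_carriers,
        cnv_events=[
            ("chr2", 10_000_000, 25_000_000, 1, 0.0),
            ("chr5", 40_000_000, 55_000_000, 3, 0.0),
            ("chr9", 5_000_000, 20_000_000, 1, 0.0),
            ("chr13", 60_000_000, 75_000_000, 3, 0.0),
        ],
    )
    return cfg


# ----------------------------------------------------------------------
# smFISH sections
# ----------------------------------------------------------------------

def generate_fish_section(config: SimConfig, section: str = "sec0",
                          genotype: str = "WT"):
    """Simulate one smFISH section: cells on a grid with layer labels,
    Neurod6 spots per cell, and Ptprd singles/clusters.

    Singles have area ~ ``single_spot_area`` (small jitter); a cluster of k
    transcripts has area k x ``single_spot_area``.  In knockout sections the
    Ptprd transcript density in layers L5 and L6 is multiplied by
    ``fish_depletion``.  Returns ``(spots, cells)`` DataFrames; truth
    columns live on ``cells`` (``truth_neurod6``, ``truth_ptprd``).
    """
    import zlib

    rng = np.random.default_rng(
        (config.seed * 1_000_003 + zlib.crc32(section.encode()) % 65_536
         + (genotype == "cKO")) % 2**31
    )
    a0 = config.single_spot_area
    spacing, radius = 40.0, 12.0
    cells_rows, spots_rows = [], []
    spot_id = 0
    for li, layer in enumerate(FISH_LAYERS):
        for j in range(config.fish_cells_per_layer):
            cid = f"{section}_{layer}_c{j:03d}"
            cx = spacing * (j % 10) + spacing / 2
            cy = spacing * (j // 10) + li * 200.0 + spacing / 2
            is_exc = rng.random() < 0.8
            nd6 = rng.poisson(15.0) if is_exc else rng.poisson(1.0)
            mu = config.spot_density
            if genotype == "cKO" and layer in ("L5", "L6"):
                mu *= config.fish_depletion
            n_singles = rng.poisson(mu)
            mean_clusters = mu * config.cluster_fraction / 3.0
            n_clusters = rng.poisson(mean_clusters)
            truth_ptprd = n_singles
            for _ in range(nd6):
                ang, r = rng.uniform(0, 2 * np.pi), radius * np.sqrt(rng.uniform())
                spots_rows.append(
                    (f"s{spot_id:06d}", "Neurod6", cx + r * np.cos(ang),
                     cy + r * np.sin(ang), max(1.0, a0 + rng.normal(0, 0.3)),
                     section, layer, cid, 1)
                )
                spot_id += 1
            for _ in range(n_singles):
                ang, r = rng.uniform(0, 2 * np.pi), radius * np.sqrt(rng.uniform())
                spots_rows.append(
                    (f"s{spot_id:06d}", "Ptprd", cx + r * np.cos(ang),
                     cy + r * np.sin(ang), max(1.0, a0 + rng.normal(0, 0.3)),
                     section, layer, cid, 1)
                )
                spot_id += 1
            for _ in range(n_clusters):
                k = int(rng.integers(2, 6))
                truth_ptprd += k
                ang, r = rng.uniform(0, 2 * np.pi), radius * np.sqrt(rng.uniform())
                spots_rows.append(
                    (f"s{spot_id:06d}", "Ptprd", cx + r * np.cos(ang),
                     cy + r * np.sin(ang), k * a0, section, layer, cid, k)
                )
                spot_id += 1
            cells_rows.append(
                (cid, cx, cy, radius, section, layer, nd6, truth_ptprd, nd6 >= 5)
            )
    spots = pd.DataFrame(
        spots_rows,
        columns=["spot_id", "channel", "x", "y", "area", "section", "layer",
                 "truth_cell", "truth_size"],
    )
    cells = pd.DataFrame(
        cells_rows,
        columns=["cell_id", "x", "y", "radius", "section", "layer",
                 "truth_neurod6", "truth_ptprd", "truth_neurod6_pos"],
    )
    return spots, cells


# ----------------------------------------------------------------------
# foci images
# ----------------------------------------------------------------------

def generate_foci_image(config: SimConfig, seed: int | None = None,
                        n_nuclei: int = 16, rate: float | None = None):
    """Simulate a nuclei image with punctate foci.

    Nuclei are disks on a grid in a labelled mask; each nucleus carries
    ``Bernoulli(rate) * (1 + Poisson(0.7))`` foci rendered as Gaussian
    blobs (sigma ``psf_sigma``) over a flat background, separated by more
    than ``2 * psf_sigma``.  Returns ``(image uint8, label mask, truth
    counts per nucleus)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.foci_rate if rate is None else rate
    size = config.foci_image_size
    rad = config.nucleus_radius
    img = np.full((size, size), 10.0)
    labels = np.zeros((size, size), dtype=np.int32)
    yy, xx = np.mgrid[0:size, 0:size]
    per_row = max(1, size // (4 * rad))
    truth = []
    for i in range(n_nuclei):
        cx = 2 * rad + (i % per_row) * 4 * rad
        cy = 2 * rad + (i // per_row) * 4 * rad
        if cy + rad >= size:
            break
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
        labels[mask] = i + 1
        k = int(rng.random() < rate) * (1 + rng.poisson(0.7))
        placed = []
        attempts = 0
        while len(placed) < k and attempts < 200:
            ang, r = rng.uniform(0, 2 * np.pi), (rad - 2 * config.psf_sigma) * np.sqrt(rng.uniform())
            fx, fy = cx + r * np.cos(ang), cy + r * np.sin(ang)
            if all((fx - px) ** 2 + (fy - py) ** 2 > (2 * config.psf_sigma) ** 2 + 1e-9
                   for px, py in placed):
                placed.append((fx, fy))
            attempts += 1
        for fx, fy in placed:
            img += 180.0 * np.exp(
                -((xx - fx) ** 2 + (yy - fy) ** 2) / (2 * config.psf_sigma**2)
            )
        truth.append((i + 1, len(placed)))
    if config.foci_poisson_noise:
        img = rng.poisson(img).astype(float)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth_df = pd.DataFrame(truth, columns=["nucleus", "truth_foci"])
    return img, labels, truth_df


def generate_foci_experiment(config: SimConfig, rates: dict[str, float],
                             n_animals: int = 3, n_nuclei: int = 16):
    """Per-genotype, per-animal foci images.

    Returns a list of dicts with keys genotype, animal, image, labels,
    truth.  Animal-level seeds are derived from ``config.seed``.
    """
    out = []
    k = 0
    for geno, rate in rates.items():
        for a in range(n_animals):
            img, labels, truth = generate_foci_image(
                config, seed=(config.seed * 7919 + k) % 2**31,
                n_nuclei=n_nuclei, rate=rate,
            )
            out.append({"genotype": geno, "animal": f"{geno}_m{a}",
                        "image": img, "labels": labels, "truth": truth})
            k += 1
    return out


# ----------------------------------------------------------------------
# survival
# ----------------------------------------------------------------------

def survival_preset(seed: int = 0, n_per_group: tuple[int, int] = (11, 10),
                    shape: float = 8.0) -> SimConfig:
    """Two-arm preset whose group medians are 18 and 23 days in expectation.

    Weibull median = scale * ln(2)**(1/shape); scales are solved from the
    target medians.  Group sizes default to the survival experiment's 11
    and 10 animals.
    """
    ln2k = np.log(2) ** (1 / shape)
    return SimConfig(
        seed=seed,
        survival_params={
            "saline": {"shape": shape, "scale": 18.0 / ln2k, "n": n_per_group[0]},
            "NR": {"shape": shape, "scale": 23.0 / ln2k, "n": n_per_group[1]},
        },
    )


def generate_survival_data(config: SimConfig, censor_time: float | None = None):
    """Draw per-group Weibull event times; optional administrative censoring.

    Returns a list of :class:`neurogi.stats.SurvivalRecord`.
    """
    from .stats import SurvivalRecord

    if not config.survival_params:
        raise ValueError("survival_params is empty")
    rng = np.random.default_rng(config.seed)
    records = []
    for group in sorted(config.survival_params):
        pars = config.survival_params[group]
        n = int(pars["n"])
        times = pars["scale"] * rng.weibull(pars["shape"], size=n)
        for i, t in enumerate(times):
            event = True
            if censor_time is not None and t > censor_time:
                t, event = censor_time, False
            records.append(
                SurvivalRecord(f"{group}_{i:03d}", float(t), event, group)
            )
    return records
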