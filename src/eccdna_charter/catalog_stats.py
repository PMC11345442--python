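"""Descriptive statistics over eccDNA catalogs.

Normalized abundance is EPM (eccDNAs per million mapped reads): catalog
size divided by the mapped-read total, times 1e6. "Frequency" per genomic
window counts a record in the window containing its midpoint, so every
record is counted exactly once. An eccDNA *species* is a unique
(chrom, start, end) interval after pooling the requested samples; species
identity ignores read support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .formats import AnnotationTrack, EccDNACatalog, GenomeModel

__all__ = [
    "AbundanceSummary",
    "SizeDistribution",
    "GeneDerivation",
    "DensityCorrelation",
    "compute_abundance",
    "size_distribution",
    "gene_derivation",
    "density_correlation",
    "drug_sensitivity_correlation",
]


@dataclass
class AbundanceSummary:
    sample_id: str
    n_records: int
    epm: float  # eccDNAs per million mapped reads
    per_chrom_per_mb: pd.Series  # records per Mb of chromosome
    per_chrom_share: pd.Series  # per-Mb densities normalized to percentages


def compute_abundance(
    catalog: EccDNACatalog, chrom_lengths: dict[str, int]
) -> AbundanceSummary:
    """EPM and per-chromosome per-Mb percentage shares.

    Shares are the per-Mb record densities normalized to sum to 100 over
    chromosomes; an empty catalog reports EPM 0 and all-zero shares.
    """
    if catalog.mapped_read_total is None or catalog.mapped_read_total <= 0:
        raise ValueError("mapped_read_total must be positive for abundance")
    n = len(catalog)
    epm = n / catalog.mapped_read_total * 1e6
    chroms = pd.Index(chrom_lengths.keys(), name="chrom")
    counts = catalog.records["chrom"].value_counts().reindex(chroms, fill_value=0)
    mb = pd.Series({c: length / 1e6 for c, length in chrom_lengths.items()})
    per_mb = counts / mb
    total = per_mb.sum()
    share = per_mb / total * 100.0 if total > 0 else per_mb * 0.0
    return AbundanceSummary(catalog.sample_id, n, epm, per_mb, share)


@dataclass
class SizeDistribution:
    bin_width: int
    edges: np.ndarray  # bin edges [0, w, 2w, ...]
    counts: np.ndarray
    modal_bin: tuple[int, int]  # [start, end) of the modal bin; ties -> smallest start


def size_distribution(catalog: EccDNACatalog, bin_width: int = 100) -> SizeDistribution:
    """Histogram of record lengths in bins [0,w), [w,2w), ...

    Counts sum to the catalog size; the modal bin tie-break is the
    smallest bin start (``argmax`` returns the first maximum).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = catalog.lengths
    if len(lengths) == 0:
        return SizeDistribution(bin_width, np.array([0, bin_width]), np.array([0]), (0, bin_width))
    n_bins = int(lengths.max() // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lengths, bins=edges)
    mode = int(np.argmax(counts))
    return SizeDistribution(bin_width, edges, counts, (mode * bin_width, (mode + 1) * bin_width))


@dataclass
class GeneDerivation:
    per_gene: pd.Series  # gene_id -> distinct eccDNA species overlapping it
    spanned_genes: pd.Series  # species index -> number of distinct genes spanned
    spanned_histogram: pd.Series  # 1..10+ -> number of species
    n_species: int
    n_species_genic: int


def _species(catalogs: Sequence[EccDNACatalog] | EccDNACatalog) -> pd.DataFrame:
    if isinstance(catalogs, EccDNACatalog):
        catalogs = [catalogs]
    pooled = pd.concat([c.records[["chrom", "start", "end"]] for c in catalogs])
    return (
        pooled.drop_duplicates()
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )


def gene_derivation(
    catalogs: Sequence[EccDNACatalog] | EccDNACatalog, genes: AnnotationTrack
) -> GeneDerivation:
    """Per-gene species counts and per-species spanned-gene counts.

    A species counts for a gene iff their intervals overlap by >= 1 bp.
    Pooling a catalog with itself changes nothing (species dedup is
    idempotent).
    """
    gene_df = genes.subset(["gene"])
    if (gene_df["gene_id"] == "").any():
        raise ValueError("gene features must carry gene_id")
    trees: dict[str, IntervalTree] = {}
    for row in gene_df.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)
    species = _species(catalogs)
    per_gene: dict[str, int] = {gid: 0 for gid in gene_df["gene_id"]}
    spanned = np.zeros(len(species), dtype=np.int64)
    for i, row in enumerate(species.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(row.start, row.end)}
        spanned[i] = len(hits)
        for gid in hits:
            per_gene[gid] += 1
    spanned_s = pd.Series(spanned, name="spanned_genes")
    capped = np.minimum(spanned[spanned > 0], 10)
    hist = pd.Series(
        np.bincount(capped, minlength=11)[1:], index=pd.RangeIndex(1, 11, name="n_genes")
    )
    return GeneDerivation(
        per_gene=pd.Series(per_gene, name="n_species").rename_axis("gene_id"),
        spanned_genes=spanned_s,
        spanned_histogram=hist,
        n_species=len(species),
        n_species_genic=int((spanned > 0).sum()),
    )


@dataclass
class DensityCorrelation:
    window: int
    table: pd.DataFrame  # chrom, window_start, eccdna_per_mb, covariate_per_mb
    r: float
    p: float
    method: str


def _window_index(positions: np.ndarray, length: int, window: int) -> np.ndarray:
    n_windows = -(-length // window)
    return np.minimum(positions // window, n_windows - 1)


def density_correlation(
    catalogs: Sequence[EccDNACatalog] | EccDNACatalog,
    genome: GenomeModel,
    covariate_track: AnnotationTrack,
    covariate_classes: Iterable[str] = ("gene",),
    window: int = 100_000,
    method: str = "pearson",
) -> DensityCorrelation:
    """Correlate per-window eccDNA frequency with a covariate density.

    Windows tile the genome; records and covariate features are assigned
    to the window of their midpoint; both sides are expressed per Mb.
    Windows with zero covariate are retained.
    """
    if window < 10_000:
        raise ValueError("window must be >= 10 kb")
    if isinstance(catalogs, EccDNACatalog):
        catalogs = [catalogs]
    cov = covariate_track.subset(covariate_classes)
    rows = []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        n_windows = -(-length // window)
        sizes = np.minimum(np.arange(1, n_windows + 1) * window, length) - np.arange(
            n_windows
        ) * window
        ecc = np.zeros(n_windows)
        for cat in catalogs:
            rec = cat.records[cat.records["chrom"] == chrom]
            if len(rec):
                mid = ((rec["start"] + rec["end"]) // 2).to_numpy()
                ecc += np.bincount(_window_index(mid, length, window), minlength=n_windows)
        csub = cov[cov["chrom"] == chrom]
        cdens = np.zeros(n_windows)
        if len(csub):
            mid = ((csub["start"] + csub["end"]) // 2).to_numpy()
            cdens = np.bincount(_window_index(mid, length, window), minlength=n_windows).astype(
                float
            )
        mb = sizes / 1e6
        for w in range(n_windows):
            rows.append((chrom, w * window, ecc[w] / mb[w], cdens[w] / mb[w]))
    table = pd.DataFrame(
        rows, columns=["chrom", "window_start", "eccdna_per_mb", "covariate_per_mb"]
    )
    x, y = table["eccdna_per_mb"], table["covariate_per_mb"]
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DensityCorrelation(window, table, float(r), float(p), method)


def drug_sensitivity_correlation(
    abundance: Sequence[AbundanceSummary],
    ic50: pd.DataFrame,
    min_pairs: int = 5,
    alpha: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate per-drug IC50 against normalized eccDNA abundance.

    ``ic50`` is drugs (rows) x samples (columns); NaN marks missing.
    Drugs with fewer than ``min_pairs`` paired observations are skipped.
    Flagging (``significant_negative``) uses the raw p-value at ``alpha``
    with r < 0; Benjamini-Hochberg adjusted p-values are reported
    alongside.
    """
    epm = pd.Series({a.sample_id: a.epm for a in abundance})
    shared = [s for s in ic50.columns if s in epm.index]
    rows = []
    for drug, values in ic50[shared].iterrows():
        mask = values.notna()
        n = int(mask.sum())
        if n < min_pairs:
            continue
        x = epm[values.index[mask]].to_numpy(dtype=float)
        y = values[mask].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        elif method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        rows.append((drug, n, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["drug", "n", "r", "p"])
    if len(out):
        mask = out["p"].notna()
        out["p_adj"] = np.nan
        if mask.any():
            out.loc[mask, "p_adj"] = stats.false_discovery_control(out.loc[mask, "p"])
        out["direction"] = np.where(out["r"] < 0, "negative", "positive")
        out["significant_negative"] = (out["r"] < 0) & (out["p"] < alpha)
    return out
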