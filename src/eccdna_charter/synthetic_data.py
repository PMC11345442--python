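"""Synthetic genomes, annotations, eccDNA catalogs and cohort data.

The generator emits every dataset the pipeline consumes, with planted,
parameterized versions of the statistical structure the analyses assume:

* a genome with a controllable GC landscape,
* gene annotation with a density gradient along each chromosome, and a
  repeat track covering a configurable genome fraction (default 52.5 %,
  the approximate repeat content of the human genome),
* eccDNA catalogs whose sizes are log-normal with a sub-100-bp mode,
  whose placement intensity couples to local GC, gene density and Alu
  density, and whose per-sample abundance is split into high (H) and low
  (L) groups,
* copy-number segments whose wGII is elevated in H samples,
* expression matrices with planted fold-change structure between groups,
* survival cohorts with a planted hazard ratio between score strata.

Every stochastic output is governed by one master seed; each generator
draws from its own stream derived from the seed by a fixed label, so
adding a generator never perturbs another's output. Identical configs
yield byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (
    AnnotationTrack,
    CNSegmentSet,
    EccDNACatalog,
    ExpressionMatrix,
    GenomeModel,
    SurvivalCohort,
    write_annotation,
    write_cn_segments,
    write_eccdna_catalog,
    write_expression,
    write_genome_fasta,
    write_survival,
)

__all__ = [
    "SimConfig",
    "TruthTable",
    "generate_genome",
    "generate_annotation",
    "generate_eccdna_catalogs",
    "generate_cn_segments",
    "generate_expression",
    "generate_survival_cohort",
    "simulate_bundle",
]

# fixed stream labels: adding a generator never perturbs another's draws
_STREAMS = {
    "genome": 11,
    "annotation": 23,
    "catalogs": 37,
    "cn": 53,
    "expression": 67,
    "survival": 79,
}

# default repeat class mix (fraction of repeat bp per class) and per-class
# feature length ranges in bp. A simplified repeat landscape: satellite
# arrays are omitted because the simulated genome models no centromeres.
DEFAULT_REPEAT_MIX = {
    "Alu": 0.20,
    "SINE": 0.14,
    "LINE": 0.16,
    "LTR": 0.14,
    "simple_repeat": 0.13,
    "low_complexity": 0.115,
    "DNA_transposon": 0.115,
}
_REPEAT_LENGTHS = {
    "Alu": (250, 350),
    "SINE": (150, 400),
    "LINE": (500, 3000),
    "LTR": (300, 1000),
    "simple_repeat": (50, 300),
    "low_complexity": (50, 300),
    "DNA_transposon": (200, 800),
    "satellite": (500, 3000),
    "other_repeat": (100, 500),
}

# gene structure: UTR5, 3 exons alternating with 2 introns, UTR3 (3 kb total)
_GENE_PARTS = [
    ("UTR5", 300),
    ("exon", 400),
    ("intron", 600),
    ("exon", 400),
    ("intron", 600),
    ("exon", 400),
    ("UTR3", 300),
]
GENE_SPAN = sum(w for _, w in _GENE_PARTS)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Placement intensity per 1-kb window w is

        weight(w) = exp(gc_bias * (GC_w - mean GC))
                    * (1 + a * geneDensity_w + b * aluDensity_w)

    with densities measured in features per Mb over ``density_block``-bp
    blocks and normalized by their genome-wide mean, and (a, b) =
    ``density_coupling``. H-group samples additionally carry a fixed
    per-chromosome log-normal intensity tilt of scale
    ``group_profile_tilt``, emulating group-specific eccDNA production.
    """

    seed: int = 0
    # genome
    n_chrom: int = 4
    chrom_length: int = 1_000_000
    gc_window: int = 1_000
    gc_base: float = 0.45
    gc_amplitude: float = 0.10
    gc_period: int = 50  # landscape period in windows
    gc_landscape: np.ndarray | None = None  # explicit per-window targets (override)
    # annotation
    gene_density_range: tuple[float, float] = (5.0, 50.0)  # genes per Mb, start -> end
    repeat_fraction: float = 0.525
    repeat_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPEAT_MIX))
    density_block: int = 100_000
    # eccDNA catalogs
    size_mode: float = 80.0  # bp; modal length, below the 100-bp boundary
    size_sigma: float = 0.45  # log-scale spread
    size_min: int = 30
    size_max: int = 1_000_000
    gc_bias: float = 6.0  # beta; ~+0.03 mean locus GC excess on the default landscape
    density_coupling: tuple[float, float] = (1.0, 1.0)  # (a, b)
    element_weight: tuple[str, float] | None = None  # per-bp weight inside one class
    n_samples: int = 18
    n_high: int = 9
    abundance_split: tuple[float, float] = (4000.0, 400.0)  # mean records H, L
    group_profile_tilt: float = 0.5
    mapped_reads_range: tuple[int, int] = (9_000_000, 11_000_000)
    # copy number
    wgii_high: float = 0.5
    wgii_low: float = 0.1
    wgii_noise: float = 0.08
    cn_splits_per_chrom: int = 6
    # expression
    n_genes_expr: int = 2_000
    samples_per_group: int = 100
    n_de_up: int = 100
    n_de_down: int = 100
    de_fold_change: float = 2.0
    expr_sigma: float = 0.4  # natural-log scale
    # survival
    n_patients: int = 300
    survival_hr: float = 2.0
    censoring_rate: float = 0.2
    median_survival_days: float = 700.0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.n_chrom <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.chrom_length < self.gc_window:
            raise ValueError("chrom_length must be at least one GC window")
        for frac in (self.gc_base, self.repeat_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if self.gc_bias < 0:
            raise ValueError("gc_bias must be >= 0")
        if min(self.abundance_split) <= 0:
            raise ValueError("abundance means must be positive")
        if not 0 <= self.n_high <= self.n_samples:
            raise ValueError("n_high must lie in [0, n_samples]")
        if abs(sum(self.repeat_mix.values()) - 1.0) > 1e-9 and self.repeat_mix:
            raise ValueError("repeat_mix fractions must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def group_labels(self) -> pd.Series:
        labels = ["H"] * self.n_high + ["L"] * (self.n_samples - self.n_high)
        return pd.Series(labels, index=self.sample_ids, name="group")


@dataclass
class TruthTable:
    """Planted ground truth accompanying a simulated bundle."""

    group_labels: pd.Series
    placement_intensity: pd.DataFrame  # chrom, window_start, weight_H, weight_L
    chrom_tilt: pd.Series | None = None
    de_genes: pd.DataFrame | None = None  # gene, fold_change, direction
    survival_strata: pd.Series | None = None  # patient -> 0/1


# ---------------------------------------------------------------------------
# genome


def _window_targets(config: SimConfig, chrom_index: int, n_windows: int) -> np.ndarray:
    if config.gc_landscape is not None:
        targets = np.asarray(config.gc_landscape, dtype=float)
        if len(targets) < n_windows:
            targets = np.resize(targets, n_windows)
        return targets[:n_windows]
    w = np.arange(n_windows)
    phase = chrom_index * 7  # deterministic per-chromosome phase offset
    return config.gc_base + config.gc_amplitude * np.sin(
        2.0 * np.pi * (w + phase) / config.gc_period
    )


_BASES_GC = np.frombuffer(b"GC", dtype=np.uint8)
_BASES_AT = np.frombuffer(b"AT", dtype=np.uint8)


def generate_genome(config: SimConfig) -> GenomeModel:
    """Emit a genome whose per-window GC tracks the configured landscape.

    Bases are drawn per-position Bernoulli against the window's target GC,
    so realized GC over any >= 10 kb window with a uniform target is within
    sampling noise (binomial s.d. < 0.005) of the target.
    """
    rng = config.rng("genome")
    sequences: dict[str, str] = {}
    for ci, name in enumerate(config.chrom_names):
        length = config.chrom_length
        n_windows = -(-length // config.gc_window)
        targets = np.clip(_window_targets(config, ci, n_windows), 0.0, 1.0)
        per_base = np.repeat(targets, config.gc_window)[:length]
        is_gc = rng.random(length) < per_base
        pick = rng.integers(0, 2, size=length)
        codes = np.where(is_gc, _BASES_GC[pick], _BASES_AT[pick]).astype(np.uint8)
        sequences[name] = codes.tobytes().decode("ascii")
    return GenomeModel(sequences)


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(genome: GenomeModel, config: SimConfig) -> AnnotationTrack:
    """Genes on a density gradient plus a repeat track at the target coverage.

    Gene counts per ``density_block`` are Poisson around a linear gradient
    from ``gene_density_range[0]`` to ``gene_density_range[1]`` genes per
    Mb along each chromosome; genes are placed on non-overlapping slots.
    Repeat features are placed without mutual overlap until the covered
    fraction reaches ``repeat_fraction`` (within a per-feature overshoot).
    """
    rng = config.rng("annotation")
    rows: list[tuple] = []
    d0, d1 = config.gene_density_range
    block = config.density_block
    gene_counter = 0
    for name in config.chrom_names:
        length = genome.lengths[name]
        n_blocks = -(-length // block)
        slots_per_block = block // GENE_SPAN
        for b in range(n_blocks):
            frac = b / max(n_blocks - 1, 1)
            lam = (d0 + (d1 - d0) * frac) * (block / 1e6)
            if lam > slots_per_block:
                raise ValueError(
                    f"gene density {lam / (block / 1e6):.1f}/Mb infeasible for "
                    f"{GENE_SPAN}-bp genes"
                )
            count = min(int(rng.poisson(lam)), slots_per_block)
            if count == 0:
                continue
            slots = rng.choice(slots_per_block, size=count, replace=False)
            for slot in np.sort(slots):
                start = b * block + int(slot) * GENE_SPAN
                if start + GENE_SPAN > length:
                    continue
                gene_counter += 1
                gid = f"GENE{gene_counter:05d}"
                rows.append((name, start, start + GENE_SPAN, "gene", gid))
                pos = start
                for part, width in _GENE_PARTS:
                    rows.append((name, pos, pos + width, part, gid))
                    pos += width
        # repeats: reject-place until coverage target is met
        if config.repeat_fraction > 0 and config.repeat_mix:
            # fill per-class bp quotas, longest feature class first, so long
            # elements are not crowded out by rejection sampling
            classes = sorted(
                config.repeat_mix, key=lambda c: -np.mean(_REPEAT_LENGTHS[c])
            )
            occupied = np.zeros(length, dtype=bool)
            target_bp = int(round(config.repeat_fraction * length))
            covered = 0
            for cls in classes:
                quota = config.repeat_mix[cls] * target_bp
                lo, hi = _REPEAT_LENGTHS[cls]
                class_bp = 0
                tries = 0
                max_tries = 80 * max(int(quota // lo), 1)
                while class_bp < quota and tries < max_tries:
                    tries += 1
                    flen = int(rng.integers(lo, hi + 1))
                    if flen >= length:
                        continue
                    start = int(rng.integers(0, length - flen))
                    if occupied[start : start + flen].any():
                        continue
                    occupied[start : start + flen] = True
                    class_bp += flen
                    rows.append((name, start, start + flen, cls, ""))
                covered += class_bp
            if covered < target_bp - int(0.02 * length):
                raise ValueError(
                    f"could not reach repeat coverage {config.repeat_fraction:.3f} "
                    f"on {name} (got {covered / length:.3f})"
                )
    track = AnnotationTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_class", "gene_id"])
    )
    track.validate_against(genome)
    return track


# ---------------------------------------------------------------------------
# eccDNA catalogs


def _window_gc(genome: GenomeModel, chrom: str, window: int) -> np.ndarray:
    codes = genome.codes(chrom)
    is_gc = (codes == ord("G")) | (codes == ord("C"))
    length = len(codes)
    n_windows = -(-length // window)
    padded = np.zeros(n_windows * window, dtype=np.float64)
    padded[:length] = is_gc
    sizes = np.minimum(np.arange(1, n_windows + 1) * window, length) - np.arange(
        n_windows
    ) * window
    return padded.reshape(n_windows, window).sum(axis=1) / sizes


def _block_density(
    positions: np.ndarray, length: int, block: int, window: int
) -> np.ndarray:
    """Per-1-kb-window density (features per Mb) smoothed over blocks."""
    n_blocks = -(-length // block)
    counts = np.bincount(np.minimum(positions // block, n_blocks - 1), minlength=n_blocks)
    per_mb = counts / (block / 1e6)
    n_windows = -(-length // window)
    win_block = np.minimum(np.arange(n_windows) * window // block, n_blocks - 1)
    return per_mb[win_block]


def placement_weights(
    genome: GenomeModel, annotation: AnnotationTrack, config: SimConfig
) -> pd.DataFrame:
    """Per-1-kb-window placement weights implied by the config.

    Returns a DataFrame (chrom, window_start, window_len, weight) where
    ``weight`` is the mean per-bp intensity of the window, recomputable
    from the genome, annotation and config alone.
    """
    genes = annotation.subset(["gene"])
    alus = annotation.subset(["Alu"])
    a, b = config.density_coupling
    frames = []
    # normalize densities by their genome-wide means
    gdens_all, adens_all = [], []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        gpos = genes.loc[genes["chrom"] == chrom, ["start", "end"]].to_numpy()
        apos = alus.loc[alus["chrom"] == chrom, ["start", "end"]].to_numpy()
        gmid = (gpos[:, 0] + gpos[:, 1]) // 2 if len(gpos) else np.empty(0, dtype=np.int64)
        amid = (apos[:, 0] + apos[:, 1]) // 2 if len(apos) else np.empty(0, dtype=np.int64)
        gdens_all.append(_block_density(gmid, length, config.density_block, config.gc_window))
        adens_all.append(_block_density(amid, length, config.density_block, config.gc_window))
    gmean = max(float(np.mean(np.concatenate(gdens_all))), 1e-12)
    amean = max(float(np.mean(np.concatenate(adens_all))), 1e-12)

    elem_cov: dict[str, np.ndarray] = {}
    if config.element_weight is not None:
        cls, _w = config.element_weight
        feats = annotation.subset([cls])
        for chrom in genome.names:
            cov = np.zeros(genome.lengths[chrom], dtype=bool)
            for row in feats[feats["chrom"] == chrom].itertuples(index=False):
                cov[row.start : row.end] = True
            elem_cov[chrom] = cov

    for ci, chrom in enumerate(genome.names):
        length = genome.lengths[chrom]
        gc = _window_gc(genome, chrom, config.gc_window)
        n_windows = len(gc)
        dens = 1.0 + a * gdens_all[ci] / gmean + b * adens_all[ci] / amean
        weight = np.exp(config.gc_bias * (gc - config.gc_base)) * np.clip(dens, 0.0, None)
        if config.element_weight is not None:
            _cls, w = config.element_weight
            cov = elem_cov[chrom]
            n_pad = n_windows * config.gc_window
            padded = np.zeros(n_pad, dtype=np.float64)
            padded[:length] = cov
            sizes = (
                np.minimum(np.arange(1, n_windows + 1) * config.gc_window, length)
                - np.arange(n_windows) * config.gc_window
            )
            covfrac = padded.reshape(n_windows, config.gc_window).sum(axis=1) / sizes
            weight = weight * (1.0 + (w - 1.0) * covfrac)
        starts = np.arange(n_windows) * config.gc_window
        sizes = np.minimum(starts + config.gc_window, length) - starts
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "window_start": starts,
                    "window_len": sizes,
                    "weight": weight,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sample_positions(
    weights: pd.DataFrame,
    genome: GenomeModel,
    config: SimConfig,
    n: int,
    rng: np.random.Generator,
    chrom_multiplier: pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` midpoint positions by inverse-CDF over window weights.

    Returns (chrom_index, position); within the chosen window the
    position is uniform.
    """
    w = weights["weight"].to_numpy() * weights["window_len"].to_numpy()
    if chrom_multiplier is not None:
        w = w * weights["chrom"].map(chrom_multiplier).to_numpy()
    cdf = np.cumsum(w)
    total = cdf[-1]
    if not np.isfinite(total) or total <= 0:
        raise ValueError("placement weights sum to zero")
    u = rng.random(n) * total
    idx = np.searchsorted(cdf, u, side="right")
    win_start = weights["window_start"].to_numpy()[idx]
    win_len = weights["window_len"].to_numpy()[idx]
    chrom_codes = pd.Categorical(weights["chrom"], categories=genome.names).codes
    chrom_idx = chrom_codes[idx]
    pos = win_start + rng.integers(0, win_len)
    return chrom_idx, pos


def _sample_positions_weighted(
    weights: pd.DataFrame,
    genome: GenomeModel,
    annotation: AnnotationTrack,
    config: SimConfig,
    n: int,
    rng: np.random.Generator,
    chrom_multiplier: pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Position sampling honouring an ``element_weight`` per-bp intensity."""
    cls, wgt = config.element_weight
    cov_prefix: dict[str, np.ndarray] = {}
    feats = annotation.subset([cls])
    for chrom in genome.names:
        cov = np.zeros(genome.lengths[chrom], dtype=bool)
        for row in feats[feats["chrom"] == chrom].itertuples(index=False):
            cov[row.start : row.end] = True
        cov_prefix[chrom] = np.concatenate([[0], np.cumsum(cov, dtype=np.int64)])

    w = weights["weight"].to_numpy() * weights["window_len"].to_numpy()
    if chrom_multiplier is not None:
        w = w * weights["chrom"].map(chrom_multiplier).to_numpy()
    cdf = np.cumsum(w)
    u = rng.random(n) * cdf[-1]
    idx = np.searchsorted(cdf, u, side="right")
    win_start = weights["window_start"].to_numpy()[idx]
    win_len = weights["window_len"].to_numpy()[idx]
    chrom_codes = pd.Categorical(weights["chrom"], categories=genome.names).codes
    chrom_idx = chrom_codes[idx]
    pos = np.empty(n, dtype=np.int64)
    u2 = rng.random(n)
    u3 = rng.random(n)
    for i in range(n):
        chrom = genome.names[chrom_idx[i]]
        pref = cov_prefix[chrom]
        a, b = int(win_start[i]), int(win_start[i] + win_len[i])
        local_cov = pref[a : b + 1] - pref[a]  # covered bases in [a, a+j)
        n_cov = int(local_cov[-1])
        n_unc = (b - a) - n_cov
        mass = wgt * n_cov + n_unc
        p_cov = (wgt * n_cov) / mass if mass > 0 else 0.0
        if u2[i] < p_cov:
            k = min(int(u3[i] * n_cov), n_cov - 1)  # k-th covered base in window
            pos[i] = a + int(np.searchsorted(local_cov, k + 1, side="left")) - 1
        else:
            k = min(int(u3[i] * n_unc), n_unc - 1)  # k-th uncovered base in window
            local_unc = np.arange(b - a + 1) - local_cov
            pos[i] = a + int(np.searchsorted(local_unc, k + 1, side="left")) - 1
    return chrom_idx, pos


def _draw_lengths(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal lengths parameterized by mode: ln L ~ N(ln m + s^2, s)."""
    mu = np.log(config.size_mode) + config.size_sigma**2
    lengths = np.exp(rng.normal(mu, config.size_sigma, size=n))
    hi = min(config.size_max, config.chrom_length)
    return np.clip(np.round(lengths), config.size_min, hi).astype(np.int64)


def generate_eccdna_catalogs(
    genome: GenomeModel, annotation: AnnotationTrack, config: SimConfig
) -> tuple[list[EccDNACatalog], TruthTable]:
    """Per-sample catalogs with planted placement intensity and H/L split.

    Record counts are Poisson around the group mean (H >> L). Midpoints
    are drawn by inverse-CDF over 1-kb-window weights (see
    :func:`placement_weights`); H samples additionally carry a fixed
    per-chromosome intensity tilt. Lengths are log-normal with the
    configured mode, truncated to [size_min, size_max].
    """
    rng = config.rng("catalogs")
    weights = placement_weights(genome, annotation, config)
    labels = config.group_labels
    tilt = pd.Series(
        np.exp(config.group_profile_tilt * rng.standard_normal(config.n_chrom)),
        index=genome.names,
        name="tilt",
    )
    mean_h, mean_l = config.abundance_split
    catalogs = []
    for sample_id in config.sample_ids:
        group = labels[sample_id]
        n = int(rng.poisson(mean_h if group == "H" else mean_l))
        mult = tilt if (group == "H" and config.group_profile_tilt > 0) else None
        if config.element_weight is None:
            chrom_idx, mid = _sample_positions(weights, genome, config, n, rng, mult)
        else:
            chrom_idx, mid = _sample_positions_weighted(
                weights, genome, annotation, config, n, rng, mult
            )
        lengths = _draw_lengths(config, n, rng)
        chrom_names = np.array(genome.names, dtype=object)[chrom_idx]
        chrom_len = np.array([genome.lengths[c] for c in genome.names])[chrom_idx]
        lengths = np.minimum(lengths, chrom_len)
        start = np.clip(mid - lengths // 2, 0, chrom_len - lengths)
        split = 1 + rng.poisson(3.0, size=n)
        discordant = rng.poisson(2.0, size=n)
        score = np.round(rng.gamma(2.0, 20.0, size=n), 1)
        df = pd.DataFrame(
            {
                "chrom": chrom_names,
                "start": start,
                "end": start + lengths,
                "split_reads": split,
                "discordant_reads": discordant,
                "score": score,
            }
        )
        mapped = int(rng.integers(*config.mapped_reads_range))
        catalogs.append(
            EccDNACatalog(sample_id, df, mapped_read_total=mapped, group_label=group)
        )
    intensity = weights.rename(columns={"weight": "weight_L"}).copy()
    intensity["weight_H"] = intensity["weight_L"] * intensity["chrom"].map(tilt)
    truth = TruthTable(
        group_labels=labels,
        placement_intensity=intensity[
            ["chrom", "window_start", "window_len", "weight_L", "weight_H"]
        ],
        chrom_tilt=tilt,
    )
    return catalogs, truth


# ---------------------------------------------------------------------------
# copy number


def generate_cn_segments(
    config: SimConfig,
    group_labels: pd.Series | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[CNSegmentSet]:
    """Integer CN segments tiling each chromosome, wGII split by group.

    Each sample draws an aberrant genome fraction around its group target
    (``wgii_high`` for H, ``wgii_low`` for L, s.d. ``wgii_noise``); per
    chromosome exactly that fraction of bases is set to a non-diploid copy
    number, so the realized wGII equals the drawn fraction. Segments are
    then split at random points, which leaves wGII invariant.
    """
    rng = config.rng("cn")
    labels = group_labels if group_labels is not None else config.group_labels
    lengths = chrom_lengths or {name: config.chrom_length for name in config.chrom_names}
    out = []
    for sample_id, group in labels.items():
        target = config.wgii_high if group == "H" else config.wgii_low
        frac = float(np.clip(rng.normal(target, config.wgii_noise), 0.0, 0.95))
        rows = []
        for chrom, length in lengths.items():
            ab_bp = int(round(frac * length))
            aberrant_cn = int(rng.choice([1, 3]))
            if ab_bp <= 0:
                rows.append((chrom, 0, length, 2))
            elif ab_bp >= length:
                rows.append((chrom, 0, length, aberrant_cn))
            else:
                offset = int(rng.integers(0, length - ab_bp + 1))
                if offset > 0:
                    rows.append((chrom, 0, offset, 2))
                rows.append((chrom, offset, offset + ab_bp, aberrant_cn))
                if offset + ab_bp < length:
                    rows.append((chrom, offset + ab_bp, length, 2))
        # split segments at random equal-CN points (wGII-invariant)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
        split_rows = []
        for row in df.itertuples(index=False):
            seg_len = row.end - row.start
            n_cuts = int(rng.integers(0, config.cn_splits_per_chrom))
            if n_cuts and seg_len > n_cuts + 1:
                cuts = np.sort(rng.choice(np.arange(1, seg_len), size=n_cuts, replace=False))
                bounds = np.concatenate([[0], cuts, [seg_len]])
                for s, e in zip(bounds[:-1], bounds[1:]):
                    split_rows.append((row.chrom, row.start + int(s), row.start + int(e), row.cn))
            else:
                split_rows.append(tuple(row))
        cnset = CNSegmentSet(sample_id, pd.DataFrame(split_rows, columns=["chrom", "start", "end", "cn"]))
        cnset.validate_tiling(lengths)
        out.append(cnset)
    return out


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    config: SimConfig, group_labels: pd.Series | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Gene x sample matrix with planted fold changes between H and L.

    Baseline per-gene log-means are N(2, 1); the first ``n_de_up`` genes
    gain log(fold change) in H samples, the next ``n_de_down`` lose it,
    and all values carry log-normal noise of scale ``expr_sigma``. The
    group-mean ratio of a planted gene is the configured fold change in
    expectation; background genes sit at ratio 1.
    """
    rng = config.rng("expression")
    n_genes = config.n_genes_expr
    if config.n_de_up + config.n_de_down > n_genes:
        raise ValueError("more DE genes than genes")
    if group_labels is None:
        ids = [f"C{i + 1:04d}" for i in range(2 * config.samples_per_group)]
        group_labels = pd.Series(
            ["H"] * config.samples_per_group + ["L"] * config.samples_per_group,
            index=ids,
            name="group",
        )
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    base = rng.normal(2.0, 1.0, size=n_genes)
    lfc = np.zeros(n_genes)
    lfc[: config.n_de_up] = np.log(config.de_fold_change)
    lfc[config.n_de_up : config.n_de_up + config.n_de_down] = -np.log(config.de_fold_change)
    is_h = (group_labels == "H").to_numpy()
    loc = base[:, None] + lfc[:, None] * is_h[None, :]
    values = np.exp(loc + rng.normal(0.0, config.expr_sigma, size=loc.shape))
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=group_labels.index), groups=group_labels
    )
    truth = pd.DataFrame(
        {
            "gene": genes[: config.n_de_up + config.n_de_down],
            "fold_change": np.exp(np.abs(lfc[: config.n_de_up + config.n_de_down])),
            "direction": ["up"] * config.n_de_up + ["down"] * config.n_de_down,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# survival


def generate_survival_cohort(
    config: SimConfig, scores: np.ndarray | None = None
) -> tuple[SurvivalCohort, pd.Series]:
    """Exponential survival with the hazard multiplied by HR above the median score.

    Censoring is independent exponential, with its rate set so the expected
    censored fraction matches ``censoring_rate``; rate 1 censors everyone.
    Returns the cohort and the true per-patient stratum (1 = high score).
    """
    rng = config.rng("survival")
    if scores is None:
        scores = rng.normal(0.0, 1.0, size=config.n_patients)
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    stratum = (scores > np.median(scores)).astype(int)
    lam0 = np.log(2.0) / config.median_survival_days
    lam = lam0 * np.power(config.survival_hr, stratum)
    event_time = rng.exponential(1.0 / lam)
    patients = [f"P{i + 1:04d}" for i in range(n)]
    if config.censoring_rate >= 1.0:
        time = rng.exponential(1.0 / lam)
        event = np.zeros(n, dtype=int)
    elif config.censoring_rate <= 0.0:
        time, event = event_time, np.ones(n, dtype=int)
    else:
        lam_c = float(np.mean(lam)) * config.censoring_rate / (1.0 - config.censoring_rate)
        censor_time = rng.exponential(1.0 / lam_c, size=n)
        event = (event_time <= censor_time).astype(int)
        time = np.minimum(event_time, censor_time)
    cohort = SurvivalCohort(
        pd.DataFrame(
            {
                "patient": patients,
                "time": np.maximum(time, 1e-3),
                "event": event,
                "score": scores,
            }
        )
    )
    return cohort, pd.Series(stratum, index=patients, name="stratum")


# ---------------------------------------------------------------------------
# bundle


def simulate_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic bundle; returns emitted paths.

    Layout: genome.fa, genes.bed, repeats.bed, catalogs/<sample>.bed,
    samples.tsv (mapped read totals), cn_segments.tsv, expression.tsv,
    survival.tsv and truth/*.tsv.
    """
    outdir = Path(outdir)
    (outdir / "catalogs").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    genome = generate_genome(config)
    annotation = generate_annotation(genome, config)
    catalogs, truth = generate_eccdna_catalogs(genome, annotation, config)
    cn = generate_cn_segments(config, truth.group_labels, genome.lengths)
    expr, de_truth = generate_expression(config)
    # panel scores for the survival cohort are planted directly as latent scores
    cohort, strata = generate_survival_cohort(config)

    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_genome_fasta(genome, paths["genome"])
    genes_track = AnnotationTrack(
        annotation.features[annotation.features["gene_id"] != ""]
    )
    repeats_track = AnnotationTrack(
        annotation.features[annotation.features["gene_id"] == ""]
    )
    paths["genes"] = outdir / "genes.bed"
    write_annotation(genes_track, paths["genes"], kind="gene_bed")
    paths["repeats"] = outdir / "repeats.bed"
    write_annotation(repeats_track, paths["repeats"], kind="repeat_bed")
    sample_rows = []
    for cat in catalogs:
        p = outdir / "catalogs" / f"{cat.sample_id}.bed"
        write_eccdna_catalog(cat, p)
        sample_rows.append((cat.sample_id, cat.mapped_read_total))
    paths["catalog_dir"] = outdir / "catalogs"
    paths["samples"] = outdir / "samples.tsv"
    pd.DataFrame(sample_rows, columns=["sample", "mapped_read_total"]).to_csv(
        paths["samples"], sep="\t", index=False
    )
    paths["cn"] = outdir / "cn_segments.tsv"
    write_cn_segments(cn, paths["cn"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression(expr, paths["expression"])
    paths["expression_groups"] = outdir / "expression_groups.tsv"
    expr.groups.rename_axis("sample").reset_index().to_csv(
        paths["expression_groups"], sep="\t", index=False
    )
    paths["survival"] = outdir / "survival.tsv"
    write_survival(cohort, paths["survival"])
    truth.group_labels.rename_axis("sample").reset_index().to_csv(
        outdir / "truth" / "group_labels.tsv", sep="\t", index=False
    )
    truth.placement_intensity.to_csv(
        outdir / "truth" / "placement_intensity.tsv", sep="\t", index=False
    )
    de_truth.to_csv(outdir / "truth" / "de_genes.tsv", sep="\t", index=False)
    strata.rename_axis("patient").reset_index().to_csv(
        outdir / "truth" / "survival_strata.tsv", sep="\t", index=False
    )
    paths["truth"] = outdir / "truth"
    return paths
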