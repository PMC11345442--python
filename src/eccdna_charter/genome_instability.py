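"""Weighted genome instability index and NMF sample stratification.

wGII follows the standard convention: sample ploidy is the
length-weighted modal integer copy number over the genome; each
chromosome contributes the fraction of its length at a copy number
different from ploidy; wGII is the unweighted mean of those fractions,
so every chromosome carries equal weight regardless of size.

Samples are split into high (H) and low (L) eccDNA-abundance groups by
rank-2 non-negative matrix factorization of a per-sample nonnegative
feature matrix (default: per-chromosome share of the sample's records).
NMF minimizes the Frobenius reconstruction error by multiplicative
updates, best of ``n_restarts`` random restarts; each sample is assigned
to the component with the larger coefficient, and the component whose
samples have the larger mean normalized abundance is labeled H.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog_stats import AbundanceSummary
from .formats import CNSegmentSet, EccDNACatalog

__all__ = [
    "WGIIResult",
    "compute_wgii",
    "GroupAssignment",
    "nmf_group",
    "nmf_rank_survey",
    "build_feature_matrix",
    "InstabilityAssociation",
    "instability_association",
]

log = logging.getLogger(__name__)


@dataclass
class WGIIResult:
    sample_id: str
    ploidy: int
    per_chromosome: pd.Series  # chrom -> aberrant fraction
    wgii: float


def compute_wgii(
    segments: CNSegmentSet,
    chrom_lengths: dict[str, int] | None = None,
    exclude: Sequence[str] = (),
) -> WGIIResult:
    """wGII of one sample from integer copy-number segments.

    Segments must tile every chromosome (a coverage gap raises, naming
    the chromosome). ``exclude`` optionally drops chromosomes (e.g. sex
    chromosomes) from both the ploidy estimate and the mean.
    """
    segments.validate_tiling(chrom_lengths)
    df = segments.segments
    if exclude:
        df = df[~df["chrom"].isin(set(exclude))]
    seg_len = df["end"] - df["start"]
    bp_by_cn = seg_len.groupby(df["cn"]).sum()
    ploidy = int(bp_by_cn.idxmax())  # length-weighted modal copy number
    aberrant = df["cn"] != ploidy
    chrom_bp = seg_len.groupby(df["chrom"], sort=False).sum()
    aberrant_bp = seg_len.where(aberrant, 0).groupby(df["chrom"], sort=False).sum()
    frac = (aberrant_bp / chrom_bp).rename("aberrant_fraction")
    return WGIIResult(segments.sample_id, ploidy, frac, float(frac.mean()))


# ---------------------------------------------------------------------------
# NMF


def _mu_nmf(
    X: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 500, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative-update NMF (Frobenius); returns (W, H, error).

    The update never increases the objective; this is asserted each
    iteration (within floating slack).
    """
    n, m = X.shape
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.random((n, k)) * scale + 1e-6
    H = rng.random((k, m)) * scale + 1e-6
    eps = 1e-12
    err_prev = np.linalg.norm(X - W @ H)
    for _ in range(n_iter):
        H *= (W.T @ X) / np.maximum(W.T @ W @ H, eps)
        W *= (X @ H.T) / np.maximum(W @ (H @ H.T), eps)
        err = np.linalg.norm(X - W @ H)
        assert err <= err_prev + 1e-6 * max(err_prev, 1.0), "MU update increased error"
        if err_prev - err < tol * max(err_prev, 1.0):
            err_prev = err
            break
        err_prev = err
    return W, H, float(err_prev)


@dataclass
class GroupAssignment:
    labels: pd.Series  # sample -> "H" | "L"
    W: np.ndarray  # sample coefficients (n_samples x k)
    H: np.ndarray  # component features (k x n_features)
    reconstruction_error: float
    h_component: int  # which component was labeled H


def nmf_group(
    features: pd.DataFrame,
    abundance: pd.Series,
    k: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
    n_iter: int = 500,
) -> GroupAssignment:
    """Two-group NMF stratification of samples.

    ``features``: samples (rows) x nonnegative features; ``abundance``:
    per-sample normalized abundance (EPM), used only to decide which
    component is called H. Best Frobenius error over ``n_restarts``
    restarts wins (ties: lowest restart index). Deterministic under
    ``seed``.
    """
    X = features.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("feature matrix must be nonnegative")
    if X.shape[0] < 4:
        raise ValueError("need >= 4 samples")
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        W, H, err = _mu_nmf(X, k, rng, n_iter=n_iter)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, err = best
    comp = np.argmax(W, axis=1)
    abundance = abundance.reindex(features.index)
    comp_means = [
        abundance.to_numpy()[comp == c].mean() if (comp == c).any() else -np.inf
        for c in range(k)
    ]
    h_comp = int(np.argmax(comp_means))
    labels = pd.Series(
        np.where(comp == h_comp, "H", "L"), index=features.index, name="group"
    )
    return GroupAssignment(labels, W, H, err, h_comp)


def build_feature_matrix(
    catalogs: Sequence[EccDNACatalog],
    chrom_lengths: dict[str, int],
    mode: str = "chrom_share",
) -> pd.DataFrame:
    """Per-sample per-chromosome eccDNA feature matrix for NMF.

    ``chrom_share``: each row is the sample's fraction of records per
    chromosome (scale-free, the default). ``chrom_epm``: per-chromosome
    records per million mapped reads. ``chrom_epm_log``: log1p of that.
    """
    chroms = list(chrom_lengths)
    rows = {}
    for cat in catalogs:
        counts = cat.records["chrom"].value_counts().reindex(chroms, fill_value=0)
        if mode == "chrom_share":
            total = counts.sum()
            rows[cat.sample_id] = counts / total if total else counts.astype(float)
        elif mode == "chrom_epm":
            rows[cat.sample_id] = counts / cat.mapped_read_total * 1e6
        elif mode == "chrom_epm_log":
            rows[cat.sample_id] = np.log1p(counts / cat.mapped_read_total * 1e6)
        else:
            raise ValueError(f"unknown feature mode {mode!r}")
    return pd.DataFrame(rows).T[chroms]


def nmf_rank_survey(
    features: pd.DataFrame,
    ks: Sequence[int] = (2, 3, 4, 5),
    n_runs: int = 20,
    seed: int = 0,
    n_iter: int = 300,
) -> pd.Series:
    """Cophenetic coefficient of NMF consensus clustering per rank k.

    Diagnostic only (the grouping itself is fixed at k = 2): for each k,
    samples are co-clustered over ``n_runs`` random restarts; the
    cophenetic correlation between the consensus (co-assignment)
    distances and their average-linkage dendrogram measures assignment
    stability (1 = perfectly stable).
    """
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import squareform

    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    out = {}
    for k in ks:
        consensus = np.zeros((n, n))
        for r in range(n_runs):
            rng = np.random.default_rng([seed, k, r])
            W, _, _ = _mu_nmf(X, k, rng, n_iter=n_iter)
            comp = np.argmax(W, axis=1)
            consensus += comp[:, None] == comp[None, :]
        consensus /= n_runs
        dist = squareform(1.0 - consensus, checks=False)
        if np.allclose(dist, dist[0] if dist.size else 0.0):
            out[k] = 1.0  # perfectly stable (all runs identical)
            continue
        coph, _ = cophenet(average(dist), dist)
        out[k] = float(coph)
    return pd.Series(out, name="cophenetic").rename_axis("k")


# ---------------------------------------------------------------------------
# association


@dataclass
class InstabilityAssociation:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    mannwhitney_u: float
    mannwhitney_p: float
    group_means: pd.Series  # H/L mean wGII


def instability_association(
    wgii: Sequence[WGIIResult],
    abundance: Sequence[AbundanceSummary],
    labels: pd.Series | None = None,
) -> InstabilityAssociation:
    """Correlate wGII with normalized abundance; contrast H vs L wGII.

    With constant wGII (or abundance) the correlations are undefined and
    reported NaN with a warning. The group contrast is two-sided
    Mann-Whitney on wGII between H and L samples (NaN without labels).
    """
    w = pd.Series({r.sample_id: r.wgii for r in wgii})
    a = pd.Series({s.sample_id: s.epm for s in abundance})
    shared = w.index.intersection(a.index)
    w, a = w[shared], a[shared]
    if w.nunique() <= 1 or a.nunique() <= 1:
        log.warning("degenerate wGII or abundance: correlation undefined")
        pr = pp = sr = sp = float("nan")
    else:
        pr, pp = stats.pearsonr(w, a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr, sp = stats.spearmanr(w, a)
    u = up = float("nan")
    gmeans = pd.Series(dtype=float)
    if labels is not None:
        labels = labels.reindex(shared)
        hi, lo = w[labels == "H"], w[labels == "L"]
        gmeans = pd.Series({"H": hi.mean(), "L": lo.mean()})
        if len(hi) and len(lo):
            u, up = stats.mannwhitneyu(hi, lo, alternative="two-sided")
    return InstabilityAssociation(
        float(pr), float(pp), float(sr), float(sp), float(u), float(up), gmeans
    )
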