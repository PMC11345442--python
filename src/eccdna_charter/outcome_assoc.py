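"""Outcome arm: differential expression, gene-panel ssGSEA scoring,
optimal-cutoff Kaplan-Meier survival and marker ROC.

Differential expression between H and L groups uses the fold-change rule
(group-mean ratio against a threshold, default 1.2) with an optional
Wilcoxon rank-sum significance gate and Benjamini-Hochberg adjustment.
The gene panel is the top-n up-regulated genes by fold change.

The ssGSEA score is the integrated difference of two running sums down
the expression-ranked gene list (in-set steps weighted by expression
rank to the power alpha, out-of-set steps uniform). Being rank-based,
it is invariant under any within-sample monotone transform.

"Optimal cutoff" dichotomization is maximally selected log-rank: every
midpoint between consecutive distinct scores that leaves both groups at
least ``min_group_frac`` of the cohort is scanned, and the cutoff
maximizing the log-rank chi-square is selected. Because maximal
selection inflates type-I error, a label-permutation p-value (the
fraction of score permutations whose own maximal chi-square reaches the
observed one) is reported alongside the naive chi-square p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .formats import ExpressionMatrix, SurvivalCohort

__all__ = [
    "DEResult",
    "differential_expression",
    "build_panel",
    "ssgsea_score",
    "SurvivalComparison",
    "km_logrank",
    "optimal_cutoff",
    "RocResult",
    "roc_auc",
]

log = logging.getLogger(__name__)

_EPS = 1e-9  # pseudocount in fold-change ratios


@dataclass
class DEResult:
    table: pd.DataFrame  # per gene: mean_h, mean_l, fold_change, p, p_adj, call
    fc_threshold: float
    alpha: float

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["call"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["call"] == "down"]


def differential_expression(
    matrix: ExpressionMatrix,
    groups: pd.Series | None = None,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> DEResult:
    """Per-gene H-vs-L fold change with optional rank-sum significance.

    fold change = (mean_H + eps) / (mean_L + eps). ``test="wilcoxon"``
    gates calls on BH-adjusted two-sided rank-sum p < alpha;
    ``test="none"`` reproduces the literal fold-change-only filter.
    Swapping the H and L labels exchanges the up and down lists exactly.
    """
    groups = groups if groups is not None else matrix.groups
    if groups is None:
        raise ValueError("no group labels supplied")
    groups = groups.reindex(matrix.samples)
    h_cols = matrix.samples[groups == "H"]
    l_cols = matrix.samples[groups == "L"]
    if len(h_cols) < 3 or len(l_cols) < 3:
        raise ValueError("each group needs >= 3 samples")
    X_h = matrix.values[h_cols].to_numpy(dtype=float)
    X_l = matrix.values[l_cols].to_numpy(dtype=float)
    mean_h = X_h.mean(axis=1)
    mean_l = X_l.mean(axis=1)
    fc = (mean_h + _EPS) / (mean_l + _EPS)
    if test == "wilcoxon":
        res = stats.mannwhitneyu(X_h, X_l, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
        p_adj = stats.false_discovery_control(p)
        sig = p_adj < alpha
    elif test == "none":
        p = np.full(len(fc), np.nan)
        p_adj = p
        sig = np.ones(len(fc), dtype=bool)
    else:
        raise ValueError(f"unknown test {test!r}")
    call = np.where(
        sig & (fc > fc_threshold), "up", np.where(sig & (fc < 1.0 / fc_threshold), "down", "none")
    )
    table = pd.DataFrame(
        {
            "mean_h": mean_h,
            "mean_l": mean_l,
            "fold_change": fc,
            "p": p,
            "p_adj": p_adj,
            "call": call,
        },
        index=matrix.genes,
    )
    return DEResult(table, fc_threshold, alpha)


def build_panel(de: DEResult, n: int = 100) -> list[str]:
    """Top-n up-regulated genes by descending fold change.

    Ties broken by ascending adjusted p, then lexicographic gene id.
    A shortfall (fewer up-genes than n) is logged, not an error.
    """
    up = de.table.loc[de.up].copy()
    up["_gene"] = up.index
    up = up.sort_values(
        by=["fold_change", "p_adj", "_gene"], ascending=[False, True, True], kind="mergesort"
    )
    panel = list(up.index[:n])
    if len(panel) < n:
        log.warning("panel shortfall: %d up-genes available for a panel of %d", len(panel), n)
    return panel


def ssgsea_score(
    matrix: ExpressionMatrix,
    panel: list[str],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """Per-sample single-sample gene-set enrichment score for a panel.

    For each sample, genes are ordered by decreasing expression (ties
    stable by matrix row order). Walking that order, the in-set running
    sum steps by rank^alpha (midranks; normalized over in-set genes) and
    the out-of-set running sum by 1/(N - |set|); the score is the sum of
    their difference over all positions. ``normalize`` applies min-max
    scaling across samples.
    """
    in_set = np.asarray(matrix.genes.isin(set(panel)))
    n_set = int(in_set.sum())
    if n_set == 0:
        raise ValueError("no panel gene present in the matrix")
    n_genes = len(matrix.genes)
    n_out = n_genes - n_set
    scores = {}
    X = matrix.values.to_numpy(dtype=float)
    for j, sample in enumerate(matrix.samples):
        x = X[:, j]
        ranks = stats.rankdata(x)  # ascending midranks
        order = np.argsort(-x, kind="stable")
        in_ord = in_set[order]
        w = np.where(in_ord, np.abs(ranks[order]) ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_ord) / n_out if n_out > 0 else np.zeros(n_genes)
        scores[sample] = float(np.sum(p_in - p_out))
    out = pd.Series(scores, name="ssgsea")
    if normalize:
        rng_ = out.max() - out.min()
        out = (out - out.min()) / rng_ if rng_ > 0 else out * 0.0
    return out


# ---------------------------------------------------------------------------
# survival machinery


def _event_tables(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean at-risk and event matrices over distinct event times.

    Returns (A, D): A[j, i] is True when patient i is at risk at the
    j-th distinct event time; D[j, i] when patient i dies there.
    Tied event times share one table (hypergeometric variance handles
    the tied deaths together).
    """
    ev_times = np.unique(time[event == 1])
    A = time[None, :] >= ev_times[:, None]
    D = (time[None, :] == ev_times[:, None]) & (event[None, :] == 1)
    return A, D


def _logrank_from_n1(
    n1: np.ndarray, d1: np.ndarray, nrisk: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank U and V summed over event times, for one or many groupings.

    ``n1``/``d1`` may be (T,) or (T, K) for K candidate groupings.
    """
    nrisk = nrisk.reshape(-1, *([1] * (n1.ndim - 1)))
    d_ = d.reshape(-1, *([1] * (n1.ndim - 1)))
    frac = n1 / nrisk
    U = (d1 - d_ * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = d_ * frac * (1.0 - frac) * (nrisk - d_) / np.maximum(nrisk - 1, 1)
        var_t = np.where(nrisk > 1, var_t, 0.0)
    V = var_t.sum(axis=0)
    return U, V


def _logrank_chi2(
    time: np.ndarray, event: np.ndarray, z: np.ndarray
) -> tuple[float, float, float, float]:
    """Two-group log-rank chi-square plus (O/E)-ratio hazard estimate."""
    A, D = _event_tables(time, event)
    nrisk = A.sum(axis=1)
    d = D.sum(axis=1)
    n1 = (A & z[None, :]).sum(axis=1)
    d1 = (D & z[None, :]).sum(axis=1)
    U, V = _logrank_from_n1(n1.astype(float), d1.astype(float), nrisk.astype(float), d.astype(float))
    chi2 = float(U**2 / V) if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, 1)) if V > 0 else 1.0
    o1, e1 = float(d1.sum()), float((d * n1 / np.maximum(nrisk, 1)).sum())
    o0, e0 = float(d.sum() - d1.sum()), float(d.sum() - (d * n1 / np.maximum(nrisk, 1)).sum())
    hr = (o1 / e1) / (o0 / e0) if min(e1, e0) > 0 and o0 > 0 and o1 > 0 else float("nan")
    return chi2, p, hr, float(U)


@dataclass
class SurvivalComparison:
    chi2: float
    p: float  # naive chi-square(1) p of the (selected) statistic
    hr: float  # (O/E)-ratio hazard estimate, group 1 vs group 0
    group_sizes: dict[str, int]
    km_curves: dict[str, pd.DataFrame]  # group -> time/survival/at_risk
    cutoff: float = float("nan")
    p_adjusted: float = float("nan")  # permutation-adjusted (optimal cutoff only)
    n_permutations: int = 0


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
         "at_risk": at_risk.to_numpy()}
    )


def km_logrank(cohort: SurvivalCohort, labels: np.ndarray | pd.Series) -> SurvivalComparison:
    """Kaplan-Meier curves and two-group log-rank test.

    ``labels`` is boolean-like (group 1 vs group 0) aligned with the
    cohort rows. Identical groups give chi-square 0, p = 1.
    """
    z = np.asarray(labels).astype(bool)
    time, event = cohort.time, cohort.event
    if z.all() or not z.any():
        raise ValueError("both groups must be non-empty")
    chi2, p, hr, _ = _logrank_chi2(time, event, z)
    curves = {
        "group1": _km_curve(time[z], event[z]),
        "group0": _km_curve(time[~z], event[~z]),
    }
    return SurvivalComparison(
        chi2=chi2,
        p=p,
        hr=hr,
        group_sizes={"group1": int(z.sum()), "group0": int((~z).sum())},
        km_curves=curves,
    )


def _maxsel_chi2(
    A: np.ndarray,
    D: np.ndarray,
    nrisk: np.ndarray,
    d: np.ndarray,
    order: np.ndarray,
    valid: np.ndarray,
) -> np.ndarray:
    """Chi-square at every cutoff size k (high group = top-k of ``order``).

    Returns the chi-square profile over k = 1..n-1 with invalid cutoffs
    set to -inf.
    """
    Ao = np.cumsum(A[:, order], axis=1, dtype=np.float64)
    Do = np.cumsum(D[:, order], axis=1, dtype=np.float64)
    n1 = Ao[:, :-1]  # top-k at risk, k = 1..n-1
    d1 = Do[:, :-1]
    U, V = _logrank_from_n1(n1, d1, nrisk.astype(float), d.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, U**2 / np.maximum(V, 1e-300), 0.0)
    return np.where(valid, chi2, -np.inf)


def optimal_cutoff(
    scores: np.ndarray | pd.Series | None,
    cohort: SurvivalCohort,
    min_group_frac: float = 0.2,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SurvivalComparison:
    """Maximally selected log-rank dichotomization with permutation p.

    Scans every midpoint between consecutive distinct scores leaving
    both groups >= ``min_group_frac`` of the cohort, selects the cutoff
    maximizing the log-rank chi-square, and reports the naive
    chi-square(1) p together with a permutation-adjusted p (the rank of
    the observed maximal statistic among the maxima of
    ``n_permutations`` random score-to-patient reassignments).
    """
    s = cohort.score if scores is None else np.asarray(scores, dtype=float)
    time, event = cohort.time, cohort.event
    n = len(time)
    if n < 20 or event.sum() < 5:
        raise ValueError("need >= 20 patients with >= 5 events")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    g = int(np.ceil(min_group_frac * n))
    k = np.arange(1, n)
    distinct = s_sorted[:-1] > s_sorted[1:]
    valid = (k >= g) & (n - k >= g) & distinct
    if not valid.any():
        raise ValueError("no valid cutoff (scores all equal or groups too small)")
    A, D = _event_tables(time, event)
    nrisk = A.sum(axis=1)
    d = D.sum(axis=1)
    chi2_profile = _maxsel_chi2(A, D, nrisk, d, order, valid)
    best_k = int(np.argmax(chi2_profile)) + 1
    best_chi2 = float(chi2_profile[best_k - 1])
    cutoff = float((s_sorted[best_k - 1] + s_sorted[best_k]) / 2.0)
    z = s > cutoff
    naive_p = float(stats.chi2.sf(best_chi2, 1))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        prof = _maxsel_chi2(A, D, nrisk, d, perm, valid)
        if prof.max() >= best_chi2:
            exceed += 1
    p_adj = (1 + exceed) / (n_permutations + 1) if n_permutations else float("nan")

    comparison = km_logrank(cohort, z)
    return SurvivalComparison(
        chi2=best_chi2,
        p=naive_p,
        hr=comparison.hr,
        group_sizes={"group1": int(z.sum()), "group0": int((~z).sum())},
        km_curves=comparison.km_curves,
        cutoff=cutoff,
        p_adjusted=float(p_adj),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    auc: float
    se: float  # DeLong standard error
    ci: tuple[float, float]  # normal-approximation CI
    n_pos: int
    n_neg: int


def roc_auc(values: np.ndarray, labels: np.ndarray, ci_level: float = 0.95) -> RocResult:
    """AUC by the rank (Mann-Whitney) formulation with midrank ties.

    The variance is DeLong's, from the positive and negative placement
    components; the CI is the normal approximation, clipped to [0, 1].
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")
    r_all = stats.rankdata(x)
    r_pos = stats.rankdata(x[y])
    r_neg = stats.rankdata(x[~y])
    auc = (r_all[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    v10 = (r_all[y] - r_pos) / n0  # placements of positives
    v01 = 1.0 - (r_all[~y] - r_neg) / n1  # placements of negatives
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    se = float(np.sqrt(var))
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci = (max(0.0, auc - zq * se), min(1.0, auc + zq * se))
    return RocResult(float(auc), se, ci, n1, n0)
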