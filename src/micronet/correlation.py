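"""Correlation matrices from abundance tables, and edge filtering.

Pairwise taxon-taxon association is the first stage of co-occurrence network
construction.  Four estimators are offered: Pearson, Spearman (Pearson on
midranks), Kendall tau-b, and a basic SparCC estimator for compositional
count data (one-pass Friedman-Alm linear approximation; no iterative
strong-pair exclusion).  Significant edges are then retained by thresholding
|r| and (optionally BH-adjusted) p.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AbundanceTable, make_edge_table

SPARCC_OMEGA_FLOOR = 1e-12  # variance floor avoiding division by zero

METHODS = ("pearson", "spearman", "kendall", "sparcc")


@dataclasses.dataclass
class CorrelationResult:
    """Symmetric correlation (R) and p-value (P) matrices.

    R has zero diagonal and entries in [-1, 1]; P is symmetric with unit
    diagonal.  ``warnings`` lists taxa whose correlations were zeroed
    (constant profiles).  ``p_is_placeholder`` flags an all-zero P matrix
    (SparCC without a permutation test).
    """

    R: pd.DataFrame
    P: pd.DataFrame
    method: str
    n_samples: int
    warnings: list[str] = dataclasses.field(default_factory=list)
    p_is_placeholder: bool = False

    @property
    def taxa(self) -> list[str]:
        return list(self.R.index)


def _finish(R: np.ndarray, P: np.ndarray, taxa, method, n, warnings=None,
            placeholder=False) -> CorrelationResult:
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 0.0)
    P = np.clip((P + P.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return CorrelationResult(
        R=pd.DataFrame(R, index=taxa, columns=taxa),
        P=pd.DataFrame(P, index=taxa, columns=taxa),
        method=method, n_samples=n,
        warnings=list(warnings or []), p_is_placeholder=placeholder,
    )


def _pearson_with_p(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moment correlation between rows of X with two-sided t-test p-values.

    p from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    Constant rows yield r = 0, p = 1.
    """
    n = X.shape[1]
    sd = X.std(axis=1)
    constant = sd == 0
    Xs = X.copy()
    Xs[constant] = 0.0  # keeps corrcoef finite; rows zeroed below
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(Xs)
    R = np.nan_to_num(R, nan=0.0)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R ** 2))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    P[np.isnan(P)] = 0.0  # |r| == 1 -> t = inf -> p = 0
    P[constant, :] = 1.0
    P[:, constant] = 1.0
    return R, P


def prevalence_filter(table: AbundanceTable, min_prevalence: float) -> AbundanceTable:
    """Drop taxa observed (nonzero) in fewer than min_prevalence of samples."""
    if min_prevalence <= 0:
        return table
    prev = (table.values > 0).mean(axis=1)
    keep = prev >= min_prevalence
    sub = table.values.loc[keep]
    grp = {t: table.group[t] for t in sub.index} if table.group else None
    tax = table.taxonomy.loc[table.taxonomy.index.isin(sub.index)] \
        if table.taxonomy is not None else None
    return AbundanceTable(values=sub, taxonomy=tax, group=grp)


def correlate(
    table: AbundanceTable,
    method: str = "spearman",
    min_prevalence: float = 0.0,
    sparcc_pseudocount: float = 1.0,
    sparcc_permutations: int = 0,
    seed: int | None = None,
) -> CorrelationResult:
    """Correlation and p-value matrices for every taxon pair.

    Requires at least 4 samples.  Taxa present in fewer than
    ``min_prevalence`` of samples are dropped first.  Constant taxa get
    r = 0 / p = 1 and are reported in ``warnings``.  For ``sparcc``,
    p-values come from a permutation test when ``sparcc_permutations > 0``,
    otherwise an all-zero placeholder flagged in the result.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    table = prevalence_filter(table, min_prevalence)
    n = table.n_samples
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    taxa = table.taxa
    X = table.values.to_numpy(dtype=float)
    warnings = [t for t, sd in zip(taxa, X.std(axis=1)) if sd == 0]

    if method == "pearson":
        R, P = _pearson_with_p(X)
    elif method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, X)  # midranks
        R, P = _pearson_with_p(ranks)
    elif method == "kendall":
        D = len(taxa)
        R = np.zeros((D, D))
        P = np.ones((D, D))
        for i, j in itertools.combinations(range(D), 2):
            if X[i].std() == 0 or X[j].std() == 0:
                continue
            res = stats.kendalltau(X[i], X[j], variant="b",
                                   method="asymptotic")
            tau = 0.0 if np.isnan(res.statistic) else res.statistic
            R[i, j] = R[j, i] = tau
            P[i, j] = P[j, i] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    else:  # sparcc
        return _sparcc_with_p(table, sparcc_pseudocount,
                              sparcc_permutations, seed, warnings)
    return _finish(R, P, taxa, method, n, warnings)


# ---------------------------------------------------------------------------
# SparCC (basic one-pass estimator)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SparccState:
    """Intermediate SparCC quantities: log-ratio variances and basis variances."""

    T: np.ndarray          # pairwise log-ratio variance t_ij (zero diagonal)
    omega_sq: np.ndarray   # per-taxon basis variance, floored positive
    pseudocount: float


def sparcc_state(table: AbundanceTable, pseudocount: float = 1.0) -> SparccState:
    """Log-ratio variance matrix and basis variances under the sparsity
    approximation.

    Fractions are (counts + pseudocount) normalized per sample;
    t_ij = Var_samples(log(f_i / f_j)); with t_i = sum_j t_ij the basis
    variances solve the sparsity-approximated system
    omega_i^2 = (t_i - T_omega) / (D - 2), T_omega = sum_i t_i / (2 (D - 1)).
    """
    D = table.n_taxa
    if D < 4:
        raise ValueError(
            f"SparCC needs at least 4 taxa (got {D}); use pearson/spearman")
    counts = table.values.to_numpy(dtype=float) + pseudocount
    frac = counts / counts.sum(axis=0, keepdims=True)
    logf = np.log(frac)
    # t_ij = Var(log f_i - log f_j), sample variance over samples (ddof=1)
    diffs = logf[:, None, :] - logf[None, :, :]
    T = diffs.var(axis=2, ddof=1)
    np.fill_diagonal(T, 0.0)
    t_i = T.sum(axis=1)
    T_omega = t_i.sum() / (2.0 * (D - 1))
    omega_sq = np.maximum((t_i - T_omega) / (D - 2), SPARCC_OMEGA_FLOOR)
    return SparccState(T=T, omega_sq=omega_sq, pseudocount=pseudocount)


def sparcc_correlate(table: AbundanceTable,
                     pseudocount: float = 1.0) -> CorrelationResult:
    """Basic SparCC correlation (no p-values: P is an all-zero placeholder)."""
    if table.n_samples < 4:
        raise ValueError(f"need at least 4 samples, got {table.n_samples}")
    st = sparcc_state(table, pseudocount)
    om = st.omega_sq
    denom = 2.0 * np.sqrt(np.outer(om, om))
    R = np.clip((om[:, None] + om[None, :] - st.T) / denom, -1.0, 1.0)
    P = np.zeros_like(R)
    return _finish(R, P, table.taxa, "sparcc", table.n_samples,
                   placeholder=True)


def _sparcc_with_p(table, pseudocount, n_perm, seed, warnings):
    obs = sparcc_correlate(table, pseudocount)
    if n_perm <= 0:
        obs.warnings = warnings
        return obs
    rng = np.random.default_rng(seed)
    D = table.n_taxa
    robs = np.abs(obs.R.to_numpy())
    exceed = np.zeros((D, D))
    vals = table.values.to_numpy(dtype=float)
    for _ in range(n_perm):
        perm = np.empty_like(vals)
        for i in range(D):  # shuffle each taxon's samples independently
            perm[i] = vals[i, rng.permutation(vals.shape[1])]
        pt = AbundanceTable(values=pd.DataFrame(
            perm, index=table.taxa, columns=table.samples))
        rnull = np.abs(sparcc_correlate(pt, pseudocount).R.to_numpy())
        exceed += rnull >= robs
    P = (exceed + 1.0) / (n_perm + 1.0)  # two-sided empirical p
    res = _finish(obs.R.to_numpy(), P, table.taxa, "sparcc",
                  table.n_samples, warnings)
    return res


# ---------------------------------------------------------------------------
# Bipartite restriction and edge filtering
# ---------------------------------------------------------------------------

def bipartite_restrict(cor: CorrelationResult,
                       group: dict[str, str]) -> CorrelationResult:
    """Zero out within-group entries, keeping only between-group pairs.

    Same-group pairs get r = 0, p = 1; between-group entries are untouched.
    Every taxon must appear in ``group``.
    """
    taxa = cor.taxa
    missing = [t for t in taxa if t not in group]
    if missing:
        raise ValueError(f"taxa missing from group table: {missing[:10]}")
    labels = np.array([group[t] for t in taxa])
    same = labels[:, None] == labels[None, :]
    R = cor.R.to_numpy().copy()
    P = cor.P.to_numpy().copy()
    R[same] = 0.0
    P[same] = 1.0
    return _finish(R, P, taxa, cor.method, cor.n_samples, cor.warnings,
                   cor.p_is_placeholder)


def filter_edges(cor: CorrelationResult, r_min: float = 0.6,
                 p_max: float = 0.05, adjust: str = "none") -> pd.DataFrame:
    """Retain unordered pairs with |r| >= r_min and (adjusted) p <= p_max.

    ``adjust`` is ``none`` or ``BH`` (Benjamini-Hochberg over the upper
    triangle).  An empty edge table is legal output.
    """
    if not 0.0 <= r_min <= 1.0:
        raise ValueError(f"r_min must be in [0, 1], got {r_min}")
    if adjust not in {"none", "BH"}:
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    taxa = cor.taxa
    R = cor.R.to_numpy()
    P = cor.P.to_numpy()
    iu, ju = np.triu_indices(len(taxa), k=1)
    pvals = P[iu, ju]
    if adjust == "BH" and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")
    rows = []
    for i, j, p in zip(iu, ju, pvals):
        r = R[i, j]
        if abs(r) >= r_min and p <= p_max:
            rows.append((taxa[i], taxa[j], r, p))
    return make_edge_table(rows)
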