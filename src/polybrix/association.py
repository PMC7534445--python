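"""Allele-trait discovery for autopolyploid cohorts.

The engine follows the dominant-marker strategy used for complex
autopolyploids, where allele dosage cannot be called reliably: each
(locus, allele) pair becomes one binary presence/absence column, screened
against the quantitative phenotype with Welch's t-test and a
Benjamini-Hochberg correction, and the survivors are vetted against
population structure with a pair of nested ordinary-least-squares models,

    model 1:  SSC ~ Group + Allele + Group x Allele
    model 2:  SSC ~ Group + Allele within Group

An allele is retained as a diagnostic candidate when its screen q-value is
significant, its group x allele interaction is NOT significant (the effect
does not differ among groups), and its within-group allele term IS
significant (the association survives conditioning on structure).

Population groups may be inferred from the allele matrix itself with a
DAPC-style procedure (PCA followed by k-means over a candidate range of k,
choosing k by BIC) or supplied externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterStats",
    "ModelFit",
    "StructureGrouping",
    "filter_loci",
    "encode_presence_absence",
    "welch_screen",
    "bh_adjust",
    "infer_structure_groups",
    "fit_model1",
    "fit_model2",
    "select_diagnostic_alleles",
    "screen_alleles",
]


# ---------------------------------------------------------------------------
# locus filtering and dominant encoding
# ---------------------------------------------------------------------------

@dataclass
class FilterStats:
    """Attrition bookkeeping for :func:`filter_loci`."""

    n_input: int
    n_removed_missing: int
    n_removed_allele_count: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_missing - self.n_removed_allele_count


def filter_loci(
    table,
    max_missing: float = 0.20,
    min_alleles: int = 2,
    max_alleles: int = 4,
):
    """Keep loci with < ``max_missing`` missing data and 2-4 observed alleles.

    The missing-data bound is strict (a locus missing exactly 20% of cells
    is removed at the default). Distinct alleles are counted over the
    allele strings observed in non-missing calls, REF included whenever it
    appears in a call. Returns ``(filtered_table, FilterStats)``.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    miss = table.missing_fraction()
    keep_missing = miss < max_missing
    n_obs = pd.Series(
        [len(table.observed_alleles(i)) for i in range(table.n_loci)],
        index=table.loci.index,
    )
    keep_alleles = (n_obs >= min_alleles) & (n_obs <= max_alleles)
    removed_missing = int((~keep_missing).sum())
    removed_alleles = int((keep_missing & ~keep_alleles).sum())
    kept = table.loci.index[keep_missing & keep_alleles]
    stats_ = FilterStats(table.n_loci, removed_missing, removed_alleles)
    return table.subset_loci(kept), stats_


def encode_presence_absence(table) -> pd.DataFrame:
    """Dominant (presence/absence) encoding of every observed locus-allele.

    Returns a samples x columns DataFrame with MultiIndex columns
    ``(locus, allele)``; entries are 1.0 when the allele occurs at least
    once in the sample's call (dosage discarded), 0.0 when absent, NaN when
    the underlying cell is MISSING (propagated to all columns of the locus).
    """
    cols: list[tuple[str, str]] = []
    data: list[np.ndarray] = []
    n_samples = len(table.samples)
    for i, locus in enumerate(table.loci.index):
        names = table.allele_strings(i)
        seen: set[int] = set()
        for call in table.calls[i]:
            if call is not None:
                seen.update(call)
        for a in sorted(seen):
            col = np.empty(n_samples)
            for s in range(n_samples):
                call = table.calls[i, s]
                col[s] = np.nan if call is None else float(a in call)
            cols.append((locus, names[a]))
            data.append(col)
    index = pd.Index(table.samples, name="sample")
    if not cols:
        return pd.DataFrame(
            index=index,
            columns=pd.MultiIndex.from_tuples([], names=["locus", "allele"]),
            dtype=float,
        )
    return pd.DataFrame(
        np.column_stack(data),
        index=index,
        columns=pd.MultiIndex.from_tuples(cols, names=["locus", "allele"]),
    )


# ---------------------------------------------------------------------------
# screening: Welch's t-test + Benjamini-Hochberg
# ---------------------------------------------------------------------------

def welch_screen(
    matrix: pd.DataFrame, ssc: pd.Series, min_class_size: int = 3
) -> pd.DataFrame:
    """Two-sided Welch t-test of the phenotype between carriers and non-carriers.

    Vectorized over all columns of the presence/absence ``matrix``; samples
    with a missing entry are excluded column-wise. Columns with fewer than
    ``min_class_size`` samples in either class, or with zero variance in
    both classes, get ``p = NaN`` and are meant to be excluded from
    multiple-testing correction.

    Returns a DataFrame indexed like ``matrix.columns`` with columns
    n_present, n_absent, mean_present, mean_absent, effect_brix
    (carrier mean - non-carrier mean), t, df (Welch-Satterthwaite), p.
    """
    y = ssc.reindex(matrix.index).to_numpy(float)
    if np.isnan(y).any():
        missing = matrix.index[np.isnan(y)].tolist()
        raise ValueError(f"phenotype undefined for samples: {missing}")
    X = matrix.to_numpy(float)
    P = X == 1.0
    A = X == 0.0
    n1 = P.sum(axis=0).astype(float)
    n0 = A.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = y @ P
        s0 = y @ A
        q1 = (y**2) @ P
        q0 = (y**2) @ A
        m1 = s1 / n1
        m0 = s0 / n0
        v1 = (q1 - n1 * m1**2) / (n1 - 1)
        v0 = (q0 - n0 * m0**2) / (n0 - 1)
        v1 = np.maximum(v1, 0.0)  # guard tiny negative rounding
        v0 = np.maximum(v0, 0.0)
        se2 = v1 / n1 + v0 / n0
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    invalid = (n1 < min_class_size) | (n0 < min_class_size)
    invalid |= ~np.isfinite(t)
    t[invalid] = np.nan
    df[invalid] = np.nan
    p[invalid] = np.nan
    return pd.DataFrame(
        {
            "n_present": n1.astype(int),
            "n_absent": n0.astype(int),
            "mean_present": m1,
            "mean_absent": m0,
            "effect_brix": m1 - m0,
            "t": t,
            "df": df,
            "p": p,
        },
        index=matrix.columns,
    )


def bh_adjust(
    pvals: pd.Series | np.ndarray, alpha: float = 0.05
) -> tuple[pd.Series, pd.Series]:
    """Benjamini-Hochberg step-up q-values and the significant set.

    NaN p-values are excluded from the correction family and stay NaN
    (never significant). Returned q-values are monotone and bounded by 1.
    """
    from statsmodels.stats.multitest import multipletests

    p = pd.Series(pvals).astype(float)
    valid = p.notna()
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q_arr = np.full(len(p), np.nan)
    sig_arr = np.zeros(len(p), dtype=bool)
    if valid.any():
        mask = valid.to_numpy()
        _, qv, _, _ = multipletests(
            p[valid].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        q_arr[mask] = qv
        sig_arr[mask] = qv <= alpha
    return pd.Series(q_arr, index=p.index), pd.Series(sig_arr, index=p.index)


# ---------------------------------------------------------------------------
# DAPC-style structure inference
# ---------------------------------------------------------------------------

@dataclass
class StructureGrouping:
    """Result of PCA + k-means population grouping with BIC model choice."""

    n_pcs: int
    k_range: tuple[int, ...]
    bic: dict[int, float]
    k: int
    labels: pd.Series  # 1-based group label per sample
    seed: int = 0


def infer_structure_groups(
    matrix: pd.DataFrame,
    k_range: Sequence[int] = range(1, 11),
    pc_variance: float = 0.9,
    n_starts: int = 50,
    seed: int = 0,
    max_missing: float = 0.20,
) -> StructureGrouping:
    """Cluster samples from their allele profiles, choosing k by BIC.

    Columns with >= ``max_missing`` missing entries are dropped; remaining
    missing entries are mean-imputed per column (imputation is used here
    only — association tests never impute). The centered matrix is reduced
    by PCA to the fewest components reaching ``pc_variance`` of the
    variance, k-means is run on the scores for every k in ``k_range`` with
    ``n_starts`` restarts, and k minimizing

        BIC(k) = n * ln(WSS_k / n) + k * ln(n)

    is chosen (ties favor the smallest k). Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = matrix.to_numpy(float)
    n = X.shape[0]
    if n < 2:
        labels = pd.Series(1, index=matrix.index)
        return StructureGrouping(0, tuple(k_range), {1: 0.0}, 1, labels, seed)
    keep = np.isnan(X).mean(axis=0) < max_missing
    X = X[:, keep]
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X = X - X.mean(axis=0)

    n_comp = min(n - 1, X.shape[1])
    if n_comp == 0 or not X.any():  # no columns, or all samples identical
        scores = np.zeros((n, 1))
        n_pcs = 0
    else:
        pca = PCA(n_components=n_comp, svd_solver="full")
        all_scores = pca.fit_transform(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        if cum[-1] <= 0:
            n_pcs = 1
        else:
            n_pcs = int(np.searchsorted(cum, pc_variance) + 1)
            n_pcs = min(n_pcs, n_comp)
        scores = all_scores[:, :n_pcs]

    total_ss = float(((scores - scores.mean(axis=0)) ** 2).sum())
    ks = sorted(set(int(k) for k in k_range))
    if total_ss < 1e-12:  # degenerate: all samples identical in PC space
        labels = pd.Series(1, index=matrix.index, name="group")
        return StructureGrouping(
            n_pcs, tuple(ks), {1: float("nan")}, 1, labels, seed
        )
    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        if k < 1 or k > n:
            continue
        if k == 1:
            wss = total_ss
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
            lab = km.fit_predict(scores)
            wss = float(km.inertia_)
        wss = max(wss, 1e-12)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
        labels_by_k[k] = lab
    best_k = min(bic, key=lambda k: (round(bic[k], 9), k))
    labels = pd.Series(labels_by_k[best_k] + 1, index=matrix.index, name="group")
    return StructureGrouping(n_pcs, tuple(ks), bic, best_k, labels, seed)


# ---------------------------------------------------------------------------
# structure-correction models (nested OLS, extra-sum-of-squares F)
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """An extra-sum-of-squares F-test between two nested OLS fits.

    ``flag`` is ``None`` for a clean fit, ``"single_group"`` when only one
    group remains (model-1 interaction undefined), or ``"inestimable"``
    when the tested term adds no rank to the design (e.g. the allele is
    constant within every group, or perfectly confounded with group).
    """

    F: float
    p: float
    df_num: int
    df_den: int
    flag: str | None = None


def _rss_rank(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _ess_f(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray) -> ModelFit:
    rss_f, rank_f = _rss_rank(y, X_full)
    rss_r, rank_r = _rss_rank(y, X_red)
    df_num = rank_f - rank_r
    df_den = len(y) - rank_f
    if df_num <= 0 or df_den <= 0:
        return ModelFit(np.nan, np.nan, df_num, df_den, "inestimable")
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return ModelFit(float(F), p, df_num, df_den, None)


def _prepare(ssc, groups, allele):
    y = np.asarray(ssc, dtype=float)
    a = np.asarray(allele, dtype=float)
    g = np.asarray(pd.Categorical(np.asarray(groups)).codes)
    mask = ~np.isnan(y) & ~np.isnan(a) & (g >= 0)
    y, a, g = y[mask], a[mask], g[mask]
    levels = np.unique(g)
    dummies = np.column_stack(
        [(g == lev).astype(float) for lev in levels]
    ) if len(levels) else np.empty((len(g), 0))
    return y, a, g, levels, dummies


def fit_model1(ssc, groups, allele) -> ModelFit:
    """Group x allele interaction test:  SSC ~ Group + Allele + Group x Allele.

    The interaction is tested by the extra-sum-of-squares F comparing the
    full model to ``SSC ~ Group + Allele``. Interaction columns that are
    inestimable (a group carrying a single allele class) are absorbed by
    rank-aware degrees of freedom. A single group returns the
    ``"single_group"`` flag with NaN statistics.
    """
    y, a, g, levels, D = _prepare(ssc, groups, allele)
    if len(levels) < 2:
        return ModelFit(np.nan, np.nan, 0, 0, "single_group")
    ones = np.ones((len(y), 1))
    X_red = np.column_stack([ones, D[:, 1:], a])
    inter = D[:, 1:] * a[:, None]
    X_full = np.column_stack([X_red, inter])
    return _ess_f(y, X_full, X_red)


def fit_model2(ssc, groups, allele) -> ModelFit:
    """Within-group allele test:  SSC ~ Group + Allele within Group.

    Nested coding: one allele effect per group (Group:Allele columns). The
    joint F compares against ``SSC ~ Group``. With a single group this is
    exactly the one-way (pooled-variance) two-sample F for the allele.
    """
    y, a, g, levels, D = _prepare(ssc, groups, allele)
    if len(levels) < 1 or len(y) == 0:
        return ModelFit(np.nan, np.nan, 0, 0, "inestimable")
    ones = np.ones((len(y), 1))
    X_red = np.column_stack([ones, D[:, 1:]])
    nested = D * a[:, None]
    X_full = np.column_stack([X_red, nested])
    return _ess_f(y, X_full, X_red)


# ---------------------------------------------------------------------------
# end-to-end screen and selection
# ---------------------------------------------------------------------------

def screen_alleles(
    matrix: pd.DataFrame,
    ssc: pd.Series,
    groups: pd.Series | np.ndarray,
    alpha: float = 0.05,
    min_class_size: int = 3,
    fit_all: bool = False,
) -> pd.DataFrame:
    """Full association table: screen, correct, model, select.

    Structure-correction models are fitted only to screen-significant
    columns (set ``fit_all`` to fit every testable column). Returns one row
    per locus-allele with the screen statistics, BH q-value, both model
    F/p values and flags, and the final ``selected`` verdict.
    """
    records = welch_screen(matrix, ssc, min_class_size=min_class_size)
    q, sig = bh_adjust(records["p"], alpha=alpha)
    records = records.assign(q=q, screen_significant=sig)
    g = pd.Series(np.asarray(groups), index=matrix.index)
    y = ssc.reindex(matrix.index)

    f1 = np.full(len(records), np.nan)
    p1 = np.full(len(records), np.nan)
    flag1 = np.full(len(records), None, dtype=object)
    f2 = np.full(len(records), np.nan)
    p2 = np.full(len(records), np.nan)
    flag2 = np.full(len(records), None, dtype=object)
    to_fit = np.flatnonzero(sig.to_numpy() | fit_all)
    cols = matrix.to_numpy(float)
    for j in to_fit:
        allele = cols[:, j]
        m1 = fit_model1(y, g, allele)
        m2 = fit_model2(y, g, allele)
        f1[j], p1[j], flag1[j] = m1.F, m1.p, m1.flag
        f2[j], p2[j], flag2[j] = m2.F, m2.p, m2.flag
    records = records.assign(
        F_interaction=f1, p_interaction=p1, interaction_flag=flag1,
        F_within=f2, p_within=p2, within_flag=flag2,
    )
    return select_diagnostic_alleles(records, alpha=alpha)


def select_diagnostic_alleles(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the structure-independence selection rule.

    selected <=> q <= alpha
               AND (interaction p > alpha OR interaction undefined because
                    only one group exists)
               AND within-group p <= alpha.

    An NaN within-group p (inestimable nesting, e.g. allele perfectly
    confounded with group) never selects.
    """
    q_ok = records["q"].le(alpha).fillna(False)
    inter_ok = records["p_interaction"].gt(alpha).fillna(False) | (
        records["interaction_flag"] == "single_group"
    )
    within_ok = records["p_within"].le(alpha).fillna(False)
    out = records.copy()
    out["selected"] = (q_ok & inter_ok & within_ok).to_numpy()
    return out
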