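"""Micro-ROI detection and multivariate pattern extraction on bin matrices.

The workflow: a mass-univariate one-way ANOVA per bin across conditions,
Benjamini-Hochberg FDR over the family of in-contour bins (tolerable limit
q = 0.1 by default), Bonferroni-corrected planned contrasts inside the
detected micro-regions of interest, plus PCA on the subject x bin matrix
and canonical discriminant analysis (MDA) on regional density tables.

Each individual must appear once per analysis, so matrices are collapsed to
one averaged row per subject before testing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .binning import BinGrid, BinMatrix


# --------------------------------------------------------------------------
# mass-univariate per-bin testing


@dataclass
class MassUnivariateResult:
    f: np.ndarray              # per-bin F (or H for the rank test)
    p: np.ndarray
    zero_variance: np.ndarray  # bins constant in every row -> p = 1 by convention
    conditions: list[str]
    n_per_condition: dict


def _grouped_rows(matrix: BinMatrix, average_sections: bool) -> tuple[np.ndarray, np.ndarray]:
    m = matrix.subject_averaged() if average_sections else matrix
    return m.values.astype(float), m.meta["condition"].to_numpy()


def mass_univariate(
    matrix: BinMatrix,
    average_sections: bool = True,
    test: str = "anova",
) -> MassUnivariateResult:
    """One test per bin across conditions (ANOVA or Kruskal-Wallis).

    Bins with zero variance everywhere are reported with F = 0, p = 1 and
    flagged; a condition with a single subject is an error.
    """
    X, groups = _grouped_rows(matrix, average_sections)
    conds = sorted(set(groups))
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    samples = []
    for c in conds:
        rows = X[groups == c]
        if len(rows) < 2:
            raise ValueError(f"condition {c!r} has a single row; "
                             "tests need >=2 subjects per condition")
        samples.append(rows)
    n_bins = X.shape[1]
    zero_var = np.array([
        all(np.ptp(s[:, b]) == 0 for s in samples)
        and np.ptp(np.concatenate([s[:, b] for s in samples])) == 0
        for b in range(n_bins)
    ])
    f = np.zeros(n_bins)
    p = np.ones(n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "anova":
            fv, pv = stats.f_oneway(*samples, axis=0)
        elif test == "kruskal":
            fv = np.empty(n_bins)
            pv = np.empty(n_bins)
            for b in range(n_bins):
                try:
                    fv[b], pv[b] = stats.kruskal(*[s[:, b] for s in samples])
                except ValueError:  # all identical
                    fv[b], pv[b] = 0.0, 1.0
        else:
            raise ValueError("test must be 'anova' or 'kruskal'")
    ok = np.isfinite(fv) & np.isfinite(pv)
    f[ok] = fv[ok]
    p[ok] = pv[ok]
    f[zero_var] = 0.0
    p[zero_var] = 1.0
    return MassUnivariateResult(
        f, p, zero_var, conds, {c: len(s) for c, s in zip(conds, samples)})


# --------------------------------------------------------------------------
# multiple-comparison corrections


class FdrResult(NamedTuple):
    q: np.ndarray
    significant: np.ndarray


def _check_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def fdr_bh(p_values, q_threshold: float = 0.1, method: str = "bh") -> FdrResult:
    """Benjamini-Hochberg step-up q-values and the significant set.

    ``method='by'`` selects the Benjamini-Yekutieli variant, valid under
    arbitrary dependence (neighbouring bins are spatially correlated, which
    plain BH formally assumes away).
    """
    p = _check_pvalues(p_values)
    if not 0 <= q_threshold <= 1:
        raise ValueError("q_threshold must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError("method must be 'bh' or 'by'")
    _, q, _, _ = multipletests(p, alpha=max(q_threshold, 1e-12), method=sm_method)
    return FdrResult(q, q <= q_threshold)


class BonferroniResult(NamedTuple):
    p_corrected: np.ndarray
    significant: np.ndarray


def bonferroni(p_values, alpha: float = 0.05) -> BonferroniResult:
    """Bonferroni correction: significant iff p <= alpha / m."""
    p = _check_pvalues(p_values)
    m = len(p)
    return BonferroniResult(np.minimum(p * m, 1.0), p <= alpha / m)


# --------------------------------------------------------------------------
# MROI detection


@dataclass
class MroiResult:
    """Per-bin statistics with FDR-adjusted significance over the bin family."""

    grid: BinGrid
    f: np.ndarray                 # full length n_bins; nan outside the family
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray       # bool, False outside the family
    family_mask: np.ndarray       # bool, bins included in the testing family
    q_threshold: float
    conditions: list[str]
    zero_variance: np.ndarray
    contrasts: pd.DataFrame | None = None

    @property
    def significant_bins(self) -> np.ndarray:
        return np.flatnonzero(self.significant)

    def table(self) -> pd.DataFrame:
        centers = self.grid.bin_centers()
        nx, ny = self.grid.nx, self.grid.ny
        idx = np.arange(self.grid.n_bins)
        df = pd.DataFrame({
            "bin_index": idx,
            "bin_i": idx // ny,
            "bin_j": idx % ny,
            "x_center_um": centers[:, 0],
            "y_center_um": centers[:, 1],
            "in_family": self.family_mask,
            "F": self.f,
            "p": self.p,
            "q": self.q,
            "significant": self.significant,
        })
        return df


def detect_mroi(
    matrix: BinMatrix,
    q_threshold: float = 0.1,
    family_mask: np.ndarray | None = None,
    test: str = "anova",
    fdr_method: str = "bh",
    average_sections: bool = True,
) -> MroiResult:
    """Mass-univariate tests + FDR: the micro-region-of-interest detector.

    ``family_mask`` (flattened, length n_bins) restricts the multiple-testing
    family, typically to in-contour bins; excluded bins get nan statistics
    and are never significant.
    """
    mu = mass_univariate(matrix, average_sections=average_sections, test=test)
    n_bins = matrix.grid.n_bins
    if family_mask is None:
        fam = np.ones(n_bins, dtype=bool)
    else:
        fam = np.asarray(family_mask, dtype=bool).ravel()
        if fam.shape != (n_bins,):
            raise ValueError("family_mask must have one flag per bin")
        if not fam.any():
            raise ValueError("family_mask excludes every bin")
    f = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    q = np.full(n_bins, np.nan)
    sig = np.zeros(n_bins, dtype=bool)
    f[fam] = mu.f[fam]
    p[fam] = mu.p[fam]
    fdr = fdr_bh(mu.p[fam], q_threshold=q_threshold, method=fdr_method)
    q[fam] = fdr.q
    sig[fam] = fdr.significant
    return MroiResult(matrix.grid, f, p, q, sig, fam, q_threshold,
                      mu.conditions, mu.zero_variance)


def planned_contrasts(
    matrix: BinMatrix,
    bins: Sequence[int],
    contrasts: Sequence[tuple[str, str]],
    test: str = "t",
    alpha: float = 0.05,
    average_sections: bool = True,
) -> pd.DataFrame:
    """Two-group contrasts inside selected (typically MROI) bins.

    ``contrasts`` is a list of (condition_a, condition_b) pairs; ``test`` is
    ``"t"`` (two-sample t) or ``"mannwhitney"``.  The Bonferroni correction
    spans contrasts x bins tested.
    """
    X, groups = _grouped_rows(matrix, average_sections)
    bins = list(bins)
    if test not in ("t", "mannwhitney"):
        raise ValueError("test must be 't' or 'mannwhitney'")
    available = set(groups)
    rows = []
    for cond_a, cond_b in contrasts:
        for c in (cond_a, cond_b):
            if c not in available:
                raise ValueError(f"contrast names absent condition {c!r}; "
                                 f"available: {sorted(available)}")
        a, b = X[groups == cond_a], X[groups == cond_b]
        for bin_idx in bins:
            xa, xb = a[:, bin_idx], b[:, bin_idx]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                stat, p = 0.0, 1.0
            elif test == "t":
                stat, p = stats.ttest_ind(xa, xb)
            else:
                stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append({"condition_a": cond_a, "condition_b": cond_b,
                         "bin_index": int(bin_idx), "stat": float(stat),
                         "p": float(p)})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_corrected"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p"] <= alpha / m
    return out


# --------------------------------------------------------------------------
# PCA on the subject x bin matrix


@dataclass
class PcaResult:
    scores: np.ndarray                 # (n_subjects, n_components)
    loadings: np.ndarray               # (n_components, n_bins)
    explained_variance_ratio: np.ndarray
    subject_ids: list[str]
    conditions: np.ndarray
    separating_component: int | None   # the condition-separating component
    separation_stat: np.ndarray        # per-component between/within F

    def component_map_values(self, component: int) -> np.ndarray:
        return self.loadings[component]


def pca_topography(matrix: BinMatrix, scale: bool = False,
                   average_sections: bool = True) -> PcaResult:
    """Principal components of the centred subject x bin matrix via SVD.

    SVD handles bins >> subjects directly.  Bins are centred but not scaled
    by default (counts share units); the condition-separating component is
    the one whose scores maximise the between-condition F — identified
    descriptively, for mapping its per-bin loadings.
    """
    m = matrix.subject_averaged() if average_sections else matrix
    X = m.values.astype(float)
    groups = m.meta["condition"].to_numpy()
    n = len(X)
    if n < 3:
        raise ValueError("PCA needs at least 3 subjects")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-12 if s[0] > 0 else np.zeros(len(s), bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    scores = U * s
    total = (s ** 2).sum()
    evr = (s ** 2) / total if total > 0 else np.zeros_like(s)

    conds = sorted(set(groups))
    sep_stat = np.zeros(len(s))
    sep_comp: int | None = None
    if len(conds) >= 2 and all((groups == c).sum() >= 2 for c in conds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in range(len(s)):
                fv, _ = stats.f_oneway(*[scores[groups == c, k] for c in conds])
                sep_stat[k] = fv if np.isfinite(fv) else 0.0
        sep_comp = int(np.argmax(sep_stat))
    return PcaResult(scores, Vt, evr, m.meta["subject_id"].tolist(),
                     groups, sep_comp, sep_stat)


# --------------------------------------------------------------------------
# canonical discriminant analysis (MDA) on regional densities


@dataclass
class MdaResult:
    scores: np.ndarray                # (n_subjects, n_variates)
    coefficients: np.ndarray          # raw discriminant weights (p, n_variates)
    loadings: np.ndarray              # structure coefficients (p, n_variates)
    canonical_correlations: np.ndarray
    group_centroids: pd.DataFrame     # groups x variates
    predictors: list[str]
    groups: np.ndarray
    top_predictor: str                # largest |loading| on variate 1

    @property
    def n_variates(self) -> int:
        return self.scores.shape[1]


def _scatter_matrices(X: np.ndarray, groups: np.ndarray):
    conds = sorted(set(groups))
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in conds:
        sub = X[groups == c]
        mu = sub.mean(axis=0)
        d = sub - mu
        W += d.T @ d
        B += len(sub) * np.outer(mu - grand, mu - grand)
    return W, B, conds


def mda(table: pd.DataFrame | np.ndarray, grouping: Sequence[str]) -> MdaResult:
    """Canonical discriminant analysis of regional densities by group.

    Solves the between/within generalized eigenproblem; canonical
    correlations are sqrt(lambda / (1 + lambda)).  Loading values are
    structure coefficients: pooled within-group correlations between each
    predictor and the canonical scores — these quantify each region's
    contribution to the group separation.
    """
    if isinstance(table, pd.DataFrame):
        predictors = [str(c) for c in table.columns]
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        predictors = [f"var_{i}" for i in range(X.shape[1])]
    groups = np.asarray(grouping)
    if len(groups) != len(X):
        raise ValueError("grouping length must match table rows")
    conds = sorted(set(groups))
    g, n, p = len(conds), len(X), X.shape[1]
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n <= p + g:
        raise ValueError(
            f"{n} subjects cannot support {p} predictors with {g} groups; "
            "reduce the predictor set")
    W, B, _ = _scatter_matrices(X, groups)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "within-group covariance is singular; drop collinear predictors "
            "or add subjects (a small ridge regularisation also works)"
        ) from exc
    order = np.argsort(evals)[::-1]
    s = min(g - 1, p)
    evals = np.clip(evals[order][:s], 0.0, None)
    A = evecs[:, order][:, :s]
    # eigh normalises a' W a = 1; rescale to unit pooled within-group variance
    A = A * np.sqrt(n - g)
    scores = (X - X.mean(axis=0)) @ A
    canon = np.sqrt(evals / (1.0 + evals))

    # structure coefficients: pooled within-group predictor/score correlations
    Xw = np.vstack([X[groups == c] - X[groups == c].mean(axis=0) for c in conds])
    Sw = np.vstack([scores[groups == c] - scores[groups == c].mean(axis=0)
                    for c in conds])
    loadings = np.zeros((p, s))
    for j in range(p):
        xn = np.linalg.norm(Xw[:, j])
        for k in range(s):
            sn = np.linalg.norm(Sw[:, k])
            loadings[j, k] = (Xw[:, j] @ Sw[:, k]) / (xn * sn) if xn * sn else 0.0

    centroids = pd.DataFrame(
        [scores[groups == c].mean(axis=0) for c in conds],
        index=conds, columns=[f"variate_{k + 1}" for k in range(s)])
    top = predictors[int(np.argmax(np.abs(loadings[:, 0])))]
    return MdaResult(scores, A, loadings, canon, centroids, predictors,
                     groups, top)


@dataclass
class ConditionAnovaResult:
    wilks_lambda: float
    f: float
    df1: float
    df2: float
    p: float
    significant: bool
    per_region: pd.DataFrame   # region, F, p


def condition_anova(
    table: pd.DataFrame, grouping: Sequence[str], alpha: float = 0.05
) -> ConditionAnovaResult:
    """MANOVA gate (Wilks' lambda, Rao's F) then per-region one-way ANOVAs.

    With a single region the multivariate statistic reduces exactly to the
    one-way ANOVA decision.
    """
    X = table.to_numpy(dtype=float)
    groups = np.asarray(grouping)
    conds = sorted(set(groups))
    g, n, p = len(conds), len(X), X.shape[1]
    if g < 2:
        raise ValueError("need at least 2 groups")
    for c in conds:
        if (groups == c).sum() < 2:
            raise ValueError(f"group {c!r} has a single subject")
    W, B, _ = _scatter_matrices(X, groups)
    detW = np.linalg.det(W)
    detT = np.linalg.det(W + B)
    if detT <= 0 or detW < 0:
        raise ValueError("singular scatter matrices; reduce predictors")
    lam = detW / detT
    # Rao's F approximation
    q = g - 1
    t = np.sqrt((p ** 2 * q ** 2 - 4) / (p ** 2 + q ** 2 - 5)) \
        if (p ** 2 + q ** 2 - 5) > 0 else 1.0
    df1 = p * q
    w = n - 1 - (p + g) / 2.0
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    pval = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows = []
        for j, name in enumerate(table.columns):
            samples = [X[groups == c, j] for c in conds]
            if np.ptp(np.concatenate(samples)) == 0:
                fv, pv = 0.0, 1.0
            else:
                fv, pv = stats.f_oneway(*samples)
                if not np.isfinite(fv):
                    fv, pv = 0.0, 1.0
            rows.append({"region": str(name), "F": float(fv), "p": float(pv)})
    return ConditionAnovaResult(float(lam), float(f), float(df1), float(df2),
                                pval, bool(pval < alpha), pd.DataFrame(rows))
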