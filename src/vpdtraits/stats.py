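"""Community-level statistics for plot-scale trait comparison.

Implements the statistical toolkit of the pipeline: IQR outlier flagging,
basal-area-weighted community means with weighted standard errors, weighted
one-way ANOVA with Tukey–Kramer pairwise tests and a compact letter display,
two-factor (plot × species) variance partitioning by partial R², standardized
major axis regression, and unscaled (covariance) PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Traits analyzed on a log10 scale in the multivariate ordination.
LOG10_TRAITS = ("asat400", "kp", "huber", "vcmax25")


@dataclass
class CWMResult:
    plot_id: str
    trait_name: str
    cwm: float
    weighted_se: float
    n_samples: int
    tukey_letter: str = ""
    flags: list[str] = field(default_factory=list)


@dataclass
class VarpartResult:
    trait_name: str
    frac_a: float          # unique to plot
    frac_b: float          # unique to species composition
    frac_shared: float
    frac_d: float          # residual
    adjusted: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class SMAFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def flag_outliers_iqr(values, k: float = 1.5) -> np.ndarray:
    """Keep-mask under the interquartile-range rule.

    A value is kept iff it lies within [Q1 − k·IQR, Q3 + k·IQR]; quartiles
    use linear interpolation (type 7). The mask only flags — removal is a
    separate, logged decision. Fewer than 4 values: everything kept.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        return np.ones(len(values), dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def effective_n(weights) -> float:
    """Kish effective sample size (Σw)²/Σw²."""
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w) ** 2 / np.sum(w**2))


def cwm(values, weights):
    """Community-weighted mean and its weighted standard error.

    mean = Σwᵢxᵢ/Σwᵢ; the weighted (reliability-weight) sample variance is
    scaled by n_eff/(n_eff − 1) and the SE is √(variance/n_eff) with the
    Kish effective sample size, so equal weights reduce to the ordinary
    mean and SE. A single species yields an undefined (NaN) SE.

    Returns ``(mean, weighted_se, n)``.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if len(x) != len(w) or len(x) == 0:
        raise ValueError("values and weights must be equal-length, non-empty")
    mean = float(np.sum(w * x) / np.sum(w))
    if len(x) < 2:
        return mean, np.nan, 1
    n_eff = effective_n(w)
    var_w = float(np.sum(w * (x - mean) ** 2) / np.sum(w))
    if n_eff > 1:
        var_w *= n_eff / (n_eff - 1.0)
        se = float(np.sqrt(var_w / n_eff))
    else:
        se = np.nan
    return mean, se, len(x)


# --- weighted one-way ANOVA with Tukey–Kramer and letters ------------------

@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    groups: list[str]
    group_means: dict[str, float]
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    flags: list[str] = field(default_factory=list)


def weighted_anova_tukey(groups: dict[str, np.ndarray],
                         weights: dict[str, np.ndarray],
                         alpha: float = 0.05,
                         pairwise_p: bool = True) -> AnovaResult:
    """Weighted one-way ANOVA with Tukey–Kramer letters.

    The fit is weighted least squares on group indicators; pairwise tests
    use the studentized range on weighted group means with a pooled
    weighted mean square error and Kish effective n per group
    (Tukey–Kramer generalization to unequal, weighted samples). Letters
    are assigned by insert-and-absorb so two groups share a letter iff
    their pairwise test is non-significant at ``alpha``.

    ``pairwise_p=False`` skips the exact studentized-range p-values (the
    p-matrix holds NaN) and decides significance against the critical
    range value instead — one quantile evaluation rather than one
    integral per pair, with identical letters.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    flags: list[str] = []
    xs = {g: np.asarray(groups[g], dtype=float) for g in names}
    ws = {g: np.asarray(weights[g], dtype=float) for g in names}
    for g in names:
        if len(xs[g]) < 2:
            flags.append(f"group_{g}_singleton")

    means = {g: float(np.sum(ws[g] * xs[g]) / np.sum(ws[g])) for g in names}
    n_tot = sum(len(xs[g]) for g in names)
    k = len(names)
    grand = sum(np.sum(ws[g] * xs[g]) for g in names) / sum(np.sum(ws[g]) for g in names)
    ssb = sum(np.sum(ws[g]) * (means[g] - grand) ** 2 for g in names)
    ssw = sum(np.sum(ws[g] * (xs[g] - means[g]) ** 2) for g in names)
    df_b, df_w = k - 1, n_tot - k
    if df_w <= 0 or ssw <= 0:
        flags.append("singular_design")
        f_stat, p_value = np.nan, np.nan
        mse = np.nan
    else:
        # weights normalized to mean 1 so the weighted MSE keeps the data scale
        w_mean = np.mean(np.concatenate([ws[g] for g in names]))
        f_stat = float((ssb / df_b) / (ssw / df_w))
        p_value = float(sps.f.sf(f_stat, df_b, df_w))
        mse = float(ssw / w_mean / df_w)

    n_eff = {g: effective_n(ws[g]) for g in names}
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    sig: dict[tuple[str, str], bool] = {}
    if np.isfinite(mse) and mse > 0:
        q_crit = _studentized_range_crit(alpha, k, df_w)
        for i, gi in enumerate(names):
            for gj in names[i + 1:]:
                se = np.sqrt((mse / 2.0) * (1.0 / n_eff[gi] + 1.0 / n_eff[gj]))
                q = abs(means[gi] - means[gj]) / se
                sig[(gi, gj)] = sig[(gj, gi)] = bool(q > q_crit)
                if pairwise_p:
                    p = float(sps.studentized_range.sf(q, k, df_w))
                    pmat.loc[gi, gj] = pmat.loc[gj, gi] = p
                else:
                    pmat.loc[gi, gj] = pmat.loc[gj, gi] = np.nan
    else:
        pmat.loc[:, :] = np.nan
    letters = compact_letter_display(names, sig)
    return AnovaResult(f_stat, p_value, names, means, pmat, letters, flags)


@lru_cache(maxsize=512)
def _studentized_range_crit(alpha: float, k: int, df: int) -> float:
    """Cached critical value of the studentized range (expensive quadrature)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def compact_letter_display(groups: list[str],
                           significant: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Produces letter columns (cliques of mutually non-significant groups)
    such that two groups share a letter iff their pair is non-significant;
    redundant columns are absorbed.
    """
    columns: list[set[str]] = [set(groups)]
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            if not significant.get((a, b), False):
                continue
            for col in list(columns):
                if a in col and b in col:
                    columns.remove(col)
                    columns.append(col - {a})
                    columns.append(col - {b})
    # absorb columns contained in another
    columns = [c for c in columns if c]
    keep: list[set[str]] = []
    for c in sorted(columns, key=len, reverse=True):
        if not any(c <= other for other in keep):
            keep.append(c)
    # every group must carry a letter; ensure coverage of isolated groups
    for g in groups:
        if not any(g in c for c in keep):
            keep.append({g})
    # deterministic ordering: by first group appearance
    pos = {g: i for i, g in enumerate(groups)}
    keep.sort(key=lambda c: min(pos[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, col in zip(alphabet, keep):
        for g in col:
            out[g] += letter
    return {g: "".join(sorted(s)) for g, s in out.items()}


# --- variance partitioning -------------------------------------------------

def _r_squared(y: np.ndarray, dummies: np.ndarray) -> float:
    x = np.column_stack([np.ones(len(y)), dummies])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    return float(1.0 - np.sum(resid**2) / ss_tot)


def _dummy(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels), drop_first=True, dtype=float).to_numpy()


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def varpart_two_factor(values, plot_labels, species_labels,
                       adjusted: bool = False,
                       trait_name: str = "") -> VarpartResult:
    """Partition trait variance between plot and species factor sets.

    Three linear fits on dummy-coded factors give R²(plot), R²(species)
    and R²(plot+species); the unique, shared and residual components are

        frac_a      = R²(both) − R²(species)      (plot-unique)
        frac_b      = R²(both) − R²(plot)         (species-unique)
        frac_shared = R²(plot) + R²(species) − R²(both)
        frac_d      = 1 − R²(both)

    Raw fractions sum to 1 exactly. ``adjusted`` replaces every R² with
    its Ezekiel adjustment (small negative components possible).
    """
    y = np.asarray(values, dtype=float)
    plots = np.asarray(plot_labels)
    species = np.asarray(species_labels)
    if len(set(plots)) < 2 or len(set(species)) < 2:
        raise ValueError("need at least 2 plots and 2 species")
    dp = _dummy(plots)
    ds = _dummy(species)
    dboth = np.column_stack([dp, ds])
    r2_p = _r_squared(y, dp)
    r2_s = _r_squared(y, ds)
    r2_b = _r_squared(y, dboth)
    flags: list[str] = []
    # full confounding: both factors explain the identical subspace
    if abs(r2_b - max(r2_p, r2_s)) < 1e-12 and abs(r2_p - r2_s) < 1e-12:
        flags.append("confounded_factors")
    if adjusted:
        n = len(y)
        r2_p = _ezekiel(r2_p, n, dp.shape[1])
        r2_s = _ezekiel(r2_s, n, ds.shape[1])
        r2_b = _ezekiel(r2_b, n, dboth.shape[1])
    frac_a = r2_b - r2_s
    frac_b = r2_b - r2_p
    shared = r2_p + r2_s - r2_b
    frac_d = 1.0 - r2_b
    return VarpartResult(trait_name, float(frac_a), float(frac_b),
                         float(shared), float(frac_d), adjusted, flags)


# --- standardized major axis ----------------------------------------------

def sma_fit(x, y) -> SMAFit:
    """Standardized major axis regression.

    slope = sign(r)·sd(y)/sd(x); the p-value is that of the Pearson
    correlation, which carries the significance of the SMA relationship.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("sma_fit needs n >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("sma_fit requires finite values")
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    if sx == 0:
        raise ValueError("zero variance in x")
    r, p = sps.pearsonr(x, y)
    sign = np.sign(r) if r != 0 else 1.0
    slope = float(sign * sy / sx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAFit(slope, intercept, float(r), float(p), len(x))


# --- unscaled PCA ----------------------------------------------------------

@dataclass
class PCAResult:
    loadings: pd.DataFrame       # traits × axes
    scores: pd.DataFrame         # rows × axes
    explained_variance: np.ndarray
    arrow_lengths: pd.Series     # per trait, from the first two axes
    flags: list[str] = field(default_factory=list)


def apply_transforms(table: pd.DataFrame,
                     log10_traits=LOG10_TRAITS) -> pd.DataFrame:
    """Log10-transform registered traits (columns) where present."""
    out = table.copy()
    for t in log10_traits:
        if t in out.columns:
            if np.any(out[t] <= 0):
                raise ValueError(f"log10 transform of non-positive values in {t}")
            out[t] = np.log10(out[t])
    return out


def pca_unscaled(table: pd.DataFrame, log10_traits=LOG10_TRAITS,
                 n_axes: int | None = None) -> PCAResult:
    """Covariance-matrix PCA on centered, transformed, unstandardized data.

    Because traits are not scaled to unit variance, a trait's arrow length
    in the biplot reflects its variance. Loading signs follow a
    deterministic convention: the largest-magnitude loading of each axis
    is positive. Rows with missing values are dropped (complete cases).
    """
    data = apply_transforms(table, log10_traits).dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    x = data.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n = len(data)
    explained = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * 1e-12)) if s[0] > 0 else 0
    flags = []
    if rank < min(x.shape):
        flags.append("rank_deficient")
    n_keep = min(n_axes or rank, rank) if rank else 0
    vt = vt[:n_keep]
    u, s_k = u[:, :n_keep], s[:n_keep]
    # sign convention: largest-|loading| positive per axis
    for i in range(n_keep):
        jmax = np.argmax(np.abs(vt[i]))
        if vt[i, jmax] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    loadings = pd.DataFrame(vt.T, index=data.columns,
                            columns=[f"PC{i+1}" for i in range(n_keep)])
    scores = pd.DataFrame(u * s_k, index=data.index, columns=loadings.columns)
    sdev = s_k / np.sqrt(n - 1)
    n_arrow = min(2, n_keep)
    arrows = np.sqrt(((loadings.to_numpy()[:, :n_arrow] * sdev[:n_arrow]) ** 2).sum(axis=1))
    return PCAResult(loadings, scores, explained[:n_keep],
                     pd.Series(arrows, index=data.columns), flags)
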