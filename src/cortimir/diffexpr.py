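"""Two-condition negative-binomial differential expression for miRNA counts.

Implements the classic count-based workflow used for the screen: per-sample
size factors by median-of-ratios, per-gene dispersions by the method of
moments with a parametric mean-dispersion fit d(mu) = a0 + a1/mu and
conservative max-sharing, a conditioned NB exact test on condition totals,
Benjamini-Hochberg FDR, and the reporting convention of the screen's summary
table: log2 of the ratio of per-condition mean RPM, with DE called at
|log2 ratio| > 1 and adjusted p < 0.01 (both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .synthetic_data import CountMatrix

__all__ = [
    "DispersionModel",
    "DISPERSION_FLOOR",
    "size_factors",
    "estimate_dispersions",
    "nb_exact_test",
    "bh_adjust",
    "log2_ratio_rpm",
    "call_de",
    "run_de",
]

DISPERSION_FLOOR = 1e-8


@dataclass
class DispersionModel:
    """Per-gene empirical and working dispersions plus the fitted curve.

    ``working = max(empirical, a0 + a1/mu, floor)`` — sharing toward the
    fitted trend only ever increases a gene's dispersion, which keeps the
    exact test conservative for genes whose few replicates happened to
    agree too well.
    """

    empirical: pd.Series
    a0: float
    a1: float
    working: pd.Series
    base_mean: pd.Series

    def fitted(self, mu: np.ndarray | pd.Series) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a0 + self.a1 / mu


def size_factors(counts: pd.DataFrame, fallback_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Each sample's factor is the median, over genes whose geometric mean
    across samples is positive, of count / geometric mean. If no gene is
    positive in every sample, either raise (default) or, with
    ``fallback_pseudo_reference=True``, compute gene geometric means over
    the positive entries of genes expressed in at least half the samples.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(mat)
    log_geomeans = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomeans)
    if not usable.any():
        if not fallback_pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; re-run with "
                "fallback_pseudo_reference=True to use a pseudo-reference "
                "built from positive entries only"
            )
        positive = mat > 0
        expressed = positive.sum(axis=1) >= mat.shape[1] / 2
        if not expressed.any():
            raise ValueError("count matrix is too sparse for size-factor estimation")
        ref = np.full(mat.shape[0], np.nan)
        for g in np.flatnonzero(expressed):
            ref[g] = log_counts[g, positive[g]].mean()
        log_geomeans, usable = ref, expressed
    # median of count/geomean ratios on the linear scale
    ratios = np.where(
        mat[usable] > 0,
        np.exp(log_counts[usable] - log_geomeans[usable, None]),
        np.nan,
    )
    factors = np.nanmedian(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _pooled_moments(
    norm: np.ndarray, conditions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Base mean and pooled within-condition variance of normalized counts."""
    base_mean = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    df = 0
    for cond in np.unique(conditions):
        cols = conditions == cond
        n = int(cols.sum())
        if n < 2:
            continue
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += n - 1
    if df == 0:
        raise ValueError(
            "no condition has >= 2 replicates; use method='blind' to pool "
            "all samples as one group"
        )
    return base_mean, ss / df


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    conditions: pd.Series,
    method: str = "pooled",
    floor: float = DISPERSION_FLOOR,
) -> DispersionModel:
    """Method-of-moments dispersions with a parametric 1/mu trend fit.

    On common-scale counts q = K/s, the empirical dispersion is
    ``alpha = (s2 - mu * zbar) / mu**2`` where s2 is the (within-condition
    pooled) sample variance, mu the base mean and zbar the mean inverse size
    factor — the shot-noise term mu*zbar is what a pure Poisson gene would
    show. The trend d(mu) = a0 + a1/mu is fitted by gamma-family regression
    on genes with positive empirical dispersion (ordinary least squares as
    fallback), and the working dispersion is max(empirical, fitted, floor).

    ``method="blind"`` pools all samples as a single group (for designs
    without replication; conservative).
    """
    norm = counts.to_numpy(dtype=float) / sf.to_numpy(dtype=float)
    cond = (
        np.zeros(counts.shape[1], dtype=int)
        if method == "blind"
        else conditions.loc[counts.columns].to_numpy()
    )
    base_mean, s2 = _pooled_moments(norm, cond)
    zbar = float((1.0 / sf.to_numpy(dtype=float)).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        empirical = np.where(base_mean > 0, (s2 - base_mean * zbar) / base_mean**2, np.nan)
    a0, a1 = _fit_dispersion_trend(base_mean, empirical)
    with np.errstate(divide="ignore"):
        fitted = np.where(base_mean > 0, a0 + a1 / base_mean, np.nan)
    working = np.fmax(np.fmax(np.nan_to_num(empirical, nan=0.0), np.nan_to_num(fitted, nan=0.0)), floor)
    index = counts.index
    return DispersionModel(
        empirical=pd.Series(empirical, index=index, name="empirical_dispersion"),
        a0=a0,
        a1=a1,
        working=pd.Series(working, index=index, name="working_dispersion"),
        base_mean=pd.Series(base_mean, index=index, name="base_mean"),
    )


def _fit_dispersion_trend(base_mean: np.ndarray, empirical: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(empirical) & (empirical > 0) & (base_mean > 0)
    if ok.sum() < 2:
        return 0.0, 0.0
    y = empirical[ok]
    x = 1.0 / base_mean[ok]
    try:
        import statsmodels.api as sm

        exog = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                y, exog, family=sm.families.Gamma(link=sm.families.links.Identity())
            ).fit(maxiter=100)
        a0, a1 = float(fit.params[0]), float(fit.params[1])
        if not (np.isfinite(a0) and np.isfinite(a1)):
            raise ValueError
    except Exception:
        a1, a0 = np.polyfit(x, y, 1)
        a0, a1 = float(a0), float(a1)
    return max(a0, 0.0), max(a1, 0.0)


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    dispersion: float,
) -> float:
    """Conditioned NB exact test on the two condition totals.

    With K_A, K_B the observed condition sums and K_S their total, the
    p-value sums, over all splits (a, K_S - a), the probabilities
    P(a) * P(K_S - a) that are no larger than the observed split's, divided
    by the total over all splits. Each condition total is NB with
    size-factor-scaled mean mu = q_hat * sum(s_j) (q_hat = K_S / sum of all
    size factors) and variance mu + dispersion * q_hat^2 * sum(s_j^2) — the
    sum of the per-sample NB variances, so a condition with m replicates
    has effective total dispersion ~ dispersion/m. All counts zero returns
    1 by convention.
    """
    if dispersion < DISPERSION_FLOOR:
        raise ValueError(f"dispersion must be >= {DISPERSION_FLOOR}")
    k_a = int(round(float(np.sum(counts_a))))
    k_b = int(round(float(np.sum(counts_b))))
    k_s = k_a + k_b
    if k_s == 0:
        return 1.0
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    s_a = float(sf_a.sum())
    s_b = float(sf_b.sum())
    q = k_s / (s_a + s_b)
    mu_a, mu_b = q * s_a, q * s_b
    size_a = s_a**2 / (dispersion * float((sf_a**2).sum()))
    size_b = s_b**2 / (dispersion * float((sf_b**2).sum()))
    ks = np.arange(k_s + 1)
    log_p = stats.nbinom.logpmf(ks, size_a, size_a / (size_a + mu_a)) + stats.nbinom.logpmf(
        k_s - ks, size_b, size_b / (size_b + mu_b)
    )
    log_obs = log_p[k_a]
    keep = log_p <= log_obs + 1e-7  # tolerate fp ties with the observed split
    p = float(np.exp(logsumexp(log_p[keep]) - logsumexp(log_p)))
    return min(p, 1.0)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    if isinstance(p_values, pd.Series):
        return pd.Series(adjusted, index=p_values.index, name="adjusted_p")
    return adjusted


def log2_ratio_rpm(mean_rpm_a: float, mean_rpm_b: float) -> float:
    """log2(mean RPM in condition B / mean RPM in condition A).

    This is the reporting convention of the screen's summary table (B = the
    differentiating 39C condition). A zero mean on either side leaves the
    ratio undefined: NaN is returned with a warning, no pseudo-count.
    """
    if mean_rpm_a <= 0 or mean_rpm_b <= 0:
        warnings.warn("zero mean RPM: log2 ratio undefined, returning NaN")
        return float("nan")
    return float(np.log2(mean_rpm_b / mean_rpm_a))


def call_de(
    results: pd.DataFrame, lfc_cut: float = 1.0, fdr_cut: float = 0.01
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the DE gates: |log2_ratio| > lfc_cut AND adjusted_p < fdr_cut.

    Both inequalities are strict. Rows with missing log2_ratio are never
    called DE (warned). Adds a ``direction`` column in {"up", "down",
    "none"} and returns (table, summary) with summary counts n_total,
    n_up, n_down.
    """
    out = results.copy()
    missing = out["log2_ratio"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} miRNA(s) with undefined log2 ratio excluded from DE calls")
    is_de = (~missing) & (out["log2_ratio"].abs() > lfc_cut) & (out["adjusted_p"] < fdr_cut)
    direction = np.where(~is_de, "none", np.where(out["log2_ratio"] > 0, "up", "down"))
    out["direction"] = direction
    summary = {
        "n_total": int(is_de.sum()),
        "n_up": int((direction == "up").sum()),
        "n_down": int((direction == "down").sum()),
    }
    return out, summary


def run_de(
    matrix: CountMatrix,
    condition_a: str = "33C",
    condition_b: str = "39C",
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.01,
    dispersion_method: str = "pooled",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full differential-expression stage on a two-condition count matrix.

    Produces the summary-table layout: per-condition mean raw count and mean
    RPM (RPM from the matrix's library sizes), log2 RPM ratio (B vs A),
    exact-test p-value, BH-adjusted p-value, and the DE direction call.
    """
    counts = matrix.counts
    cond = matrix.conditions
    cols_a = cond.index[cond == condition_a]
    cols_b = cond.index[cond == condition_b]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError(f"conditions {condition_a!r}/{condition_b!r} not found")
    sf = size_factors(counts)
    model = estimate_dispersions(counts, sf, cond, method=dispersion_method)
    rpm = matrix.rpm()
    sfa = sf[cols_a].to_numpy()
    sfb = sf[cols_b].to_numpy()
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in counts.index:
            ka = counts.loc[gene, cols_a].to_numpy()
            kb = counts.loc[gene, cols_b].to_numpy()
            p = nb_exact_test(ka, kb, sfa, sfb, float(model.working[gene]))
            records.append(
                {
                    "mirna_id": gene,
                    "mean_count_a": float(ka.mean()),
                    "mean_count_b": float(kb.mean()),
                    "mean_rpm_a": float(rpm.loc[gene, cols_a].mean()),
                    "mean_rpm_b": float(rpm.loc[gene, cols_b].mean()),
                    "log2_ratio": log2_ratio_rpm(
                        float(rpm.loc[gene, cols_a].mean()), float(rpm.loc[gene, cols_b].mean())
                    ),
                    "p_value": p,
                }
            )
    table = pd.DataFrame.from_records(records).set_index("mirna_id")
    table["adjusted_p"] = bh_adjust(table["p_value"])
    return call_de(table, lfc_cut=lfc_cut, fdr_cut=fdr_cut)
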