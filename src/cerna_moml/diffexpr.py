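"""Differential expression: low-count filter, TMM, voom-style weights,
moderated t-statistics, and threshold selection.

This is a deliberately compact re-implementation of the standard
count-based DE stack, not a wrapper around it:

* features with log2-CPM < 1 in more than half the samples are dropped;
* library composition is corrected with trimmed-mean-of-M-values (TMM)
  scale factors (30% trim on M, 5% on A, factors rescaled to geometric
  mean one);
* counts are transformed to log2-CPM with a 0.5 prior count, and
  per-observation precision weights are derived from a LOWESS fit of the
  square-root residual standard deviation against mean log2 count
  (weight = predicted SD to the power -4);
* per-feature weighted least squares on the tumour/normal indicator is
  followed by empirical-Bayes variance moderation: residual variances are
  shrunk toward a prior estimated by method of moments on the scaled-F
  distribution of the sample variances, and moderated t-statistics use
  the augmented degrees of freedom;
* features pass at |log2FC| > 1 and Benjamini-Hochberg FDR < 0.01
  (strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .formats_io import CountsMatrix, TUMOUR, NORMAL


@dataclass
class NormalizedExpression:
    """voom-style normalized expression: log2-CPM plus precision weights."""

    matrix: pd.DataFrame  # log2-CPM, features x samples
    weights: pd.DataFrame  # same shape, > 0
    tmm_factors: pd.Series  # per-sample scale factors, > 0


@dataclass
class DEResult:
    feature_id: str
    log_fc: float
    t_mod: float
    p: float
    fdr: float
    passed: bool


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def log_cpm(counts: np.ndarray, lib_size: np.ndarray | None = None,
            prior: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a prior count, on raw library sizes."""
    counts = np.asarray(counts, dtype=float)
    if lib_size is None:
        lib_size = counts.sum(axis=0)
    return np.log2((counts + prior) / (lib_size + 2.0 * prior) * 1e6)


def filter_low_expressed(counts: CountsMatrix, min_log_cpm: float = 1.0,
                         max_low_fraction: float = 0.5) -> CountsMatrix:
    """Drop features with log2-CPM below ``min_log_cpm`` in strictly more
    than ``max_low_fraction`` of the samples."""
    if counts.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lcpm = log_cpm(counts.values.to_numpy())
    low_frac = (lcpm < min_log_cpm).mean(axis=1)
    keep = low_frac <= max_low_fraction
    if not keep.any():
        raise ValueError("empty after filtering")
    kept = [f for f, k in zip(counts.feature_ids, keep) if k]
    return counts.subset_features(kept)


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """TMM factor of one sample against the reference column."""
    n_obs, n_ref = obs.sum(), ref.sum()
    use = (obs > 0) & (ref > 0)
    if use.sum() == 0:
        return 1.0
    o, r = obs[use].astype(float), ref[use].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # precision weights from the delta method on binomial counts
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.allclose(m, m[0], atol=1e-10):
        return float(2.0 ** np.average(m, weights=1.0 / w))
    m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
    a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
    keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if keep.sum() == 0:
        return 1.0
    return float(2.0 ** np.average(m[keep], weights=1.0 / w[keep]))


def tmm_factors(counts: CountsMatrix, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean one.

    The reference sample defaults to the column whose upper quartile of
    CPM is closest to the mean upper quartile.
    """
    v = counts.values.to_numpy().astype(float)
    lib = v.sum(axis=0)
    if (lib == 0).any():
        bad = counts.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero library size")
    if ref_sample is None:
        uq = np.array([np.quantile(v[:, j] / lib[j], 0.75) for j in range(v.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.sample_ids.index(ref_sample)
    ref = v[:, ref_idx]
    factors = np.array([
        _tmm_pair_factor(v[:, j], ref, trim_m, trim_a) for j in range(v.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def voom_transform(counts: CountsMatrix, factors: pd.Series | None = None,
                   weight_mode: str = "voom", span: float = 0.5) -> NormalizedExpression:
    """log2-CPM on TMM-scaled libraries with mean-variance precision weights.

    With ``weight_mode="none"`` all weights are 1.  Weights come from a
    LOWESS fit of sqrt(residual SD) on mean log2 count, evaluated per
    observation at the fitted count and raised to the -4 power on the SD
    scale.  With fewer than 10 features the LOWESS trend is unreliable and
    weights fall back to 1 with a warning.
    """
    if factors is None:
        factors = tmm_factors(counts)
    v = counts.values.to_numpy().astype(float)
    lib = v.sum(axis=0)
    eff_lib = lib * factors.reindex(counts.sample_ids).to_numpy()
    if (eff_lib <= 0).any():
        raise ValueError("non-positive effective library size")
    logcpm = np.log2((v + 0.5) / (eff_lib + 1.0) * 1e6)

    groups = counts.group.to_numpy()
    design = np.column_stack([np.ones(v.shape[1]), (groups == TUMOUR).astype(float)])

    weights = np.ones_like(logcpm)
    if weight_mode == "voom":
        if v.shape[0] < 10:
            warnings.warn("fewer than 10 features: voom weights fall back to 1")
        else:
            coef, *_ = np.linalg.lstsq(design, logcpm.T, rcond=None)
            fitted = (design @ coef).T
            resid = logcpm - fitted
            dof = v.shape[1] - design.shape[1]
            sigma = np.sqrt((resid ** 2).sum(axis=1) / dof)
            mean_log_count = logcpm.mean(axis=1) + np.mean(np.log2(eff_lib + 1.0)) - np.log2(1e6)
            fit = lowess(np.sqrt(sigma), mean_log_count, frac=span, return_sorted=True)
            fx, fy = fit[:, 0], fit[:, 1]
            # per-observation fitted log2 count under the group-mean model
            fitted_count = fitted + np.log2(eff_lib + 1.0)[None, :] - np.log2(1e6)
            sqrt_sd = np.interp(fitted_count, fx, fy)
            sqrt_sd = np.clip(sqrt_sd, 1e-6, None)
            weights = sqrt_sd ** -4
    elif weight_mode != "none":
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    idx, cols = counts.values.index, counts.values.columns
    return NormalizedExpression(
        matrix=pd.DataFrame(logcpm, index=idx, columns=cols),
        weights=pd.DataFrame(weights, index=idx, columns=cols),
        tmm_factors=factors,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F model for sample variances.

    Under the hierarchical model s2 ~ s0^2 * F(df, d0), log(s2) has known
    digamma/trigamma moments; matching them yields the prior degrees of
    freedom d0 and prior variance s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-300, None)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = np.sum((e - emean) ** 2) / max(n - 1, 1)
    evar -= special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return float(d0), float(s0_2)


def moderated_t(norm: NormalizedExpression, groups: pd.Series | None = None,
                d0: float | None = None) -> list[DEResult]:
    """Per-feature weighted two-group fit with empirical-Bayes moderation.

    Parameters
    ----------
    norm
        voom-style normalized expression (weights may all be 1).
    groups
        Per-sample tumour/normal labels; defaults to labels carried by
        the expression columns' order is taken from ``norm.matrix``.
    d0
        Prior degrees of freedom override: 0 disables moderation
        (ordinary t), ``numpy.inf`` pools completely to the prior
        variance.  ``None`` estimates d0 from the data.
    """
    if groups is None:
        raise ValueError("groups labels are required")
    groups = groups.reindex(norm.matrix.columns)
    is_t = (groups == TUMOUR).to_numpy()
    is_n = (groups == NORMAL).to_numpy()
    if is_t.sum() == 0 or is_n.sum() == 0:
        raise ValueError("both tumour and normal groups must be non-empty")
    n_samples = norm.matrix.shape[1]
    resid_df = n_samples - 2
    if resid_df <= 0:
        raise ValueError("zero residual degrees of freedom")

    y = norm.matrix.to_numpy()
    w = norm.weights.to_numpy()
    sw_t = (w * is_t).sum(axis=1)
    sw_n = (w * is_n).sum(axis=1)
    mean_t = (w * y * is_t).sum(axis=1) / sw_t
    mean_n = (w * y * is_n).sum(axis=1) / sw_n
    log_fc = mean_t - mean_n
    fitted = np.where(is_t[None, :], mean_t[:, None], mean_n[:, None])
    s2 = (w * (y - fitted) ** 2).sum(axis=1) / resid_df
    se_unit = np.sqrt(1.0 / sw_t + 1.0 / sw_n)

    if d0 is None:
        d0_hat, s0_2 = fit_f_dist(s2, resid_df)
    else:
        d0_hat = float(d0)
        _, s0_2 = fit_f_dist(s2, resid_df)
    if np.isinf(d0_hat):
        s2_post = np.full_like(s2, s0_2)
        total_df = np.inf
    elif d0_hat == 0:
        s2_post = s2
        total_df = resid_df
    else:
        s2_post = (d0_hat * s0_2 + resid_df * s2) / (d0_hat + resid_df)
        total_df = d0_hat + resid_df

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / (np.sqrt(s2_post) * se_unit)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), total_df)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    results = []
    for i, fid in enumerate(norm.matrix.index):
        passed = bool(abs(log_fc[i]) > 1.0 and fdr[i] < 0.01)
        results.append(DEResult(fid, float(log_fc[i]), float(t_mod[i]),
                                float(p[i]), float(fdr[i]), passed))
    return results


def select_de(results: list[DEResult], feature_class: pd.Series,
              lfc_min: float = 1.0, fdr_max: float = 0.01) -> dict:
    """Split features passing |log2FC| > lfc_min and FDR < fdr_max by class.

    Both inequalities are strict.  Returns {"mRNA": set, "lncRNA": set,
    "miRNA": set}.
    """
    out = {c: set() for c in ("mRNA", "lncRNA", "miRNA")}
    for r in results:
        if abs(r.log_fc) > lfc_min and r.fdr < fdr_max:
            cls = feature_class.get(r.feature_id)
            if cls in out:
                out[cls].add(r.feature_id)
    return out


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log_fc": [r.log_fc for r in results],
            "t_mod": [r.t_mod for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "passed": [r.passed for r in results],
        }
    ).set_index("feature_id")
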