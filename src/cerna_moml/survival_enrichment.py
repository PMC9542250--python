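"""Survival screening of shared ceRNA genes and gene-set enrichment.

Each shared gene is dichotomized at the cohort median of its tumour
expression (ties at the median go to the low group); the low and high
groups are compared with Kaplan-Meier curves and the log-rank test, and
the hazard ratio of high vs low comes from a univariate Cox
proportional-hazards fit (Efron tie handling).  A gene is
combination-significant when its log-rank p is below the significance
level in EVERY cohort of the combination it is shared across.

Gene-set enrichment is a generic upper-tail hypergeometric test of a
gene list against user-supplied GMT sets over an explicit universe, with
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cross_cancer import SharedCeRNATable
from .diffexpr import bh_adjust
from .formats_io import GeneSetCollection


@dataclass
class GeneSurvivalResult:
    gene_id: str
    cohort_id: str
    hazard_ratio: float
    logrank_p: float
    significant: bool
    direction: str  # "high-risk" | "low-risk" | "none"
    diverged: bool = False


class KMEstimate:
    """Product-limit survival curve S(t), right-continuous step function."""

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if times.size == 0:
            raise ValueError("empty survival input")
        if (times < 0).any():
            raise ValueError("negative follow-up time")
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        self._kmf = kmf
        sf = kmf.survival_function_
        self.step_times = sf.index.to_numpy(dtype=float)
        self.step_survival = sf.iloc[:, 0].to_numpy(dtype=float)
        if (np.diff(self.step_survival) > 1e-12).any():
            raise AssertionError("survival curve must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t) evaluated right-continuously; S(t) = 1 before the first event."""
        idx = np.searchsorted(self.step_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.step_survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate of the survival function."""
    return KMEstimate(np.asarray(times), np.asarray(events))


def dichotomize(expr_gene: pd.Series | np.ndarray, cutpoint: str = "median") -> pd.Series:
    """Split samples into low/high expression groups.

    ``median``: high = strictly above the cohort median, ties at the
    median go to low.  ``quartiles``: low = bottom quartile, high = top
    quartile, middle samples dropped (NaN).
    """
    x = pd.Series(expr_gene, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    if x.nunique() == 1:
        raise ValueError("constant expression: cannot dichotomize")
    if cutpoint == "median":
        med = x.median()
        return pd.Series(np.where(x > med, "high", "low"), index=x.index)
    if cutpoint == "quartiles":
        lo, hi = x.quantile([0.25, 0.75])
        out = pd.Series(np.nan, index=x.index, dtype=object)
        out[x <= lo] = "low"
        out[x > hi] = "high"
        return out
    raise ValueError(f"unknown cutpoint {cutpoint!r}")


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(groups, times, events) -> tuple[float, float, bool]:
    """Univariate Cox PH fit on the binary low/high indicator.

    Returns (hazard ratio of high vs low, Wald p, diverged flag).  The
    diverged flag marks monotone-likelihood fits (complete separation of
    events between groups), where the coefficient runs away.
    """
    g = pd.Series(groups).map({"low": 0.0, "high": 1.0})
    if g.isna().any():
        raise ValueError("groups must be 'low'/'high'")
    df = pd.DataFrame({
        "high": g.to_numpy(),
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
    })
    if df["high"].nunique() < 2:
        raise ValueError("both groups must be non-empty")
    cph = CoxPHFitter()
    diverged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            return np.inf, np.nan, True
        diverged = any("convergence" in str(w.message).lower() for w in caught)
    coef = float(cph.params_["high"])
    p = float(cph.summary.loc["high", "p"])
    if abs(coef) > 10:
        diverged = True
    return float(np.exp(coef)), p, diverged


def screen_shared_genes(shared: SharedCeRNATable, expression: dict,
                        clinical: dict, alpha: float = 0.05,
                        cutpoint: str = "median") -> pd.DataFrame:
    """Survival-screen every gene of every shared combination.

    ``expression`` and ``clinical`` map cohort id -> tumour expression
    matrix (features x samples) and clinical table (index sample_id,
    columns time/event).  For each combination of >= 2 cohorts, each
    shared gene is tested in each member cohort; it is
    combination-significant when the log-rank p < ``alpha`` in every one.

    Returns a long-format frame with one row per (gene, combination,
    cohort) carrying HR, log-rank p, and the combination verdict.
    """
    from itertools import combinations as _combos

    rows = []
    for r in range(2, len(shared.cohorts) + 1):
        for subset in _combos(shared.cohorts, r):
            genes = sorted(shared.genes_in_exactly(subset))
            for gene in genes:
                per_cohort = []
                for cohort in subset:
                    expr = expression.get(cohort)
                    clin = clinical.get(cohort)
                    if expr is None or clin is None or gene not in expr.index:
                        per_cohort = []
                        break
                    samples = [s for s in expr.columns if s in clin.index]
                    x = expr.loc[gene, samples]
                    try:
                        groups = dichotomize(x, cutpoint=cutpoint)
                    except ValueError:
                        per_cohort = []
                        break
                    keep = groups.notna()
                    g = groups[keep]
                    t = clin.loc[g.index, "time"].to_numpy()
                    e = clin.loc[g.index, "event"].to_numpy()
                    lo, hi = g == "low", g == "high"
                    chi2, p = logrank_test(t[lo.to_numpy()], e[lo.to_numpy()],
                                           t[hi.to_numpy()], e[hi.to_numpy()])
                    hr, _, diverged = cox_hr(g.to_numpy(), t, e)
                    direction = "none"
                    if p < alpha:
                        direction = "high-risk" if hr > 1 else "low-risk"
                    per_cohort.append(GeneSurvivalResult(
                        gene, cohort, hr, p, p < alpha, direction, diverged))
                if not per_cohort:
                    continue
                combo_sig = all(res.significant for res in per_cohort)
                for res in per_cohort:
                    rows.append({
                        "gene_id": res.gene_id,
                        "combination": "&".join(subset),
                        "cohort_id": res.cohort_id,
                        "hazard_ratio": res.hazard_ratio,
                        "logrank_p": res.logrank_p,
                        "significant": res.significant,
                        "direction": res.direction,
                        "diverged": res.diverged,
                        "combination_significant": combo_sig,
                    })
    return pd.DataFrame(rows)


def geneset_enrichment(gene_list, gmt: GeneSetCollection, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list per GMT set.

    The universe must contain the gene list; genes of a set outside the
    universe are ignored.  Returns a frame with per-set overlap, p, and
    BH-adjusted fdr, sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    n = len(genes)
    N = len(universe)
    rows = []
    for name in sorted(gmt.sets):
        members = gmt.sets[name] & universe
        K = len(members)
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return df
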