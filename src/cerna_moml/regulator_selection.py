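"""Per-gene LASSO regulator models with stability selection and bootstrap
confirmation.

For every differentially expressed mRNA the model regresses tumour-sample
expression on the gene's own copy-number value, its DNA-methylation beta
value, the expression of its candidate miRNA regulators (from the
interaction tables) and of its candidate transcription factors:

    mRNA ~ CNA + DM + miRNA expression + TF expression

lncRNA targets use miRNA expression columns only.  Each model is an
L1-penalized least-squares fit; the penalty is chosen by 10-fold
cross-validation on a fixed log-spaced grid (ties in CV error broken
toward the larger penalty, i.e. the sparser model).  The fit is repeated
``runs`` times with re-randomized fold assignments, and predictors with a
non-zero coefficient in strictly more than ``threshold`` runs are
retained.  Retained predictors are then confirmed by a case-resampling
bootstrap of the restricted fit at the full-data penalty: a predictor is
significant when its percentile confidence interval excludes zero.  The
significant miRNA predictors of each target feed ceRNA pair calling.

The penalty is parametrized as in coordinate-descent solvers,
(1/2n)||y - Xb||^2 + lambda * ||b||_1, so the all-zero solution appears
exactly at lambda_max = max|X'y|/n.  Columns are standardized (mean 0,
SD 1) and the response centred before fitting, which absorbs the
intercept without penalizing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .formats_io import RegulatorBundle

KIND_CNA = "CNA"
KIND_DM = "DM"
KIND_MIRNA = "miRNA"
KIND_TF = "TF"


@dataclass
class DesignSpec:
    """Design matrix of one per-gene model, standardized and ready to fit."""

    target_id: str
    target_class: str  # "mRNA" | "lncRNA"
    y: np.ndarray  # centred response over tumour samples
    X: np.ndarray  # standardized predictors, n x p
    column_ids: list  # predictor identifiers (regulator ids; "CNA"/"DM" for self terms)
    column_kinds: list  # parallel list of KIND_* labels
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target_class == "lncRNA" and any(
            k != KIND_MIRNA for k in self.column_kinds
        ):
            raise ValueError("lncRNA designs may contain only miRNA columns")
        if len(self.column_ids) != self.X.shape[1]:
            raise ValueError("column_ids length does not match X")


@dataclass
class RegulatorModel:
    """Stability-selection result for one target RNA."""

    target_id: str
    target_class: str
    runs: int
    threshold: int
    column_ids: list
    column_kinds: list
    selection_count: dict  # predictor id -> times non-zero across runs
    lambda_per_run: list
    lambda_star: float  # full-data CV-optimal penalty
    coefficients: dict  # predictor id -> full-data coefficient at lambda_star
    selected: list  # predictors with selection_count > threshold
    bootstrap_ci: dict = field(default_factory=dict)  # id -> (lo, hi)
    significant: list = field(default_factory=list)
    mirna_set: set = field(default_factory=set)

    def __post_init__(self) -> None:
        cols = set(self.column_ids)
        assert set(self.selected) <= cols
        assert set(self.significant) <= set(self.selected)
        assert self.mirna_set <= set(self.significant)


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-standardize to mean 0, SD 1 (constant columns become 0)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def lambda_max(y: np.ndarray, X: np.ndarray) -> float:
    """Smallest penalty at which the LASSO solution is exactly zero."""
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def default_lambda_grid(y: np.ndarray, X: np.ndarray, n_lambda: int = 100,
                        min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(y, X)
    if lmax <= 0:
        lmax = 1e-12
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


@njit(cache=True)
def _cd_path(G: np.ndarray, Xty: np.ndarray, n_samples: float,
             alphas: np.ndarray, tol: float = 1e-8,
             max_iter: int = 1000) -> np.ndarray:  # pragma: no cover - jit
    """Pathwise coordinate descent on the Gram system.

    Minimizes (1/2n)||y - Xb||^2 + alpha*||b||_1 for each alpha in the
    (descending) grid with warm starts; covariance updates make the cost
    per sweep O(p^2), independent of n.  Returns coefs (n_alphas, p).
    """
    p = G.shape[0]
    coefs = np.zeros((alphas.shape[0], p))
    b = np.zeros(p)
    Gb = np.zeros(p)  # running G @ b
    for ia in range(alphas.shape[0]):
        lam_n = alphas[ia] * n_samples
        for _ in range(max_iter):
            max_delta = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                cj = Xty[j] - Gb[j] + gjj * b[j]
                if cj > lam_n:
                    bj = (cj - lam_n) / gjj
                elif cj < -lam_n:
                    bj = (cj + lam_n) / gjj
                else:
                    bj = 0.0
                d = bj - b[j]
                if d != 0.0:
                    for k in range(p):
                        Gb[k] += G[k, j] * d
                    b[j] = bj
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
            if max_delta < tol:
                break
        coefs[ia] = b
    return coefs


def lasso_fit(y: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    """Solve (1/2n)||y - Xb||^2 + lam*||b||_1; lam = 0 is plain least squares."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if lam == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    coefs = _cd_path(X.T @ X, X.T @ y, float(len(y)),
                     np.array([float(lam)]))
    return coefs[0]


def _cv_folds(n: int, folds: int, rng: np.random.Generator) -> list:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def _cv_fold_errors(y: np.ndarray, X: np.ndarray, G: np.ndarray,
                    Xty: np.ndarray, grid: np.ndarray, folds: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-fold mean held-out squared error, shape (folds, n_grid)."""
    n = len(y)
    out = np.empty((folds, len(grid)))
    for i, test in enumerate(_cv_folds(n, folds, rng)):
        Xt, yt = X[test], y[test]
        G_tr = G - Xt.T @ Xt
        Xty_tr = Xty - Xt.T @ yt
        coefs = _cd_path(G_tr, Xty_tr, float(n - len(test)), grid)
        pred = Xt @ coefs.T  # (n_test, n_grid)
        out[i] = ((yt[:, None] - pred) ** 2).mean(axis=0)
    return out


def _select_lambda_index(fold_errors: np.ndarray, rule: str) -> int:
    """Grid index of the CV-chosen penalty (grid is descending).

    ``rule="min"`` takes the penalty minimizing the mean CV error (exact
    ties to the larger penalty).  ``rule="1se"`` takes the largest penalty
    whose mean CV error is within one standard error of the minimum — the
    sparser choice that guards against the flat-CV-curve overselection of
    the plain minimum.
    """
    cvm = fold_errors.mean(axis=0)
    imin = int(np.argmin(cvm))
    if rule == "min":
        return imin
    if rule == "1se":
        k = fold_errors.shape[0]
        cvse = fold_errors.std(axis=0, ddof=1) / np.sqrt(k)
        return int(np.argmax(cvm <= cvm[imin] + cvse[imin]))
    raise ValueError(f"unknown lambda rule {rule!r}")


def fit_lasso_cv(y: np.ndarray, X: np.ndarray, folds: int = 10,
                 lambda_grid: np.ndarray | None = None,
                 rng: np.random.Generator | None = None,
                 lambda_rule: str = "min") -> tuple[np.ndarray, float]:
    """Cross-validated LASSO: returns (beta at lambda_star, lambda_star).

    By default lambda_star minimizes the mean held-out squared error over
    the grid (exact ties go to the larger penalty);
    ``lambda_rule="1se"`` applies the one-standard-error rule instead.
    Deterministic given the rng state (the only randomness is the fold
    assignment).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} smaller than folds={folds}")
    if np.std(y) == 0:
        warnings.warn("constant response: all coefficients zero")
        grid = lambda_grid if lambda_grid is not None else np.array([1.0])
        return np.zeros(X.shape[1]), float(grid[0])
    if rng is None:
        rng = np.random.default_rng()
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(y, X)
    grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        grid = np.sort(grid)[::-1]

    G, Xty = X.T @ X, X.T @ y
    fold_errors = _cv_fold_errors(y, X, G, Xty, grid, folds, rng)
    istar = _select_lambda_index(fold_errors, lambda_rule)
    lam_star = float(grid[istar])
    beta = _cd_path(G, Xty, float(n), grid)[istar]
    return beta, lam_star


def stability_select(y: np.ndarray, X: np.ndarray, column_ids: list,
                     column_kinds: list, target_id: str = "",
                     target_class: str = "mRNA", runs: int = 100,
                     threshold: int = 75, folds: int = 10,
                     lambda_rule: str = "1se",
                     rng: np.random.Generator | None = None) -> RegulatorModel:
    """Repeat CV-LASSO ``runs`` times with reshuffled folds; retain
    predictors non-zero in strictly more than ``threshold`` runs.

    The per-run penalty uses the one-standard-error rule by default: with
    the data fixed across runs, the CV-minimum penalty is nearly constant
    and sits deep in the flat part of the CV curve, where weakly
    correlated decoys carry non-zero (tiny) coefficients in essentially
    every run, defeating the selection-frequency filter.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    counts = np.zeros(X.shape[1], dtype=int)
    lambdas = []
    if np.std(y) == 0:
        warnings.warn("constant response: all coefficients zero")
        beta_full, lam_full = np.zeros(X.shape[1]), 1.0
        lambdas = [lam_full] * runs
    else:
        grid = default_lambda_grid(y, X)
        G, Xty = X.T @ X, X.T @ y
        # full-data path is shared by all runs: only the CV choice of
        # lambda varies with the fold reshuffle
        full_path = _cd_path(G, Xty, float(n), grid)
        for _ in range(runs):
            fold_errors = _cv_fold_errors(y, X, G, Xty, grid, folds, rng)
            istar = _select_lambda_index(fold_errors, lambda_rule)
            counts += full_path[istar] != 0
            lambdas.append(float(grid[istar]))
        fold_errors = _cv_fold_errors(y, X, G, Xty, grid, folds, rng)
        istar = _select_lambda_index(fold_errors, lambda_rule)
        beta_full, lam_full = full_path[istar], float(grid[istar])
    selected = [c for c, k in zip(column_ids, counts) if k > threshold]
    return RegulatorModel(
        target_id=target_id,
        target_class=target_class,
        runs=runs,
        threshold=threshold,
        column_ids=list(column_ids),
        column_kinds=list(column_kinds),
        selection_count={c: int(k) for c, k in zip(column_ids, counts)},
        lambda_per_run=lambdas,
        lambda_star=lam_full,
        coefficients={c: float(b) for c, b in zip(column_ids, beta_full)},
        selected=selected,
    )


def bootstrap_confirm(y: np.ndarray, X: np.ndarray, column_ids: list,
                      selected: list, lambda_star: float, B: int = 1000,
                      level: float = 0.95,
                      rng: np.random.Generator | None = None) -> dict:
    """Case-resampling bootstrap CIs for the selected predictors.

    The LASSO is refit at the full-data ``lambda_star`` on the columns in
    ``selected`` only; percentile intervals at ``level``; a predictor is
    significant when its interval excludes zero.

    Returns {"ci": {id: (lo, hi)}, "significant": [ids],
    "estimates": {id: full-data restricted coefficient}}.
    """
    if not selected:
        return {"ci": {}, "significant": [], "estimates": {}}
    if B < 100:
        warnings.warn(f"B={B} bootstrap resamples give unstable CIs")
    if rng is None:
        rng = np.random.default_rng()
    idx = [column_ids.index(c) for c in selected]
    Xs = np.asarray(X, dtype=float)[:, idx]
    y = np.asarray(y, dtype=float)
    n = len(y)
    boot = np.empty((B, len(idx)))
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        boot[b] = lasso_fit(y[rows], Xs[rows], lambda_star)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)
    est = lasso_fit(y, Xs, lambda_star)
    ci = {c: (float(l), float(h)) for c, l, h in zip(selected, lo, hi)}
    significant = [c for c, l, h in zip(selected, lo, hi) if l > 0 or h < 0]
    return {"ci": ci, "significant": significant,
            "estimates": {c: float(e) for c, e in zip(selected, est)}}


def build_design(target_id: str, target_class: str, expression: pd.DataFrame,
                 bundle: RegulatorBundle,
                 allowed_mirnas: set | None = None,
                 allowed_tfs: set | None = None) -> DesignSpec | None:
    """Assemble the standardized design for one target from the bundle.

    mRNA targets get CNA_self, DM_self, candidate miRNA and TF expression
    columns; lncRNA targets get candidate miRNA expression only.  Samples
    with an NA in any design column (or the response) are dropped for this
    model only.  Returns None when the target has no candidate miRNA
    regulators with available expression (such targets cannot join ceRNA
    pairs and have no model to fit).
    """
    if target_id not in expression.index:
        return None
    cols: list[np.ndarray] = []
    ids: list[str] = []
    kinds: list[str] = []
    samples = list(expression.columns)

    mirnas = sorted(bundle.mirna_candidates(target_id, target_class))
    if allowed_mirnas is not None:
        mirnas = [m for m in mirnas if m in allowed_mirnas]
    mirnas = [m for m in mirnas if m in expression.index]
    if not mirnas:
        return None

    if target_class == "mRNA":
        for kind, mat in ((KIND_CNA, bundle.cna.values), (KIND_DM, bundle.dm.values)):
            if target_id in mat.index:
                cols.append(mat.loc[target_id].reindex(samples).to_numpy(dtype=float))
                ids.append(kind)
                kinds.append(kind)
        tfs = sorted(bundle.tf_candidates(target_id))
        if allowed_tfs is not None:
            tfs = [t for t in tfs if t in allowed_tfs]
        tfs = [t for t in tfs if t in expression.index and t != target_id]
    else:
        tfs = []

    for m in mirnas:
        cols.append(expression.loc[m, samples].to_numpy(dtype=float))
        ids.append(m)
        kinds.append(KIND_MIRNA)
    for t in tfs:
        cols.append(expression.loc[t, samples].to_numpy(dtype=float))
        ids.append(t)
        kinds.append(KIND_TF)

    y = expression.loc[target_id, samples].to_numpy(dtype=float)
    X = np.column_stack(cols)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    kept_samples = [s for s, k in zip(samples, ok) if k]
    return DesignSpec(
        target_id=target_id,
        target_class=target_class,
        y=y - y.mean(),
        X=standardize(X),
        column_ids=ids,
        column_kinds=kinds,
        sample_ids=kept_samples,
    )


def fit_regulator_model(design: DesignSpec, runs: int = 100, threshold: int = 75,
                        folds: int = 10, B: int = 1000, level: float = 0.95,
                        require_negative_mirna: bool = True,
                        lambda_rule: str = "1se",
                        rng: np.random.Generator | None = None) -> RegulatorModel:
    """Stability selection plus bootstrap confirmation for one design.

    With ``require_negative_mirna`` (default), miRNA predictors whose
    confirmed coefficient is positive are excluded from the target's
    miRNA set — the sponge mechanism assumes repression.
    """
    if rng is None:
        rng = np.random.default_rng()
    model = stability_select(
        design.y, design.X, design.column_ids, design.column_kinds,
        target_id=design.target_id, target_class=design.target_class,
        runs=runs, threshold=threshold, folds=folds,
        lambda_rule=lambda_rule, rng=rng,
    )
    boot = bootstrap_confirm(design.y, design.X, design.column_ids,
                             model.selected, model.lambda_star, B=B,
                             level=level, rng=rng)
    model.bootstrap_ci = boot["ci"]
    model.significant = boot["significant"]
    kind_of = dict(zip(design.column_ids, design.column_kinds))
    mirnas = set()
    for c in model.significant:
        if kind_of[c] != KIND_MIRNA:
            continue
        if require_negative_mirna and boot["estimates"].get(c, 0.0) > 0:
            continue
        mirnas.add(c)
    model.mirna_set = mirnas
    return model


def build_mirna_maps(models: list[RegulatorModel]) -> dict:
    """target_id -> significant miRNA regulator set (empty sets dropped)."""
    return {m.target_id: set(m.mirna_set) for m in models if m.mirna_set}


def models_to_frame(models: list[RegulatorModel]) -> pd.DataFrame:
    """Long-format table of per-predictor results for serialization."""
    rows = []
    for m in models:
        for c, kind in zip(m.column_ids, m.column_kinds):
            lo, hi = m.bootstrap_ci.get(c, (np.nan, np.nan))
            rows.append({
                "target_id": m.target_id,
                "target_class": m.target_class,
                "predictor": c,
                "kind": kind,
                "selection_count": m.selection_count[c],
                "coefficient": m.coefficients[c],
                "selected": c in m.selected,
                "ci_lo": lo,
                "ci_hi": hi,
                "significant": c in m.significant,
                "in_mirna_set": c in m.mirna_set,
            })
    return pd.DataFrame(rows)


def mirna_maps_from_frame(df: pd.DataFrame) -> dict:
    out: dict = {}
    for _, row in df[df["in_mirna_set"]].iterrows():
        out.setdefault(row["target_id"], set()).add(row["predictor"])
    return out
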