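"""ceRNA pair calling: shared-miRNA candidates filtered by Pearson
correlation, a hypergeometric shared-miRNA test, and multiple sensitivity
correlation (mscor) with permutation significance.

A candidate pair is two target RNAs (mRNA-mRNA or lncRNA-mRNA) whose
significant miRNA regulator sets overlap.  The sponge mechanism predicts
(i) strong positive expression correlation between the partners,
(ii) more shared miRNA regulators than chance given each partner's
regulator set size, and (iii) a drop in their correlation once the shared
miRNA pool is conditioned away.  The drop is the sensitivity correlation

    scor  = cor(x, y) - pcor(x, y | one shared miRNA)
    mscor = cor(x, y) - pcor(x, y | all shared miRNAs)

Significance of mscor is assessed by jointly permuting the sample order
of the shared-miRNA matrix (breaking the miRNA-target coupling while
preserving the pair's own correlation), one-sided for positive mscor, and
Benjamini-Hochberg adjusted across all pairs tested.  Default thresholds:
Pearson r > 0.40, hypergeometric p < 0.05, adjusted mscor p < 0.05, all
strict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .formats_io import make_pair_key, split_pair_key

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    pearson_min: float = 0.40
    hypergeom_p_max: float = 0.05
    mscor_padj_max: float = 0.05


@dataclass
class CeRNACandidate:
    pair: str  # canonical pair key
    rna_a: str
    rna_b: str
    pair_class: str  # "mRNA-mRNA" | "lncRNA-mRNA"
    shared_mirnas: frozenset
    pearson_r: float = np.nan
    hypergeom_p: float = np.nan
    scor: float = np.nan
    mscor: float = np.nan
    mscor_p: float = np.nan
    mscor_p_adj: float = np.nan
    passed: bool = False


@dataclass
class CeRNANetwork:
    """Scored candidate pairs of one cohort plus the miRNA universe used."""

    cohort_id: str
    candidates: list = field(default_factory=list)
    mirna_population: set = field(default_factory=set)

    @property
    def passed(self) -> list:
        return [c for c in self.candidates if c.passed]

    def passed_keys(self) -> set:
        return {c.pair for c in self.passed}

    def summary(self) -> tuple[int, int]:
        """(pair count, unique RNA count) over passed pairs."""
        return len(self.passed), unique_rna_count(self.passed_keys())

    def to_frame(self, passed_only: bool = True) -> pd.DataFrame:
        rows = self.passed if passed_only else self.candidates
        return pd.DataFrame({
            "pair_key": [c.pair for c in rows],
            "rna_a": [c.rna_a for c in rows],
            "rna_b": [c.rna_b for c in rows],
            "shared_mirna_count": [len(c.shared_mirnas) for c in rows],
            "pearson_r": [c.pearson_r for c in rows],
            "hypergeom_p": [c.hypergeom_p for c in rows],
            "mscor": [c.mscor for c in rows],
            "mscor_p_adj": [c.mscor_p_adj for c in rows],
        })


def unique_rna_count(pair_keys) -> int:
    genes: set = set()
    for k in pair_keys:
        a, b = split_pair_key(k)
        genes.update((a, b))
    return len(genes)


def candidate_pairs(mirna_maps: dict, feature_classes: pd.Series | dict) -> list:
    """All unordered target pairs sharing at least one miRNA regulator.

    lncRNA-lncRNA combinations are not ceRNA pair classes here and are
    skipped; the pair class is mRNA-mRNA or lncRNA-mRNA.
    """
    if isinstance(feature_classes, pd.Series):
        feature_classes = feature_classes.to_dict()
    out = []
    for a, b in combinations(sorted(mirna_maps), 2):
        shared = mirna_maps[a] & mirna_maps[b]
        if not shared:
            continue
        ca = feature_classes.get(a, "mRNA")
        cb = feature_classes.get(b, "mRNA")
        if ca == cb == "lncRNA":
            continue
        pair_class = "mRNA-mRNA" if ca == cb == "mRNA" else "lncRNA-mRNA"
        key = make_pair_key(a, b)
        ka, kb = split_pair_key(key)
        out.append(CeRNACandidate(pair=key, rna_a=ka, rna_b=kb,
                                  pair_class=pair_class,
                                  shared_mirnas=frozenset(shared)))
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: Pearson correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def hypergeom_shared_p(k_shared: int, size_a: int, size_b: int,
                       population_n: int) -> float:
    """Upper-tail P(X >= k) for the shared-miRNA count.

    X ~ Hypergeometric(population_n, size_a, size_b): draw one partner's
    regulator set (size_b) from the miRNA universe and count how many fall
    in the other partner's set (size_a).
    """
    if not (0 <= k_shared <= min(size_a, size_b) <= population_n):
        raise ValueError(
            f"invalid hypergeometric arguments: k={k_shared}, "
            f"sizes=({size_a},{size_b}), N={population_n}"
        )
    return float(stats.hypergeom.sf(k_shared - 1, population_n, size_a, size_b))


def _drop_collinear(Z: np.ndarray) -> np.ndarray:
    """Remove columns that are linearly dependent on earlier ones."""
    if Z.shape[1] == 0:
        return Z
    keep: list[int] = []
    for j in range(Z.shape[1]):
        cand = Z[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    if len(keep) < Z.shape[1]:
        warnings.warn("rank-deficient conditioning set: collinear columns dropped")
    return Z[:, keep]


def partial_corr(x: np.ndarray, y: np.ndarray, Z: np.ndarray | None,
                 method: str = "residual") -> float:
    """Partial correlation of x and y given the columns of Z.

    ``method="residual"`` correlates the least-squares residuals of x and
    y on [1, Z]; ``method="precision"`` inverts the joint correlation
    matrix.  The two agree to numerical precision on full-rank input.
    With an empty Z this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z is None or np.size(Z) == 0:
        return pearson_r(x, y)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    Z = _drop_collinear(Z)
    n, k = Z.shape
    if n <= k + 2:
        raise ValueError(f"need n > |Z| + 2 (n={n}, |Z|={k})")
    if method == "residual":
        D = np.column_stack([np.ones(n), Z])
        rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
        ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        return pearson_r(rx, ry)
    if method == "precision":
        R = np.corrcoef(np.column_stack([x, y, Z]), rowvar=False)
        P = np.linalg.pinv(R)
        return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    raise ValueError(f"unknown method {method!r}")


def mscor(x: np.ndarray, y: np.ndarray, M: np.ndarray | None,
          method: str = "residual") -> float:
    """Multiple sensitivity correlation: cor(x,y) minus pcor(x,y | M).

    M holds the expression of ALL miRNAs shared by the pair (samples in
    rows).  With a single column this is the plain sensitivity
    correlation (scor); with no columns it is exactly 0.
    """
    if M is None or np.size(M) == 0:
        return 0.0
    return pearson_r(x, y) - partial_corr(x, y, M, method=method)


def scor_mean(x: np.ndarray, y: np.ndarray, M: np.ndarray) -> float:
    """Mean single-miRNA sensitivity correlation over the columns of M."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    vals = [mscor(x, y, M[:, [j]]) for j in range(M.shape[1])]
    return float(np.mean(vals))


def mscor_significance(x: np.ndarray, y: np.ndarray, M: np.ndarray,
                       n_perm: int = 1000,
                       rng: np.random.Generator | None = None) -> tuple[float, float]:
    """One-sided permutation p-value for mscor.

    The sample order of M's rows is permuted jointly ``n_perm`` times
    (x and y stay fixed, so their correlation is preserved while the
    miRNA-target coupling is destroyed); p = (1 + #{perm >= observed}) /
    (1 + n_perm).  Returns (observed mscor, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    observed = mscor(x, y, M, method="precision")

    # Schur-complement form of pcor(x, y | M): the M-block correlation is
    # invariant under the joint row permutation, so only the x-M and y-M
    # cross-correlations need recomputing per permutation.
    n = len(x)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    ZM = (M - M.mean(axis=0)) / M.std(axis=0)
    S = ZM.T @ ZM / n
    S_inv = np.linalg.pinv(S)
    r_xy = float(zx @ zy / n)

    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    RxM = zx[perms] @ ZM / n  # (n_perm, m)
    RyM = zy[perms] @ ZM / n
    q_xy = np.einsum("ij,jk,ik->i", RxM, S_inv, RyM)
    q_xx = np.einsum("ij,jk,ik->i", RxM, S_inv, RxM)
    q_yy = np.einsum("ij,jk,ik->i", RyM, S_inv, RyM)
    denom = np.sqrt(np.clip((1.0 - q_xx) * (1.0 - q_yy), 1e-300, None))
    pcor_perm = (r_xy - q_xy) / denom
    mscor_perm = r_xy - pcor_perm
    count = int(np.sum(mscor_perm >= observed))
    return float(observed), (1.0 + count) / (1.0 + n_perm)


def infer_network(expression: pd.DataFrame, mirna_maps: dict,
                  feature_classes: pd.Series | dict,
                  thresholds: Thresholds | None = None,
                  n_perm: int = 1000,
                  mirna_population: set | None = None,
                  cohort_id: str = "cohort",
                  rng: np.random.Generator | None = None) -> CeRNANetwork:
    """Score all candidate pairs and apply the three conjunctive filters.

    Filters run cheapest first (Pearson, then hypergeometric, then the
    permutation mscor test); the passed set is unaffected by the order
    since all three must hold.  The mscor p-values are BH-adjusted across
    the pairs that reached the mscor stage.  The hypergeometric population
    defaults to the distinct miRNAs appearing in any target's significant
    regulator set.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if rng is None:
        rng = np.random.default_rng()
    if mirna_population is None:
        mirna_population = set().union(*mirna_maps.values()) if mirna_maps else set()
    pop_n = len(mirna_population)

    candidates = candidate_pairs(mirna_maps, feature_classes)
    net = CeRNANetwork(cohort_id=cohort_id, candidates=candidates,
                       mirna_population=set(mirna_population))

    tested: list[CeRNACandidate] = []
    for c in candidates:
        try:
            x = expression.loc[c.rna_a].to_numpy(dtype=float)
            y = expression.loc[c.rna_b].to_numpy(dtype=float)
        except KeyError:
            logger.warning("pair %s dropped: expression missing", c.pair)
            continue
        try:
            c.pearson_r = pearson_r(x, y)
        except ValueError:
            logger.warning("pair %s dropped: constant expression", c.pair)
            continue
        if not c.pearson_r > thresholds.pearson_min:
            continue
        c.hypergeom_p = hypergeom_shared_p(
            len(c.shared_mirnas), len(mirna_maps[c.rna_a]),
            len(mirna_maps[c.rna_b]), pop_n)
        if not c.hypergeom_p < thresholds.hypergeom_p_max:
            continue
        mirs = sorted(c.shared_mirnas & set(expression.index))
        if not mirs:
            logger.warning("pair %s dropped: shared miRNA expression missing", c.pair)
            continue
        M = expression.loc[mirs].to_numpy(dtype=float).T
        c.scor = scor_mean(x, y, M)
        c.mscor, c.mscor_p = mscor_significance(x, y, M, n_perm=n_perm, rng=rng)
        tested.append(c)

    if tested:
        padj = bh_adjust(np.array([c.mscor_p for c in tested]))
        for c, pa in zip(tested, padj):
            c.mscor_p_adj = float(pa)
            c.passed = bool(pa < thresholds.mscor_padj_max)
    return net
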