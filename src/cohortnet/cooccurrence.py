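"""Compositional co-occurrence estimation with bootstrap edge significance.

Two estimators of between-ASV association from count tables are provided as
sklearn-style estimator classes, with thin functional wrappers:

* :class:`SparCC` -- the sparse compositional correlation algorithm: Dirichlet
  resampling of fractions, log-ratio variation matrix
  ``t_ij = Var(ln(x_i/x_j))``, a linear solve for basis variances under a
  sparsity assumption, and iterative exclusion of the most strongly correlated
  pairs; the final correlation is the median over repeated estimation
  iterations.
* :class:`PearsonCLR` -- plain Pearson correlation between centred-log-ratio
  transformed ASV vectors, the fast cross-check estimator.

Edge significance uses a permutation bootstrap: each ASV's counts are permuted
across samples independently (destroying co-structure while preserving every
marginal), the correlation matrix is re-estimated, and the one-sided p-value
of each pair is the proportion of bootstrap correlations at least as large as
the observed one (positive tail; only positive co-occurrences are used for
network construction downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CountTable, clr_transform

__all__ = [
    "CorrelationEstimate",
    "SparCC",
    "PearsonCLR",
    "sparcc_correlations",
    "pearson_clr_correlations",
    "bootstrap_pvalues",
]


@dataclass
class CorrelationEstimate:
    """A symmetric ASV x ASV correlation matrix with optional p-values."""

    asv_ids: list
    r: np.ndarray                      # symmetric, unit diagonal, clamped to [-1, 1]
    p: np.ndarray | None = None        # symmetric one-sided p-values, or None
    method: str = "sparcc"
    n_boot: int = 0
    internals: dict = field(default_factory=dict)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.asv_ids, columns=self.asv_ids)

    def p_frame(self) -> pd.DataFrame | None:
        if self.p is None:
            return None
        return pd.DataFrame(self.p, index=self.asv_ids, columns=self.asv_ids)

    def write_tsv(self, r_path, p_path=None) -> None:
        self.r_frame().to_csv(r_path, sep="\t", index_label="asv_id")
        if p_path is not None and self.p is not None:
            self.p_frame().to_csv(p_path, sep="\t", index_label="asv_id")


# ---------------------------------------------------------------------------
# SparCC internals
# ---------------------------------------------------------------------------

def _dirichlet_fractions(counts: np.ndarray, rng) -> np.ndarray:
    """One Dirichlet posterior draw of relative abundances per sample."""
    gammas = rng.standard_gamma(counts + 1.0)
    return gammas / gammas.sum(axis=1, keepdims=True)


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var(ln(x_i / x_j)) computed via the log-fraction covariance."""
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(t: np.ndarray, n_exclusion_iter: int,
                        exclusion_threshold: float):
    """Solve for basis variances under sparsity; iteratively exclude pairs.

    Returns (rho, omega_sq, n_excluded_pairs, excluded_mask).
    """
    p = t.shape[0]
    # sparsity approximation: sum_j t_ij ~ (p - 2) * w_i + sum_j w_j
    m_diag = np.full(p, float(p - 1))
    m_off = np.ones((p, p))
    t_row = t.sum(axis=1)
    excluded = np.zeros((p, p), dtype=bool)

    def solve():
        m = m_off.copy()
        np.fill_diagonal(m, m_diag)
        w = np.linalg.solve(m, t_row)
        w = np.maximum(w, 1e-10)  # clamp non-physical negative basis variances
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho, w

    rho, w = solve()
    n_excl = 0
    for _ in range(n_exclusion_iter):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        masked[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # keep the linear system well-posed: never exclude an ASV's last pairs
        if m_diag[i] <= 2 or m_diag[j] <= 2:
            excluded[i, j] = excluded[j, i] = True
            continue
        excluded[i, j] = excluded[j, i] = True
        m_diag[i] -= 1.0
        m_diag[j] -= 1.0
        m_off[i, j] -= 1.0
        m_off[j, i] -= 1.0
        t_row[i] -= t[i, j]
        t_row[j] -= t[i, j]
        n_excl += 1
        rho, w = solve()
    return rho, w, n_excl, excluded


def _sparcc_matrix(counts: np.ndarray, n_iter: int, n_exclusion_iter: int,
                   exclusion_threshold: float, rng):
    """Median correlation over ``n_iter`` Dirichlet estimation iterations."""
    rs, ws, ts, excl_counts = [], [], [], []
    for _ in range(n_iter):
        fractions = _dirichlet_fractions(counts, rng)
        t = _variation_matrix(fractions)
        rho, w, _, excluded = _basis_correlations(
            t, n_exclusion_iter, exclusion_threshold)
        rs.append(rho)
        ws.append(w)
        ts.append(t)
        excl_counts.append(excluded.astype(int))
    r = np.median(rs, axis=0)
    np.fill_diagonal(r, 1.0)
    internals = {
        "basis_variance": np.median(ws, axis=0),
        "variation_matrix": np.median(ts, axis=0),
        "exclusion_count": np.sum(excl_counts, axis=0),
    }
    return r, internals


def _as_counts(X):
    if isinstance(X, CountTable):
        return X.counts, X.asv_ids
    if isinstance(X, pd.DataFrame):
        return CountTable(X).counts, list(X.columns)
    arr = np.asarray(X)
    return arr, [f"A{j + 1}" for j in range(arr.shape[1])]


class SparCC(BaseEstimator):
    """Sparse compositional correlation estimator.

    Parameters
    ----------
    n_iter : int
        Estimation iterations (Dirichlet resamples); the final correlation is
        their elementwise median.
    n_exclusion_iter : int
        Maximum strongly-correlated pairs excluded from the basis-variance
        system per iteration.
    exclusion_threshold : float
        Absolute correlation above which a pair is eligible for exclusion.
    random_state : int or None
        Seed for the Dirichlet resampling.

    Attributes
    ----------
    correlation_ : ndarray of shape (n_asvs, n_asvs)
    basis_variance_ : ndarray of shape (n_asvs,)
    estimate_ : CorrelationEstimate
    """

    def __init__(self, n_iter: int = 20, n_exclusion_iter: int = 50,
                 exclusion_threshold: float = 0.1, random_state=None):
        self.n_iter = n_iter
        self.n_exclusion_iter = n_exclusion_iter
        self.exclusion_threshold = exclusion_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        counts, asv_ids = _as_counts(X)
        if counts.shape[1] < 4:
            raise ValueError(
                "SparCC needs >= 4 ASVs (basis-variance system is "
                f"under-determined below that), got {counts.shape[1]}")
        row_sums = counts.sum(axis=1)
        if np.any(row_sums == 0):
            raise ValueError("every sample must have at least one read")
        all_zero = (counts != 0).sum(axis=0) == 0
        if np.any(all_zero):
            bad = np.asarray(asv_ids, dtype=object)[all_zero][0]
            raise ValueError(f"degenerate all-zero ASV: {bad!r}")
        rng = np.random.default_rng(self.random_state)
        r, internals = _sparcc_matrix(
            counts, self.n_iter, self.n_exclusion_iter,
            self.exclusion_threshold, rng)
        self.correlation_ = r
        self.basis_variance_ = internals["basis_variance"]
        self.asv_ids_ = list(asv_ids)
        self.estimate_ = CorrelationEstimate(
            asv_ids=list(asv_ids), r=r, method="sparcc", internals=internals)
        return self

    def _refit_matrix(self, counts, rng):
        """Correlation matrix only, for bootstrap re-estimation."""
        r, _ = _sparcc_matrix(counts, self.n_iter, self.n_exclusion_iter,
                              self.exclusion_threshold, rng)
        return r


class PearsonCLR(BaseEstimator):
    """Pearson correlation between clr-transformed ASV abundance vectors.

    Zero-variance clr columns (possible only for degenerate inputs) yield an
    undefined correlation; those entries are recorded as 0 and the offending
    ASVs flagged in ``constant_asvs_``.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        counts, asv_ids = _as_counts(X)
        if counts.shape[0] < 3:
            raise ValueError("need >= 3 samples for clr-Pearson correlations")
        r, constant = self._corr(counts)
        self.correlation_ = r
        self.asv_ids_ = list(asv_ids)
        self.constant_asvs_ = [asv_ids[j] for j in np.flatnonzero(constant)]
        self.estimate_ = CorrelationEstimate(
            asv_ids=list(asv_ids), r=r, method="pearson_clr",
            internals={"constant_asvs": self.constant_asvs_})
        return self

    def _corr(self, counts):
        logx = np.log(counts + self.pseudocount)
        clr = logx - logx.mean(axis=1, keepdims=True)
        sd = clr.std(axis=0)
        constant = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(clr, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return r, constant

    def _refit_matrix(self, counts, rng):
        r, _ = self._corr(counts)
        return r


# ---------------------------------------------------------------------------
# Functional wrappers + bootstrap significance
# ---------------------------------------------------------------------------

def sparcc_correlations(table: CountTable, n_estimate_iter: int = 20,
                        n_exclusion_iter: int = 50,
                        exclusion_threshold: float = 0.1,
                        seed: int = 0) -> CorrelationEstimate:
    """SparCC correlation matrix for a count table (see :class:`SparCC`)."""
    est = SparCC(n_iter=n_estimate_iter, n_exclusion_iter=n_exclusion_iter,
                 exclusion_threshold=exclusion_threshold, random_state=seed)
    return est.fit(table).estimate_


def pearson_clr_correlations(table: CountTable,
                             pseudocount: float = 1.0) -> CorrelationEstimate:
    """clr-Pearson correlation matrix for a count table."""
    return PearsonCLR(pseudocount=pseudocount).fit(table).estimate_


def _estimator_for(estimate: CorrelationEstimate, **overrides):
    if estimate.method == "sparcc":
        return SparCC(**overrides)
    if estimate.method == "pearson_clr":
        return PearsonCLR(**{k: v for k, v in overrides.items()
                             if k in ("pseudocount",)})
    raise ValueError(f"unknown correlation method {estimate.method!r}")


def bootstrap_pvalues(table: CountTable, estimate: CorrelationEstimate,
                      n_boot: int = 500, seed: int = 0,
                      **estimator_params) -> np.ndarray:
    """One-sided bootstrap p-values for every pair; stored on the estimate.

    Each bootstrap permutes every ASV's counts across samples independently
    (correlation-free null with preserved marginals) and re-estimates the
    correlation matrix with the same method.  ``p_ij`` is the proportion of
    bootstrap correlations >= the observed ``r_ij`` (positive tail).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if list(estimate.asv_ids) != list(table.asv_ids):
        raise ValueError("estimate and table ASV ids differ")
    counts = table.counts
    rng = np.random.default_rng(seed)
    estimator = _estimator_for(estimate, **estimator_params)
    exceed = np.zeros_like(estimate.r)
    for _ in range(n_boot):
        permuted = rng.permuted(counts, axis=0)  # independent per-ASV shuffles
        r_b = estimator._refit_matrix(permuted, rng)
        exceed += r_b >= estimate.r
    p = exceed / n_boot
    p = (p + p.T) / 2.0  # symmetrize (exact for symmetric r_b, guards fp noise)
    np.fill_diagonal(p, 0.0)
    estimate.p = p
    estimate.n_boot = n_boot
    return p
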