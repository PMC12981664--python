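"""Cohort ecology: abundances, gradients, preferences, PERMANOVA and
sample-wise modularity.

Links inferred cohorts to environmental context: per-sample cohort abundances
(summed member reads), compositionality-safe log-ratios between cohorts and
their correlation with environmental gradients, abundance-weighted
environmental preference z-scores, a permutational multivariate ANOVA
(pseudo-F on a Gower-centred distance matrix, Anderson-style) for the
fraction of community variation explained by the environment, and per-sample
modularity of the co-occurrence network restricted to the ASVs present in
each sample -- the statistic whose decline at gradient extremes signals the
dominance of fewer cohorts under stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Partition, modularity
from .io import CountTable, SampleMetadata
from .network import CoNetwork

__all__ = [
    "PreferenceMatrix",
    "PermanovaResult",
    "GradientFit",
    "CubicFit",
    "cohort_abundance",
    "cohort_log_ratio",
    "gradient_correlation",
    "environmental_preference",
    "bray_curtis_distance_matrix",
    "permanova",
    "sample_modularity",
    "modularity_gradient_fit",
]


def cohort_abundance(table: CountTable, partition: Partition,
                     include_unassigned: bool = False) -> pd.DataFrame:
    """Samples x cohorts matrix of summed member-ASV counts.

    With ``include_unassigned`` an extra column holds all reads not mapped to
    any cohort, so rows sum exactly to the sample totals.
    """
    from .cohorts import _cohort_count_matrix

    cm = _cohort_count_matrix(table, partition)
    if include_unassigned:
        cm["unassigned"] = table.counts.sum(axis=1) - cm.sum(axis=1)
    return cm


def cohort_log_ratio(abundance: pd.DataFrame, cohort_a, cohort_b,
                     pseudocount: float = 1.0) -> pd.Series:
    """Per-sample ln((n_a + pc) / (n_b + pc)) between two cohorts.

    Log-ratios of cohort abundances are insensitive to sequencing depth, so
    they avoid the compositionality bias of raw abundances.  ``pseudocount``
    may be 0 when both cohorts have positive counts everywhere.
    """
    for c in (cohort_a, cohort_b):
        if c not in abundance.columns:
            raise KeyError(f"unknown cohort label {c!r}")
    a = abundance[cohort_a].to_numpy(dtype=float) + pseudocount
    b = abundance[cohort_b].to_numpy(dtype=float) + pseudocount
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("zero abundance with pseudocount 0; use pseudocount > 0")
    return pd.Series(np.log(a / b), index=abundance.index,
                     name=f"log_ratio_{cohort_a}_{cohort_b}")


@dataclass
class GradientFit:
    r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def gradient_correlation(log_ratios: pd.Series,
                         env_variable: pd.Series) -> GradientFit:
    """Least-squares line and Pearson correlation of a log-ratio series
    against an environmental variable (pairwise-complete observations)."""
    df = pd.concat([log_ratios, env_variable], axis=1, join="inner").dropna()
    if df.shape[0] < 3:
        raise ValueError("need >= 3 paired finite observations")
    y = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    res = stats.linregress(x, y)
    return GradientFit(r=float(res.rvalue), slope=float(res.slope),
                       intercept=float(res.intercept),
                       p_value=float(res.pvalue), n=len(x))


@dataclass
class PreferenceMatrix:
    """Cohort x environmental-variable preference z-scores."""

    z: pd.DataFrame               # z-scored across cohorts, per variable
    weighted_means: pd.DataFrame  # underlying abundance-weighted means


def environmental_preference(abundance: pd.DataFrame,
                             metadata: SampleMetadata,
                             variables=None) -> PreferenceMatrix:
    """Abundance-weighted environmental preference of each cohort.

    pref(c, v) = sum_s w_cs x_vs / sum_s w_cs with weights w the cohort
    counts.  Each variable column is z-scored across cohorts (population SD),
    so columns have mean 0 and SD 1 whenever >= 2 cohorts carry data.
    Cohorts with zero total abundance are NaN-coded.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need >= 2 cohorts for preference z-scores")
    env = metadata.numeric(variables).reindex(abundance.index)
    means = {}
    for cohort in abundance.columns:
        w = abundance[cohort].to_numpy(dtype=float)
        row = {}
        for var in env.columns:
            x = env[var].to_numpy(dtype=float)
            ok = np.isfinite(x)
            wsum = w[ok].sum()
            row[var] = np.nan if wsum == 0 else float((w[ok] * x[ok]).sum() / wsum)
        means[cohort] = row
    wm = pd.DataFrame(means).T
    z = (wm - wm.mean(axis=0)) / wm.std(axis=0, ddof=0)
    return PreferenceMatrix(z=z, weighted_means=wm)


def bray_curtis_distance_matrix(table: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (on proportions)."""
    from scipy.spatial.distance import pdist, squareform

    from .io import relative_abundance

    rel = relative_abundance(table).to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class PermanovaResult:
    """Distance-based multivariate ANOVA decomposition."""

    terms: pd.DataFrame  # index: term names + "residual"; cols: df, SS, R2, F, p
    n_permutations: int
    method: str = "sequential"

    @property
    def r2(self) -> pd.Series:
        return self.terms["R2"]

    def to_json(self) -> str:
        return self.terms.reset_index(names="term").to_json(orient="records")


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def permanova(distance: pd.DataFrame, predictors: pd.DataFrame,
              n_perm: int = 999, seed: int = 0,
              method: str = "sequential") -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the Gower-centred inner-product matrix of the (squared)
    distances along the hat matrices of the predictor design.  ``sequential``
    adds terms in column order (sums of squares and R-squared values, plus the
    residual, sum to the total); ``marginal`` tests each term after all
    others.  p-values are permutation proportions with the observed statistic
    included in numerator and denominator.  Numeric predictors are used as
    given (one df each); rank-deficient designs raise with the aliased
    columns listed.
    """
    if method not in ("sequential", "marginal"):
        raise ValueError("method must be 'sequential' or 'marginal'")
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    pred = predictors.reindex(distance.index)
    if pred.isna().any().any():
        keep = ~pred.isna().any(axis=1)
        pred = pred.loc[keep]
        idx = [distance.index.get_loc(i) for i in pred.index]
        d = d[np.ix_(idx, idx)]
    n = d.shape[0]
    x = pred.to_numpy(dtype=float)
    terms = list(pred.columns)
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        aliased = []
        base = np.ones((n, 1))
        for j, t in enumerate(terms):
            cand = np.column_stack([base, x[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                aliased.append(t)
            else:
                base = cand
        raise ValueError(f"rank-deficient predictors; aliased terms: {aliased}")

    g = _gower_center(d)
    ss_total = np.trace(g)
    df_res = n - len(terms) - 1

    def decompose(gmat):
        """Per-term SS and pseudo-F for one (possibly permuted) G."""
        ss, fs = {}, {}
        h_full = _hat(design)
        ss_res = np.trace(gmat) - np.trace(h_full @ gmat)
        if method == "sequential":
            prev = np.trace(_hat(np.ones((n, 1))) @ gmat)  # = 0 after centring
            cols = [np.ones(n)]
            for t, j in zip(terms, range(len(terms))):
                cols.append(x[:, j])
                cur = np.trace(_hat(np.column_stack(cols)) @ gmat)
                ss[t] = cur - prev
                prev = cur
        else:
            for t, j in zip(terms, range(len(terms))):
                others = [np.ones(n)] + [x[:, jj] for jj in range(len(terms))
                                         if jj != j]
                h_red = _hat(np.column_stack(others))
                ss[t] = np.trace(h_full @ gmat) - np.trace(h_red @ gmat)
        for t in terms:
            fs[t] = (ss[t] / 1.0) / (ss_res / df_res)
        return ss, fs, ss_res

    ss_obs, f_obs, ss_res = decompose(g)
    rng = np.random.default_rng(seed)
    exceed = {t: 1 for t in terms}  # observed included
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_perm, _ = decompose(gp)
        for t in terms:
            if f_perm[t] >= f_obs[t]:
                exceed[t] += 1

    rows = []
    for t in terms:
        rows.append({"term": t, "df": 1, "SS": ss_obs[t],
                     "R2": ss_obs[t] / ss_total, "F": f_obs[t],
                     "p": exceed[t] / (n_perm + 1)})
    rows.append({"term": "residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    frame = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(terms=frame, n_permutations=n_perm, method=method)


def sample_modularity(network: CoNetwork, partition: Partition,
                      table: CountTable) -> pd.Series:
    """Modularity of the per-sample subnetwork under the full-network cohorts.

    For each sample, the network is restricted to the ASVs present (count >
    0) in that sample and its modularity is computed with the cluster labels
    inherited from the full network.  Samples whose subnetwork has no edges
    are NaN-coded.
    """
    missing = [n for n in network.node_ids if n not in partition.labels]
    if missing:
        raise ValueError(f"partition missing network nodes: {missing[:5]}")
    node_set = [a for a in table.asv_ids if a in set(network.node_ids)]
    col_index = {a: j for j, a in enumerate(table.asv_ids)}
    counts = table.counts
    out = {}
    for i, sample in enumerate(table.sample_ids):
        present = [a for a in node_set if counts[i, col_index[a]] > 0]
        if len(present) < 2:
            out[sample] = np.nan
            continue
        sub = network.subgraph(present)
        if sub.is_empty:
            out[sample] = np.nan
            continue
        out[sample] = modularity(sub, partition.restricted_to(present))
    return pd.Series(out, name="sample_modularity")


@dataclass
class CubicFit:
    """Cubic polynomial fit of a response against a standardized variable."""

    coefficients: np.ndarray  # ascending powers 0..3 of (x - center) / scale
    center: float
    scale: float
    n: int

    def predict(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.center) / self.scale
        return np.polynomial.polynomial.polyval(z, self.coefficients)


def modularity_gradient_fit(sample_q: pd.Series,
                            env_variable: pd.Series) -> CubicFit:
    """OLS cubic polynomial of per-sample modularity against a gradient.

    The variable is centred and scaled before fitting for numerical
    conditioning; ``predict`` accepts values on the original scale.
    """
    df = pd.concat([sample_q, env_variable], axis=1, join="inner").dropna()
    if df.shape[0] < 5:
        raise ValueError("need >= 5 finite (modularity, variable) pairs")
    y = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    center, scale = float(np.mean(x)), float(np.std(x))
    scale = scale if scale > 0 else 1.0
    z = (x - center) / scale
    design = np.vander(z, 4, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return CubicFit(coefficients=coef, center=center, scale=scale, n=len(y))
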