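"""Synthetic amplicon communities with planted cohort structure.

The generator emulates the statistical structure of the real datasets this
pipeline is built for: groups of ASVs ("cohorts") whose abundances co-vary
because they share a Gaussian niche response along a one-dimensional
environmental gradient (think temperature), a pool of unstructured background
ASVs, per-ASV base abundances and per-sample noise on a lognormal scale,
compositional closure, and variable sequencing depth.  Because the planted
memberships and niche parameters are recorded exactly, every downstream stage
-- network inference, consensus clustering, null models, ecology -- can be
scored against a known truth.

Latent model for member i of cohort g in sample s at gradient value x_s:

    E[abundance] = a_g(x_s) * w_i * eps_is,   a_g(x) = exp(-(x - mu_g)^2 / (2 sigma_g^2))

with w_i ~ lognormal(0, member_weight_sigma) and eps_is ~ lognormal(0,
sample_noise_sigma).  Background ASVs have gradient-independent expectation
``background_scale * w_i * eps_is``.  Per sample, reads are drawn multinomially
from the closed expectations at a lognormally distributed depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountTable, SampleMetadata

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_community",
    "generate_null_community",
    "generate_paired_datasets",
    "BACKGROUND",
]

#: membership label for unstructured ASVs
BACKGROUND = "background"


@dataclass
class GeneratorConfig:
    """All knobs of the planted-cohort community generator.

    Defaults define the standard study condition used throughout the test
    suite: 6 cohorts x 40 members plus 60 background ASVs (20% of features)
    over 300 samples spanning a temperature-like gradient of 0-30 units, with
    evenly spaced niche optima and a width of 1.5 units (neighbouring optima
    more than 3 SD apart, i.e. cohorts with distinct optima).
    """

    n_samples: int = 300
    n_cohorts: int = 6
    members_per_cohort: int = 40
    n_background: int = 60
    gradient_range: tuple = (0.0, 30.0)
    niche_centers: list | None = None   # default: evenly spaced in range
    niche_widths: list | None = None    # default: 1.5 for every cohort
    member_weight_sigma: float = 1.0
    sample_noise_sigma: float = 0.6
    background_scale: float = 0.25
    depth_mean: float = 20000.0         # median of the lognormal depth
    depth_sigma: float = 0.3
    seed: int = 0
    gradient_name: str = "temperature"

    def resolved_niches(self) -> tuple:
        """Niche centers/widths with defaults filled in; validates lengths."""
        lo, hi = self.gradient_range
        if self.niche_centers is None:
            # cell midpoints of an even partition of the gradient range
            edges = np.linspace(lo, hi, self.n_cohorts + 1)
            centers = (edges[:-1] + edges[1:]) / 2.0
        else:
            centers = np.asarray(self.niche_centers, dtype=float)
        widths = (np.full(self.n_cohorts, 1.5)
                  if self.niche_widths is None
                  else np.asarray(self.niche_widths, dtype=float))
        if len(centers) != self.n_cohorts or len(widths) != self.n_cohorts:
            raise ValueError(
                "niche_centers and niche_widths must each have one entry per cohort"
            )
        if np.any(widths <= 0):
            raise ValueError("all niche widths must be > 0")
        return centers, widths

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("n_cohorts", "members_per_cohort", "n_background"):
            if getattr(self, name) < 0 or (name != "n_background" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        lo, hi = self.gradient_range
        if not hi > lo:
            raise ValueError("gradient_range must be a non-empty interval")
        for name in ("member_weight_sigma", "sample_noise_sigma", "depth_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_mean <= 0 or self.background_scale < 0:
            raise ValueError("depth_mean must be > 0 and background_scale >= 0")
        self.resolved_niches()


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated community."""

    membership: dict               # asv id -> cohort label (int from 1) or BACKGROUND
    gradient: pd.Series            # sample id -> gradient value
    cohort_activity: pd.DataFrame  # samples x cohorts latent activities a_g(x_s)
    depths: pd.Series              # sample id -> drawn sequencing depth
    niche_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    niche_widths: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def cohort_labels(self) -> list:
        return sorted({m for m in self.membership.values() if m != BACKGROUND})

    def membership_of(self, asv_ids) -> pd.Series:
        return pd.Series({a: self.membership[a] for a in asv_ids})

    def to_json(self, path=None) -> str:
        payload = {
            "membership": {k: (v if isinstance(v, str) else int(v))
                           for k, v in self.membership.items()},
            "gradient": self.gradient.to_dict(),
            "depths": {k: int(v) for k, v in self.depths.items()},
            "niche_centers": np.asarray(self.niche_centers).tolist(),
            "niche_widths": np.asarray(self.niche_widths).tolist(),
            "cohort_activity": {
                "index": list(self.cohort_activity.index),
                "columns": [int(c) for c in self.cohort_activity.columns],
                "values": self.cohort_activity.to_numpy().tolist(),
            },
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def _lognormal(rng, sigma, size):
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _draw_depths(rng, n, depth_mean, depth_sigma):
    depths = np.exp(rng.normal(np.log(depth_mean), depth_sigma, size=n))
    return np.maximum(np.rint(depths).astype(np.int64), 1)


def _sample_counts(rng, expected, depths):
    """Multinomial reads per sample from closed expected abundances."""
    probs = expected / expected.sum(axis=1, keepdims=True)
    counts = np.empty(expected.shape, dtype=np.int64)
    for s in range(expected.shape[0]):
        counts[s] = rng.multinomial(depths[s], probs[s])
    return counts


def _build_community(config, rng, member_ids, member_weights, background_ids,
                     background_weights):
    """Core generation given explicit ASV identities and base weights.

    ``member_ids``/``member_weights`` are (n_cohorts, members_per_cohort)
    nested lists / arrays.  Shared between :func:`generate_community` and
    :func:`generate_paired_datasets` so paired datasets can reuse identities
    and weights for overlapping cohorts.
    """
    config.validate()
    centers, widths = config.resolved_niches()
    lo, hi = config.gradient_range
    x = np.linspace(lo, hi, config.n_samples)
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]

    # latent cohort activities (n_samples x n_cohorts)
    activity = np.exp(-((x[:, None] - centers[None, :]) ** 2)
                      / (2.0 * widths[None, :] ** 2))

    asv_ids, expected_cols, membership = [], [], {}
    for g in range(config.n_cohorts):
        for j in range(config.members_per_cohort):
            asv = member_ids[g][j]
            asv_ids.append(asv)
            membership[asv] = g + 1
            expected_cols.append(activity[:, g] * member_weights[g][j])
    for j in range(config.n_background):
        asv = background_ids[j]
        asv_ids.append(asv)
        membership[asv] = BACKGROUND
        expected_cols.append(np.full(config.n_samples,
                                     config.background_scale * background_weights[j]))

    expected = np.column_stack(expected_cols)
    expected *= _lognormal(rng, config.sample_noise_sigma, expected.shape)
    depths = _draw_depths(rng, config.n_samples, config.depth_mean, config.depth_sigma)
    counts = _sample_counts(rng, expected, depths)

    table = CountTable.from_arrays(counts, sample_ids, asv_ids)
    metadata = SampleMetadata(
        pd.DataFrame({config.gradient_name: x}, index=sample_ids)
    )
    truth = SyntheticTruth(
        membership=membership,
        gradient=pd.Series(x, index=sample_ids, name=config.gradient_name),
        cohort_activity=pd.DataFrame(activity, index=sample_ids,
                                     columns=list(range(1, config.n_cohorts + 1))),
        depths=pd.Series(depths, index=sample_ids, name="depth"),
        niche_centers=centers,
        niche_widths=widths,
    )
    return table, metadata, truth


def generate_community(config: GeneratorConfig | None = None):
    """Generate one planted-cohort community.

    Returns ``(CountTable, SampleMetadata, SyntheticTruth)``.  Deterministic
    for a fixed ``config.seed``.
    """
    config = config if config is not None else GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    member_ids = [[f"C{g + 1}_A{j + 1:03d}" for j in range(config.members_per_cohort)]
                  for g in range(config.n_cohorts)]
    member_weights = _lognormal(
        rng, config.member_weight_sigma,
        (config.n_cohorts, config.members_per_cohort))
    background_ids = [f"BG_A{j + 1:03d}" for j in range(config.n_background)]
    background_weights = _lognormal(rng, config.member_weight_sigma,
                                    config.n_background)
    return _build_community(config, rng, member_ids, member_weights,
                            background_ids, background_weights)


def generate_null_community(n_samples: int, n_asvs: int, depth: float,
                            seed: int = 0) -> CountTable:
    """Community with no co-occurrence structure (type-I-error fixture).

    Every ASV has an independent lognormal base abundance and independent
    per-sample lognormal noise; reads are multinomial at a lognormal depth
    with median ``depth``.
    """
    if n_samples < 2 or n_asvs < 2 or depth <= 0:
        raise ValueError("n_samples, n_asvs must be >= 2 and depth > 0")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, size=n_asvs)
    expected = base[None, :] * rng.lognormal(0.0, 0.5, size=(n_samples, n_asvs))
    depths = _draw_depths(rng, n_samples, depth, 0.3)
    counts = _sample_counts(rng, expected, depths)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    asv_ids = [f"N_A{j + 1:04d}" for j in range(n_asvs)]
    return CountTable.from_arrays(counts, sample_ids, asv_ids)


def generate_paired_datasets(config: GeneratorConfig, overlap_fraction: float,
                             seed: int = 0):
    """Two communities sharing a fraction of their planted cohorts.

    Shared cohorts carry identical ASV identifiers *and* identical member base
    weights in both datasets (their realized counts still differ through
    per-dataset noise and sampling); non-shared cohorts and all background
    ASVs use disjoint identifiers.  Returns ``((table1, truth1), (table2,
    truth2))``.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    config.validate()
    n_shared = int(round(overlap_fraction * config.n_cohorts))
    rng_shared = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    shared_ids = [[f"SH{g + 1}_A{j + 1:03d}" for j in range(config.members_per_cohort)]
                  for g in range(n_shared)]
    shared_weights = _lognormal(
        rng_shared, config.member_weight_sigma,
        (n_shared, config.members_per_cohort))

    results = []
    for d in (1, 2):
        rng = np.random.default_rng(np.random.SeedSequence([seed, d]))
        member_ids = [list(ids) for ids in shared_ids]
        weights = list(np.asarray(shared_weights))
        for g in range(n_shared, config.n_cohorts):
            member_ids.append([f"D{d}C{g + 1}_A{j + 1:03d}"
                               for j in range(config.members_per_cohort)])
            weights.append(_lognormal(rng, config.member_weight_sigma,
                                      config.members_per_cohort))
        background_ids = [f"D{d}BG_A{j + 1:03d}" for j in range(config.n_background)]
        background_weights = _lognormal(rng, config.member_weight_sigma,
                                        config.n_background)
        table, _, truth = _build_community(config, rng, member_ids, weights,
                                           background_ids, background_weights)
        results.append((table, truth))
    return tuple(results)
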