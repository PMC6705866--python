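"""Synthetic MET data generator with known truth.

Emulates a randomized-complete-block trial of m genotypes in p environments
with q replicates, in which genotypes fall into three stability groups:
positive-unstable (large interaction variance, positive marginal mean),
negative-unstable (large interaction variance, negative marginal mean) and
stable (standard-Gaussian interactions, zero marginal mean).  Per-environment
residual variances are heterogeneous design constants.  The defaults are a
20-genotype (5/5/10), 5-environment, 2-replicate trial with residual
variances (0.546, 1.209, 4.690, 7.377, 9.026) trait-units^2.

Each genotype's marginal effect is a Gaussian realization centered at its
group's magnitude; interactions are independent zero-mean Gaussians per
environment with the group's variance.  The realized genetic value of cell
(i, j) is u_ij = g_i + ge_ij, so the across-environment genetic covariance
implied by the design is Var(g) on off-diagonals plus the mean interaction
variance on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .met_data import METDataset

__all__ = [
    "SimulationDesign",
    "SimulatedTruth",
    "simulate_met",
    "apply_missingness",
]

_TABLE_PV = (0.546, 1.209, 4.690, 7.377, 9.026)


@dataclass(frozen=True)
class SimulationDesign:
    m: int = 20
    p: int = 5
    q: int = 2
    group_sizes: tuple[int, int, int] = (5, 5, 10)
    group_means: tuple[float, float, float] = (2.4, -2.4, 0.0)
    marginal_sd: float = 1.0
    stable_interaction_variance: float = 1.0
    unstable_interaction_variance: float = 2.0
    residual_variances: tuple[float, ...] = _TABLE_PV
    env_effects: tuple[float, ...] | None = None
    block_effects: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.m:
            raise ValueError(
                f"group sizes {self.group_sizes} do not sum to m={self.m}"
            )
        if len(self.residual_variances) != self.p:
            raise ValueError("need one residual variance per environment")
        for name in ("marginal_sd", "stable_interaction_variance",
                     "unstable_interaction_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.residual_variances):
            raise ValueError("residual variances must be >= 0")
        if self.env_effects is not None and len(self.env_effects) != self.p:
            raise ValueError("need one environment effect per environment")
        if self.block_effects is not None and len(self.block_effects) != self.q:
            raise ValueError("need one block effect per replicate")

    @property
    def group_labels(self) -> np.ndarray:
        """Per-genotype group: 'positive-unstable' / 'negative-unstable' / 'stable'."""
        names = ("positive-unstable", "negative-unstable", "stable")
        return np.repeat(names, self.group_sizes)

    def interaction_variances(self) -> np.ndarray:
        """Per-genotype interaction variance."""
        u = self.unstable_interaction_variance
        s = self.stable_interaction_variance
        return np.repeat(
            [u, u, s], self.group_sizes
        ).astype(float)

    def implied_covariance(self) -> np.ndarray:
        """Across-environment genetic covariance of the mixture design.

        Off-diagonal entries equal the population variance of genotype
        marginal effects; the diagonal adds the mean interaction variance.
        """
        w = np.asarray(self.group_sizes, dtype=float) / self.m
        mu = np.asarray(self.group_means, dtype=float)
        var_g = self.marginal_sd**2 + float(w @ mu**2 - (w @ mu) ** 2)
        mean_int = float(w @ [self.unstable_interaction_variance,
                              self.unstable_interaction_variance,
                              self.stable_interaction_variance])
        return var_g * np.ones((self.p, self.p)) + mean_int * np.eye(self.p)


@dataclass(frozen=True)
class SimulatedTruth:
    """Realized effects behind one simulated dataset."""

    design: SimulationDesign
    genotype_effects: np.ndarray  # (m,)
    interaction: np.ndarray  # (m, p)
    residual_variances: np.ndarray  # (p,) design constants
    realized_residual_variances: np.ndarray  # (p,) sample variance of the noise

    @property
    def genetic_values(self) -> np.ndarray:
        """u_ij = g_i + ge_ij, shape (m, p)."""
        return self.genotype_effects[:, None] + self.interaction

    @property
    def realized_genetic_covariance(self) -> np.ndarray:
        """Sample covariance of the realized genetic values across environments."""
        return np.atleast_2d(np.cov(self.genetic_values, rowvar=False))

    def first_factor_loadings(self) -> np.ndarray:
        """lambda_1 alpha_1 of the realized genetic covariance (sign: the
        largest-magnitude coordinate is positive)."""
        evals, evecs = np.linalg.eigh(self.realized_genetic_covariance)
        lam = np.sqrt(max(evals[-1], 0.0))
        vec = evecs[:, -1]
        if vec[int(np.argmax(np.abs(vec)))] < 0:
            vec = -vec
        return lam * vec


def simulate_met(
    design: SimulationDesign | None = None, seed: int | None = None
) -> tuple[METDataset, SimulatedTruth]:
    """Draw one complete m x p x q dataset from the design.

    Deterministic for a given (design, seed); ``seed`` overrides the
    design's own seed when given.
    """
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    m, p, q = design.m, design.p, design.q

    mu = np.repeat(design.group_means, design.group_sizes)
    g = mu + design.marginal_sd * rng.standard_normal(m)
    int_sd = np.sqrt(design.interaction_variances())
    ge = int_sd[:, None] * rng.standard_normal((m, p))
    res_sd = np.sqrt(np.asarray(design.residual_variances))
    noise = res_sd[None, :, None] * rng.standard_normal((m, p, q))

    env_eff = np.zeros(p) if design.env_effects is None else np.asarray(design.env_effects)
    blk_eff = np.zeros(q) if design.block_effects is None else np.asarray(design.block_effects)

    gen_labels = [f"G{i + 1}" for i in range(m)]
    env_labels = [f"E{j + 1}" for j in range(p)]
    rows = []
    for j in range(p):
        for r in range(q):
            for i in range(m):
                rows.append((
                    gen_labels[i], env_labels[j], f"B{r + 1}",
                    env_eff[j] + blk_eff[r] + g[i] + ge[i, j] + noise[i, j, r],
                ))
    records = pd.DataFrame(rows, columns=["genotype", "environment", "block", "value"])
    data = METDataset(records)

    # realized residual variance = pooled within-cell replicate variance,
    # the quantity the model's sigma_e2 is identified by
    if q > 1:
        cell_means = noise.mean(axis=2, keepdims=True)
        realized_res = np.sum((noise - cell_means) ** 2, axis=(0, 2)) / (m * (q - 1))
    else:
        realized_res = np.var(noise[:, :, 0], axis=0, ddof=1)
    truth = SimulatedTruth(
        design=design,
        genotype_effects=g,
        interaction=ge,
        residual_variances=np.asarray(design.residual_variances, dtype=float),
        realized_residual_variances=realized_res,
    )
    return data, truth


def _training_ok(data: METDataset, removed: set[tuple[str, str]]) -> bool:
    """Every environment keeps >= 1 cell and every genotype >= 1 environment."""
    gi = {g: i for i, g in enumerate(data.genotypes)}
    ei = {e: j for j, e in enumerate(data.environments)}
    table = data.cell_table.copy()
    for g, e in removed:
        table[gi[g], ei[e]] = False
    return bool(table.any(axis=0).all() and table.any(axis=1).all())


def apply_missingness(
    data: METDataset,
    fraction: float | None = None,
    cells: list[tuple[str, str]] | None = None,
    seed: int = 0,
    max_retries: int = 1000,
) -> METDataset:
    """Remove whole genotype x environment cells (all replicates).

    Either a random ``fraction`` of observed cells (respecting the
    constraints that every environment retains at least one cell and every
    genotype remains observed in at least one environment) or an explicit
    cell list.  ``fraction=0`` is the identity.
    """
    if (fraction is None) == (cells is None):
        raise ValueError("give exactly one of fraction or cells")
    if cells is not None:
        if not _training_ok(data, set(cells)):
            raise ValueError(
                "removal set would orphan a genotype or environment"
            )
        return data.drop_cells(cells)
    if fraction == 0:
        return data
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    observed = [
        (data.genotypes[i], data.environments[j])
        for i, j in zip(*np.nonzero(data.cell_table))
    ]
    n_remove = int(round(fraction * len(observed)))
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        pick = rng.choice(len(observed), size=n_remove, replace=False)
        chosen = [observed[i] for i in pick]
        if _training_ok(data, set(chosen)):
            return data.drop_cells(chosen)
    raise ValueError(
        f"could not find a feasible {fraction:.0%} removal set in "
        f"{max_retries} attempts"
    )
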