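"""Gibbs sampler for the Bayesian factor-analytic MET model.

All full conditionals are conjugate: Gaussian for the fixed effects,
factor scores and specific effects; truncated Gaussian for the ordered
singular values; scaled inverse chi-squared for the variance components.
The environment eigenvectors have a Gaussian conditional that ignores the
orthonormality constraint, so each alpha_k is sampled in the "corrected"
subspace orthogonal to the columns already updated this scan: build an
orthonormal complement H of those columns (Gram-Schmidt), draw the
Gaussian in the lower-dimensional coordinates, normalize to unit length
(the back-transformation preserves norms) and map back with H.

A single scan updates, in order,
beta -> lambda_1..k -> alpha_1..k -> f -> delta -> psi -> sigma_e2,
recomputing the partial residuals from the current state before each
conditional rather than patching them incrementally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .met_data import DesignMatrices, METDataset, build_design_matrices
from .model import ModelState, PriorSpec, genetic_component, log_likelihood

__all__ = [
    "SamplerConfig",
    "ChainStore",
    "initialize_state",
    "gram_schmidt_complement",
    "sample_beta",
    "sample_lambda",
    "sample_alpha",
    "sample_f",
    "sample_delta",
    "sample_psi",
    "sample_sigma_e",
    "run_gibbs",
]

_SING_TOL = 1e-12  # relative threshold for a numerically null conditional


@dataclass(frozen=True)
class SamplerConfig:
    """Chain-control settings.

    ``retained`` = floor((iterations - burn_in) / thin) draws are kept.
    ``full_rank=True`` forces k = p with the specific effects fixed at zero.
    """

    k: int
    iterations: int
    burn_in: int = 0
    thin: int = 1
    seed: int = 0
    full_rank: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in or self.burn_in < 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ChainStore:
    """Retained post-burn-in, thinned draws of every parameter.

    Arrays are indexed draw-first: ``lambdas`` has shape (retained, k),
    ``alphas`` (retained, p, k), ``f`` (retained, m, k), and so on.
    Eigenvector/score signs are aligned at storage time (the coordinate of
    each alpha_k with the largest absolute running posterior mean is made
    positive, flipping f_k jointly), which leaves every likelihood-relevant
    product unchanged.
    """

    config: SamplerConfig
    priors: PriorSpec
    genotypes: list[str]
    environments: list[str]
    cell_labels: list[tuple[str, str]]
    beta: np.ndarray
    lambdas: np.ndarray
    alphas: np.ndarray
    f: np.ndarray
    delta: np.ndarray
    psi: np.ndarray
    sigma_e2: np.ndarray
    loglik: np.ndarray

    @property
    def retained(self) -> int:
        return len(self.loglik)

    @property
    def k(self) -> int:
        return self.lambdas.shape[1]

    @property
    def p(self) -> int:
        return self.alphas.shape[1]

    @property
    def m(self) -> int:
        return self.f.shape[1]

    def state_at(self, i: int) -> ModelState:
        return ModelState(
            beta=self.beta[i],
            lambdas=self.lambdas[i],
            alphas=self.alphas[i],
            f=self.f[i],
            delta=self.delta[i],
            psi=self.psi[i],
            sigma_e2=self.sigma_e2[i],
        )

    def posterior_mean_state(self) -> ModelState:
        """Coordinatewise posterior means (alphas averaged after alignment;
        the mean eigenvectors are not re-orthonormalized)."""
        return ModelState(
            beta=self.beta.mean(0),
            lambdas=self.lambdas.mean(0),
            alphas=self.alphas.mean(0),
            f=self.f.mean(0),
            delta=self.delta.mean(0),
            psi=self.psi.mean(0),
            sigma_e2=self.sigma_e2.mean(0),
        )

    def save(self, path) -> None:
        """Persist to a self-describing ``.npz`` archive."""
        np.savez_compressed(
            path,
            beta=self.beta, lambdas=self.lambdas, alphas=self.alphas,
            f=self.f, delta=self.delta, psi=self.psi,
            sigma_e2=self.sigma_e2, loglik=self.loglik,
            genotypes=np.array(self.genotypes),
            environments=np.array(self.environments),
            cell_env=np.array([c[0] for c in self.cell_labels]),
            cell_block=np.array([c[1] for c in self.cell_labels]),
            config=np.array([self.config.k, self.config.iterations,
                             self.config.burn_in, self.config.thin,
                             self.config.seed, int(self.config.full_rank)]),
            priors=np.array([self.priors.sigma_beta2, self.priors.nu_e,
                             self.priors.S_e2, self.priors.nu_k,
                             self.priors.S_k2, self.priors.lambda_prior_variance]),
        )

    @classmethod
    def load(cls, path) -> "ChainStore":
        with np.load(path, allow_pickle=False) as z:
            cfg = z["config"]
            pri = z["priors"]
            return cls(
                config=SamplerConfig(
                    k=int(cfg[0]), iterations=int(cfg[1]), burn_in=int(cfg[2]),
                    thin=int(cfg[3]), seed=int(cfg[4]), full_rank=bool(cfg[5]),
                ),
                priors=PriorSpec(*[float(v) for v in pri]),
                genotypes=[str(g) for g in z["genotypes"]],
                environments=[str(e) for e in z["environments"]],
                cell_labels=list(zip([str(e) for e in z["cell_env"]],
                                     [str(b) for b in z["cell_block"]])),
                beta=z["beta"], lambdas=z["lambdas"], alphas=z["alphas"],
                f=z["f"], delta=z["delta"], psi=z["psi"],
                sigma_e2=z["sigma_e2"], loglik=z["loglik"],
            )


# ---------------------------------------------------------------------------
# helpers


def _weights(state: ModelState, dm: DesignMatrices) -> np.ndarray:
    """Per-record residual precisions 1 / sigma_e2[env]."""
    return 1.0 / state.sigma_e2[dm.env_index]


def _gen_sort(dm: DesignMatrices) -> np.ndarray:
    """Stable permutation grouping records by genotype (cached on dm)."""
    cached = getattr(dm, "_gen_sort_cache", None)
    if cached is None:
        cached = np.argsort(dm.gen_index, kind="stable")
        object.__setattr__(dm, "_gen_sort_cache", cached)
    return cached


def _gen_starts(dm: DesignMatrices) -> np.ndarray:
    """Segment start offsets of each genotype in the sorted record order."""
    cached = getattr(dm, "_gen_starts_cache", None)
    if cached is None:
        g_sorted = dm.gen_index[_gen_sort(dm)]
        cached = np.flatnonzero(np.r_[True, np.diff(g_sorted) > 0])
        object.__setattr__(dm, "_gen_starts_cache", cached)
    return cached


def _truncnorm_draw(rng, mean: float, sd: float, lower: float, upper: float) -> float:
    """Inverse-CDF truncated-normal draw with a safe far-tail fallback."""
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    pa, pb = ndtr(a), ndtr(b)
    if pb - pa > 1e-12:
        return mean + sd * float(ndtri(rng.uniform(pa, pb)))
    # interval far in a tail: scipy's sampler handles the conditioning
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def gram_schmidt_complement(Hs: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the subspace orthogonal to the columns of ``Hs``.

    ``Hs`` is p x s with orthonormal columns (s may be 0); the result Hk is
    p x (p - s) with Hk' Hs = 0 and Hk' Hk = I, so that (Hs, Hk) is an
    orthonormal basis of R^p.
    """
    Hs = np.atleast_2d(np.asarray(Hs, dtype=float))
    p, s = Hs.shape
    if s > 0:
        gram = Hs.T @ Hs
        if np.max(np.abs(gram - np.eye(s))) > 1e-8:
            raise ValueError("columns of Hs are not orthonormal")
    if s == 0:
        return np.eye(p)
    # full QR of Hs: trailing columns span the orthogonal complement
    q, _ = np.linalg.qr(Hs, mode="complete")
    Hk = q[:, s:]
    # one projection pass against Hs guards against roundoff
    Hk = Hk - Hs @ (Hs.T @ Hk)
    return Hk / np.linalg.norm(Hk, axis=0)


# ---------------------------------------------------------------------------
# conditional samplers (each recomputes its partial residual from the state)


def sample_beta(
    state: ModelState, dm: DesignMatrices, y: np.ndarray,
    priors: PriorSpec, rng: np.random.Generator,
) -> np.ndarray:
    """Draw the environment-block fixed effects from their Gaussian conditional."""
    w = _weights(state, dm)
    a0 = y - genetic_component(state, dm) - state.delta[dm.ge_index]
    # cell-means coding makes X1' R^-1 X1 diagonal
    prec = np.bincount(dm.cell_index, weights=w, minlength=dm.n_cells)
    prec = prec + 1.0 / priors.sigma_beta2
    mean = np.bincount(dm.cell_index, weights=w * a0, minlength=dm.n_cells) / prec
    return mean + rng.standard_normal(dm.n_cells) / np.sqrt(prec)


def sample_lambda(
    k_index: int, state: ModelState, dm: DesignMatrices, y: np.ndarray,
    priors: PriorSpec, rng: np.random.Generator,
) -> float:
    """Draw singular value k from its ordered truncated-normal conditional.

    The truncation interval [lambda_{k+1}, lambda_{k-1}] (0 below the last,
    +inf above the first) keeps the vector ordered and nonnegative after a
    single-coordinate update.
    """
    w = _weights(state, dm)
    comp = state.alphas[dm.env_index, k_index] * state.f[dm.gen_index, k_index]
    without_k = genetic_component(state, dm) - state.lambdas[k_index] * comp
    a1 = y - state.beta[dm.cell_index] - without_k - state.delta[dm.ge_index]
    lower = state.lambdas[k_index + 1] if k_index + 1 < state.k else 0.0
    upper = state.lambdas[k_index - 1] if k_index > 0 else np.inf
    prec_data = float(np.sum(w * comp**2))
    if prec_data <= _SING_TOL * max(1.0, float(np.sum(w))):
        warnings.warn(
            f"factor {k_index + 1} is numerically null; "
            "drawing its singular value from the truncated prior",
            RuntimeWarning,
        )
        return _truncnorm_draw(
            rng, 0.0, np.sqrt(priors.lambda_prior_variance), lower, upper
        )
    prec = prec_data + 1.0 / priors.lambda_prior_variance
    mean = float(np.sum(w * comp * a1)) / prec
    return _truncnorm_draw(rng, mean, 1.0 / np.sqrt(prec), lower, upper)


def sample_alpha(
    k_index: int, state: ModelState, dm: DesignMatrices, y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw eigenvector k in the subspace orthogonal to columns 1..k-1.

    Four steps: complement basis H of the already-updated columns; Gaussian
    draw of the (p-s)-dimensional corrected-subspace coordinates; unit
    normalization; back-transformation alpha_k = H alpha_tilde.  When the
    data carry no information on this eigenvector (singular precision) the
    draw falls back to the spherical-uniform prior on the corrected subspace.
    """
    w = _weights(state, dm)
    lam = state.lambdas[k_index]
    fk = state.f[dm.gen_index, k_index]
    comp = state.alphas[dm.env_index, k_index] * fk
    a3 = (
        y - state.beta[dm.cell_index]
        - (genetic_component(state, dm) - lam * comp)
        - state.delta[dm.ge_index]
    )
    H = gram_schmidt_complement(state.alphas[:, :k_index])
    # Delta_k = lam * diag(Zf f_k) X2 has one nonzero per row, so
    # Delta' R^-1 Delta is diagonal with entries by environment
    W = lam**2 * np.bincount(dm.env_index, weights=w * fk**2, minlength=state.p)
    b = lam * np.bincount(dm.env_index, weights=w * fk * a3, minlength=state.p)
    if np.min(W) <= _SING_TOL * max(1.0, np.max(W)):
        warnings.warn(
            f"eigenvector {k_index + 1} conditional is singular; "
            "drawing uniformly on the corrected-subspace sphere",
            RuntimeWarning,
        )
        z = rng.standard_normal(H.shape[1])
        return H @ (z / np.linalg.norm(z))
    mean_sub = H.T @ (b / W)
    prec_sub = (H.T * W) @ H
    L = np.linalg.cholesky(prec_sub)
    z = rng.standard_normal(H.shape[1])
    draw = mean_sub + np.linalg.solve(L.T, z)
    draw /= np.linalg.norm(draw)
    return H @ draw


def sample_f(
    state: ModelState, dm: DesignMatrices, y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw all genotype factor scores jointly from their Gaussian conditional.

    The stacked-score precision I + A4' R^-1 A4 is block diagonal by
    genotype (records of different genotypes never share an A4 column), so
    the draw factorizes into m independent k-dimensional Gaussians.
    """
    m, k = state.f.shape
    w = _weights(state, dm)
    a5 = y - state.beta[dm.cell_index] - state.delta[dm.ge_index]
    v = state.loadings[dm.env_index, :]  # n x k rows of A4
    # segment-sum rows by genotype (records pre-sorted once per design)
    order = _gen_sort(dm)
    starts = _gen_starts(dm)
    vs = v[order]
    ws = w[order]
    vw = vs * ws[:, None]
    M = (vw[:, :, None] * vs[:, None, :]).reshape(len(ws), k * k)
    B = np.add.reduceat(M, starts, axis=0).reshape(m, k, k)
    c = np.add.reduceat(vs * (ws * a5[order])[:, None], starts, axis=0)
    prec = B + np.eye(k)
    mean = np.linalg.solve(prec, c[:, :, None])[:, :, 0]
    L = np.linalg.cholesky(prec)
    z = rng.standard_normal((m, k, 1))
    return mean + np.linalg.solve(np.swapaxes(L, 1, 2), z)[:, :, 0]


def sample_delta(
    state: ModelState, dm: DesignMatrices, y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the specific effects; independent by genotype-environment cell."""
    if np.any(state.psi <= 0):
        raise ValueError(
            "specific-effect prior is degenerate (psi entry <= 0); "
            "use full_rank mode for k = p"
        )
    m, p = state.m, state.p
    w = _weights(state, dm)
    a7 = y - state.beta[dm.cell_index] - genetic_component(state, dm)
    prec = np.bincount(dm.ge_index, weights=w, minlength=m * p)
    prec = prec + 1.0 / np.tile(state.psi, m)
    mean = np.bincount(dm.ge_index, weights=w * a7, minlength=m * p) / prec
    return mean + rng.standard_normal(m * p) / np.sqrt(prec)


def sample_psi(
    state: ModelState, data: METDataset, priors: PriorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-environment specific variances from scaled inverse chi-squared.

    Only the specific effects of observed cells enter the sum of squares;
    m_j counts the genotypes observed in environment j.
    """
    m_per_env = data.genotypes_per_environment()
    delta_grid = state.delta.reshape(state.m, state.p)
    ss = np.sum(delta_grid**2 * data.cell_table, axis=0)
    df = m_per_env + priors.nu_k
    return (ss + priors.nu_k * priors.S_k2) / rng.chisquare(df)


def sample_sigma_e(
    state: ModelState, data: METDataset, dm: DesignMatrices,
    priors: PriorSpec, rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-environment residual variances from scaled inverse chi-squared."""
    from .model import predict_mean

    resid = data.y - predict_mean(state, dm)
    n_per_env = data.records_per_environment()
    if np.any(n_per_env == 0):
        raise ValueError("environment with zero records")
    ss = np.bincount(dm.env_index, weights=resid**2, minlength=state.p)
    df = n_per_env + priors.nu_e
    return (ss + priors.nu_e * priors.S_e2) / rng.chisquare(df)


# ---------------------------------------------------------------------------
# initialization and the scan loop


def initialize_state(
    data: METDataset, dm: DesignMatrices, config: SamplerConfig,
    rng: np.random.Generator,
) -> ModelState:
    """Method-of-moments starting point.

    Cell means seed beta; the genotype x environment table of residual
    means gives a sample covariance across environments whose top-k
    eigenpairs seed the singular values and eigenvectors; scores and
    specific effects start at zero; residual variances at the within-
    environment residual variance; specific variances at the part of the
    genetic variance the k factors leave unexplained.
    """
    n_per_env = data.records_per_environment()
    if np.any(n_per_env < 2):
        bad = [data.environments[j] for j in np.flatnonzero(n_per_env < 2)]
        raise ValueError(
            f"environments with fewer than 2 observations: {bad}; "
            "the residual-variance posterior would be degenerate"
        )
    y = data.y
    counts = np.bincount(dm.cell_index, minlength=dm.n_cells)
    beta = np.bincount(dm.cell_index, weights=y, minlength=dm.n_cells) / counts
    resid = y - beta[dm.cell_index]

    sigma_e2 = np.empty(data.p)
    for j in range(data.p):
        rj = resid[dm.env_index == j]
        sigma_e2[j] = float(np.var(rj, ddof=1))
    if np.any(sigma_e2 <= 0):
        bad = [data.environments[j] for j in np.flatnonzero(sigma_e2 <= 0)]
        raise ValueError(
            f"zero within-cell residual variance in environments {bad}; "
            "the data carry no replicate-level noise to estimate"
        )

    # genotype x environment table of residual means (0 in missing cells)
    table = np.zeros((data.m, data.p))
    np.add.at(table, (dm.gen_index, dm.env_index), resid)
    cell_n = np.zeros((data.m, data.p))
    np.add.at(cell_n, (dm.gen_index, dm.env_index), 1.0)
    table = np.divide(table, cell_n, out=np.zeros_like(table), where=cell_n > 0)
    S = np.cov(table, rowvar=False)
    S = np.atleast_2d(S)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1][: config.k]
    lambdas = np.sqrt(np.clip(evals[order], 0.0, None))
    alphas = evecs[:, order]

    if config.full_rank:
        psi = np.zeros(data.p)
    else:
        explained = np.sum((alphas * lambdas) ** 2, axis=1)
        psi = np.clip(np.diag(S) - explained, 1e-3, None)

    # principal-component regression scores keep the first scans of the
    # singular-value conditionals informative (an all-zero start would make
    # every factor numerically null at scan one)
    centered = table - table.mean(axis=0)
    f = np.zeros((data.m, config.k))
    nonzero = lambdas > 1e-12
    f[:, nonzero] = (centered @ alphas[:, nonzero]) / lambdas[nonzero]

    return ModelState(
        beta=beta,
        lambdas=lambdas,
        alphas=alphas,
        f=f,
        delta=np.zeros(data.m * data.p),
        psi=psi,
        sigma_e2=sigma_e2,
    )


def run_gibbs(
    data: METDataset,
    config: SamplerConfig,
    priors: PriorSpec | None = None,
    dm: DesignMatrices | None = None,
) -> ChainStore:
    """Run the Gibbs sampler and return the retained, thinned draws.

    Every retained draw is checked against the state invariants (ordered
    nonnegative singular values, orthonormal eigenvectors, valid variances);
    a violation raises with the scan index rather than being repaired.
    """
    priors = priors or PriorSpec()
    if dm is None:
        dm = build_design_matrices(data)
    k = data.p if config.full_rank else config.k
    if config.full_rank and config.k != data.p:
        config = SamplerConfig(
            k=data.p, iterations=config.iterations, burn_in=config.burn_in,
            thin=config.thin, seed=config.seed, full_rank=True,
        )
    if k > data.p:
        raise ValueError(f"k={k} exceeds the number of environments p={data.p}")
    rng = np.random.default_rng(config.seed)
    state = initialize_state(data, dm, config, rng)
    y = data.y

    R = config.retained
    store = ChainStore(
        config=config,
        priors=priors,
        genotypes=list(data.genotypes),
        environments=list(data.environments),
        cell_labels=list(dm.cell_labels),
        beta=np.empty((R, dm.n_cells)),
        lambdas=np.empty((R, k)),
        alphas=np.empty((R, data.p, k)),
        f=np.empty((R, data.m, k)),
        delta=np.empty((R, data.m * data.p)),
        psi=np.empty((R, data.p)),
        sigma_e2=np.empty((R, data.p)),
        loglik=np.empty(R),
    )

    running_alpha_sum = np.zeros((data.p, k))
    kept = 0
    for scan in range(config.iterations):
        state.beta = sample_beta(state, dm, y, priors, rng)
        for j in range(k):
            state.lambdas[j] = sample_lambda(j, state, dm, y, priors, rng)
        for j in range(k):
            state.alphas[:, j] = sample_alpha(j, state, dm, y, rng)
        state.f = sample_f(state, dm, y, rng)
        if not config.full_rank:
            state.delta = sample_delta(state, dm, y, rng)
            state.psi = sample_psi(state, data, priors, rng)
        state.sigma_e2 = sample_sigma_e(state, data, dm, priors, rng)

        # keep every thin-th post-burn-in scan, counting from burn_in + 1,
        # so exactly floor((iterations - burn_in) / thin) draws are stored
        if scan >= config.burn_in and (scan - config.burn_in + 1) % config.thin == 0:
            alphas = state.alphas.copy()
            f = state.f.copy()
            for j in range(k):
                ref = running_alpha_sum[:, j] if kept else alphas[:, j]
                pivot = int(np.argmax(np.abs(ref)))
                if alphas[pivot, j] < 0:
                    alphas[:, j] *= -1
                    f[:, j] *= -1
            running_alpha_sum += alphas
            aligned = ModelState(
                beta=state.beta.copy(), lambdas=state.lambdas.copy(),
                alphas=alphas, f=f, delta=state.delta.copy(),
                psi=state.psi.copy(), sigma_e2=state.sigma_e2.copy(),
            )
            try:
                aligned.validate(ortho_tol=1e-8)
            except ValueError as exc:
                raise RuntimeError(f"invariant violated at scan {scan + 1}: {exc}")
            store.beta[kept] = aligned.beta
            store.lambdas[kept] = aligned.lambdas
            store.alphas[kept] = aligned.alphas
            store.f[kept] = aligned.f
            store.delta[kept] = aligned.delta
            store.psi[kept] = aligned.psi
            store.sigma_e2[kept] = aligned.sigma_e2
            store.loglik[kept] = log_likelihood(aligned, data, dm)
            kept += 1
    assert kept == R
    return store
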