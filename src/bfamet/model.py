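"""Model state, priors and likelihood of the Bayesian factor-analytic MET model.

The model for a plot observation is

    y = X1 beta + sum_k lambda_k diag(X2 alpha_k) Zf f_k + Z delta + eps

where beta are environment-block cell means, lambda_k >= 0 are ordered
singular values, alpha_k orthonormal environment eigenvectors, f_k
genotype factor scores with standard-normal priors, delta genotype-by-
environment specific effects with per-environment variances psi, and eps
has an environment-blocked diagonal covariance R = blockdiag(sigma_e2[j] I).
The genetic covariance across environments implied by a state is

    Sigma = sum_k lambda_k^2 alpha_k alpha_k' + diag(psi),

i.e. the spectral form of the factor-analytic structure Sigma = Gamma Gamma' + Psi
with Gamma = [lambda_1 alpha_1, ..., lambda_k alpha_k].  With k = p factors
("full rank") the specific effects are identically zero and Sigma is an
unstructured covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .met_data import DesignMatrices, METDataset

__all__ = [
    "PriorSpec",
    "ModelState",
    "ConditionalWorkspace",
    "conditional_workspace",
    "predict_mean",
    "genetic_component",
    "log_likelihood",
    "implied_genetic_covariance",
]

ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    Defaults follow the vague conditionally-conjugate choices: an effectively
    flat Gaussian for fixed effects and singular values (variance 1e12), a
    Jeffreys-type scaled-inverse-chi-squared for the residual variances
    (nu_e = 0, S_e2 = 0), and nu_k = 1, S_k2 = 0 for the specific variances,
    matching the degrees of freedom the specific-variance conditional uses.
    """

    sigma_beta2: float = 1e12
    nu_e: float = 0.0
    S_e2: float = 0.0
    nu_k: float = 1.0
    S_k2: float = 0.0
    lambda_prior_variance: float = 1e12

    def __post_init__(self) -> None:
        for name in ("sigma_beta2", "nu_e", "S_e2", "nu_k", "S_k2", "lambda_prior_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


@dataclass
class ModelState:
    """One complete draw of all model unknowns.

    Shapes: ``beta`` (c,), ``lambdas`` (k,), ``alphas`` (p, k), ``f`` (m, k),
    ``delta`` (m*p,) genotype-major, ``psi`` (p,), ``sigma_e2`` (p,).
    """

    beta: np.ndarray
    lambdas: np.ndarray
    alphas: np.ndarray
    f: np.ndarray
    delta: np.ndarray
    psi: np.ndarray
    sigma_e2: np.ndarray

    @property
    def k(self) -> int:
        return len(self.lambdas)

    @property
    def p(self) -> int:
        return self.alphas.shape[0]

    @property
    def m(self) -> int:
        return self.f.shape[0]

    @property
    def loadings(self) -> np.ndarray:
        """Gamma = [lambda_1 alpha_1, ..., lambda_k alpha_k], shape (p, k)."""
        return self.alphas * self.lambdas

    def copy(self) -> "ModelState":
        return ModelState(*(np.array(getattr(self, f.name)) for f in
                            self.__dataclass_fields__.values()))  # type: ignore[arg-type]

    def validate(self, ortho_tol: float = ORTHO_TOL) -> None:
        """Assert the state invariants; raise ValueError on violation."""
        lam = self.lambdas
        if np.any(lam < 0) or np.any(np.diff(lam) > 0):
            raise ValueError(f"singular values not ordered nonnegative: {lam}")
        gram = self.alphas.T @ self.alphas
        if np.max(np.abs(gram - np.eye(self.k))) > ortho_tol:
            raise ValueError("eigenvector columns not orthonormal")
        if np.any(self.psi < 0):
            raise ValueError("negative specific variance")
        if np.any(self.sigma_e2 <= 0):
            raise ValueError("nonpositive residual variance")
        if self.k == self.p and np.any(self.psi != 0):
            raise ValueError("full-rank model must have zero specific variances")


def genetic_component(state: ModelState, dm: DesignMatrices) -> np.ndarray:
    """sum_k lambda_k diag(X2 alpha_k) Zf f_k as an n-vector."""
    # gather formulation: row r contributes sum_k lam_k alpha[env_r, k] f[gen_r, k]
    load = state.loadings  # p x k
    return np.einsum(
        "rk,rk->r", load[dm.env_index, :], state.f[dm.gen_index, :]
    ) if state.k else np.zeros(len(dm.env_index))


def predict_mean(state: ModelState, dm: DesignMatrices) -> np.ndarray:
    """Fitted mean theta = X1 beta + genetic component + Z delta."""
    if len(state.beta) != dm.n_cells:
        raise ValueError(
            f"beta has length {len(state.beta)}, expected {dm.n_cells} cells"
        )
    return (
        state.beta[dm.cell_index]
        + genetic_component(state, dm)
        + state.delta[dm.ge_index]
    )


def log_likelihood(
    state: ModelState, data: METDataset, dm: DesignMatrices
) -> float:
    """Gaussian log-likelihood with mean theta and blocked-diagonal R."""
    if np.any(state.sigma_e2 <= 0):
        raise ValueError("residual variances must be positive")
    resid = data.y - predict_mean(state, dm)
    var = state.sigma_e2[dm.env_index]
    return float(
        -0.5 * (len(resid) * np.log(2 * np.pi) + np.sum(np.log(var))
                + np.sum(resid**2 / var))
    )


@dataclass(frozen=True)
class ConditionalWorkspace:
    """Partial residuals entering the full conditionals, all length n.

    ``A0`` strips the genetic and specific components from y (fixed-effect
    conditional); ``A1k``/``A3k`` strip everything except factor k's term
    (singular-value / eigenvector conditionals, ``A2k`` being the factor's
    regressor diag(X2 alpha_k) Zf f_k); ``A5`` keeps only the genetic part
    (score conditional); ``A6``/``A7`` isolate the specific effects; ``theta``
    is the full fitted mean.  Indexed by 1-based factor number.
    """

    A0: np.ndarray
    A1k: dict[int, np.ndarray]
    A2k: dict[int, np.ndarray]
    A3k: dict[int, np.ndarray]
    A5: np.ndarray
    A6: np.ndarray
    A7: np.ndarray
    theta: np.ndarray


def conditional_workspace(
    state: ModelState, dm: DesignMatrices, y: np.ndarray
) -> ConditionalWorkspace:
    """Recompute every partial residual from the current state."""
    fixed = state.beta[dm.cell_index]
    spec = state.delta[dm.ge_index]
    load = state.loadings
    terms = [
        load[dm.env_index, k] * state.f[dm.gen_index, k] for k in range(state.k)
    ]
    genetic = np.sum(terms, axis=0) if terms else np.zeros_like(y)
    a1k, a2k, a3k = {}, {}, {}
    for k in range(state.k):
        others = genetic - terms[k]
        a1k[k + 1] = y - fixed - others - spec
        lam = state.lambdas[k]
        a2k[k + 1] = terms[k] / lam if lam > 0 else (
            state.alphas[dm.env_index, k] * state.f[dm.gen_index, k]
        )
        a3k[k + 1] = a1k[k + 1]
    return ConditionalWorkspace(
        A0=y - genetic - spec,
        A1k=a1k,
        A2k=a2k,
        A3k=a3k,
        A5=y - fixed - spec,
        A6=genetic,
        A7=y - fixed - genetic,
        theta=fixed + genetic + spec,
    )


def implied_genetic_covariance(state: ModelState) -> np.ndarray:
    """Sigma = sum_k lambda_k^2 alpha_k alpha_k' + diag(psi); symmetric PSD."""
    gamma = state.loadings
    sigma = gamma @ gamma.T + np.diag(state.psi)
    return 0.5 * (sigma + sigma.T)
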