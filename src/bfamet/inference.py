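"""Posterior summaries, biplot credibility regions and convergence diagnostics.

Point estimates follow highest-posterior-density logic: the MAP proxy is
the midpoint of the shortest interval holding a small fraction of the
sorted draws (a Chen-Shao-style mode estimate), and credible intervals are
the shortest contiguous windows at the stated probability.  Bivariate
credibility regions for biplots discard the 5% of retained draws farthest
(in Euclidean distance) from the distribution center and report the convex
hull of the rest.  The convergence checks are the standard Geweke
difference-of-means z, the Heidelberger-Welch stationarity/halfwidth scan,
and the Raftery-Lewis two-state run-length analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.spatial import ConvexHull, QhullError
from statsmodels.regression.linear_model import yule_walker

from .gibbs import ChainStore

__all__ = [
    "DegenerateChainError",
    "CredRegion2D",
    "VariancePartition",
    "BiplotCoordinates",
    "map_estimate",
    "hpd_interval",
    "credible_region_2d",
    "geweke_z",
    "heidelberger_welch",
    "HeidelbergerWelchResult",
    "raftery_lewis",
    "RafteryLewisResult",
    "variance_partition",
    "biplot_coordinates",
    "summarize_chain",
]


class DegenerateChainError(ValueError):
    """The draw sequence has zero variance; the diagnostic is undefined."""


# ---------------------------------------------------------------------------
# point and interval estimates


def map_estimate(draws, fraction: float = 0.05) -> float:
    """HPD-based posterior mode proxy.

    Midpoint of the shortest interval containing ``fraction`` of the sorted
    draws; for a unimodal posterior this tracks the density mode.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 draws, got {n}")
    win = max(2, int(np.ceil(fraction * n)))
    widths = x[win - 1:] - x[: n - win + 1]
    i = int(np.argmin(widths))
    return float(0.5 * (x[i] + x[i + win - 1]))


def hpd_interval(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(prob * N) sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 draws, got {n}")
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    keep = int(np.ceil(prob * n))
    widths = x[keep - 1:] - x[: n - keep + 1]
    i = int(np.argmin(widths))  # ties break to the lowest start
    return float(x[i]), float(x[i + keep - 1])


@dataclass(frozen=True)
class CredRegion2D:
    """Bivariate credibility region: retained points and their convex hull."""

    label: str
    points: np.ndarray  # retained (kept, 2)
    center: np.ndarray  # coordinatewise posterior mean (2,)
    prob: float
    hull_vertices: np.ndarray | None  # (v, 2) polygon, None when degenerate

    @property
    def area(self) -> float:
        if self.hull_vertices is None:
            return 0.0
        x, y = self.hull_vertices[:, 0], self.hull_vertices[:, 1]
        return float(0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    @property
    def contains_origin(self) -> bool:
        if self.hull_vertices is None:
            return bool(np.all(self.points == 0.0))
        hull = ConvexHull(self.hull_vertices)
        eqs = hull.equations  # A x + b <= 0 inside
        return bool(np.all(eqs[:, -1] <= 1e-12))


def credible_region_2d(draws_x, draws_y, prob: float = 0.95, label: str = "") -> CredRegion2D:
    """Euclidean-distance credibility region around the posterior mean.

    The farthest (1 - prob) fraction of paired draws is discarded; the
    region is the convex hull of the rest.
    """
    x = np.asarray(draws_x, dtype=float)
    y = np.asarray(draws_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("draws_x and draws_y must be equal-length vectors")
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 paired draws, got {n}")
    center = np.array([x.mean(), y.mean()])
    d = np.hypot(x - center[0], y - center[1])
    keep = int(np.ceil(prob * n))
    idx = np.argsort(d, kind="stable")[:keep]
    pts = np.column_stack([x[idx], y[idx]])
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # collinear or identical points
        verts = None
    return CredRegion2D(label=label, points=pts, center=center, prob=prob,
                        hull_vertices=verts)


# ---------------------------------------------------------------------------
# convergence diagnostics


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density of ``x`` at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    v = float(np.var(x, ddof=1))
    if v == 0.0:
        raise DegenerateChainError("constant draw sequence")
    xc = x - x.mean()
    best_aic = n * np.log(v)
    s0 = v
    max_order = min(20, n // 10)
    for order in range(1, max_order + 1):
        rho, sigma = yule_walker(xc, order=order, method="mle")
        sigma2 = float(sigma) ** 2
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2 * order
        if aic < best_aic:
            best_aic = aic
            s0 = sigma2 / (1.0 - float(np.sum(rho))) ** 2
    return s0


def geweke_z(draws, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke difference-of-means z between early and late chain windows."""
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 200:
        raise ValueError(f"need >= 200 draws, got {n}")
    if first + last > 1.0 or first <= 0 or last <= 0:
        raise ValueError("windows overlap: need first + last <= 1")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    if np.var(a) == 0 and np.var(b) == 0:
        raise DegenerateChainError("constant draw sequence")
    var = _spectrum0(a) / len(a) + _spectrum0(b) / len(b)
    return float((a.mean() - b.mean()) / np.sqrt(var))


@dataclass(frozen=True)
class HeidelbergerWelchResult:
    stationary: bool
    start_index: int  # first usable draw of the original sequence
    halfwidth_ratio: float
    halfwidth_passed: bool


# asymptotic 5% critical value of the Cramer-von Mises statistic
_CVM_CRIT_05 = 0.461


def heidelberger_welch(draws, eps: float = 0.1) -> HeidelbergerWelchResult:
    """Stationarity scan (Cramer-von Mises on Brownian-bridge sums) plus
    a 95% halfwidth test on the portion judged stationary.

    Successive 10% prefixes are discarded (up to half the chain) until the
    remaining sequence passes at the 5% level.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 200:
        raise ValueError(f"need >= 200 draws, got {n}")
    if np.var(x) == 0:
        raise DegenerateChainError("constant draw sequence")
    s0 = _spectrum0(x[n // 2:])
    stationary, start = False, 0
    for frac in np.arange(0.0, 0.55, 0.1):
        start = int(frac * n)
        seg = x[start:]
        ns = len(seg)
        csum = np.cumsum(seg)
        t = np.arange(1, ns + 1)
        bridge = (csum - t * seg.mean()) / np.sqrt(ns * s0)
        cvm = float(np.sum(bridge**2) / ns)
        if cvm < _CVM_CRIT_05:
            stationary = True
            break
    if not stationary:
        return HeidelbergerWelchResult(False, n, np.nan, False)
    seg = x[start:]
    hw = 1.96 * np.sqrt(_spectrum0(seg) / len(seg))
    mean = seg.mean()
    ratio = np.inf if mean == 0 else float(hw / abs(mean))
    return HeidelbergerWelchResult(True, start, ratio, ratio < eps)


@dataclass(frozen=True)
class RafteryLewisResult:
    burn_in: int
    n_required: int
    n_min: int
    thinning: int
    dependence_factor: float


def raftery_lewis(
    draws, q: float = 0.025, r: float = 0.005, s: float = 0.95,
    eps: float = 0.001,
) -> RafteryLewisResult:
    """Raftery-Lewis run-length control for estimating the q-quantile to
    precision r with probability s.

    Dichotomizes the chain at its q-quantile, finds the thinning at which
    the binary sequence is adequately first-order Markov (BIC comparison
    with a second-order chain), and converts the transition probabilities
    into burn-in and required chain length; the dependence factor I is the
    ratio of the required length to the length an iid chain would need.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    phi = ndtri(0.5 * (1.0 + s))
    n_min = int(np.ceil(phi**2 * q * (1 - q) / r**2))
    if n < n_min:
        raise ValueError(
            f"chain of length {n} is shorter than the pilot minimum {n_min}"
        )
    z = (x <= np.quantile(x, q)).astype(np.int8)

    def _bic_second_order(zz: np.ndarray) -> float:
        ntr = len(zz) - 2
        counts = np.zeros((2, 2, 2))
        np.add.at(counts, (zz[:-2], zz[1:-1], zz[2:]), 1.0)
        g2 = 0.0
        for i in range(2):
            for j in range(2):
                for kk in range(2):
                    if counts[i, j, kk] == 0:
                        continue
                    expected = (
                        counts[i, j, :].sum() * counts[:, j, kk].sum()
                        / max(counts[:, j, :].sum(), 1.0)
                    )
                    g2 += 2.0 * counts[i, j, kk] * np.log(counts[i, j, kk] / expected)
        return g2 - np.log(ntr) * 2.0

    kthin = 1
    while True:
        zz = z[::kthin]
        if len(zz) < 3 or _bic_second_order(zz) < 0:
            break
        kthin += 1
    zz = z[::kthin]
    trans = np.zeros((2, 2))
    np.add.at(trans, (zz[:-1], zz[1:]), 1.0)
    rows = trans.sum(axis=1)
    if rows[0] == 0 or rows[1] == 0:
        raise DegenerateChainError("dichotomized chain never changes state")
    alpha = trans[0, 1] / rows[0]  # P(below -> above)
    beta = trans[1, 0] / rows[1]
    ab = alpha + beta
    burn = int(np.ceil(
        np.log(eps * ab / max(alpha, beta)) / np.log(abs(1.0 - ab))
    )) * kthin
    n_keep = int(np.ceil(
        alpha * beta * (2.0 - ab) / ab**3 * phi**2 / r**2
    )) * kthin
    return RafteryLewisResult(
        burn_in=max(burn, 0),
        n_required=n_keep,
        n_min=n_min,
        thinning=kthin,
        dependence_factor=float((max(burn, 0) + n_keep) / n_min),
    )


# ---------------------------------------------------------------------------
# chain-level summaries


def _geometric_mean(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("geometric mean of negative entries")
    if np.any(v == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


@dataclass(frozen=True)
class VariancePartition:
    """Geometric means over environments of the variance components at the
    posterior mean state (loadings enter as posterior means of the products
    lambda_k alpha_k)."""

    k: int
    genetic_from_loadings: float  # gm of diag(Gamma Gamma')
    genetic_total: float  # gm of diag(Gamma Gamma' + Psi)
    specific: float  # gm of psi
    residual: float  # gm of sigma_e2


def variance_partition(chain: ChainStore) -> VariancePartition:
    """Variance-partition diagnostic of a fitted chain."""
    products = chain.alphas * chain.lambdas[:, None, :]  # (R, p, k)
    gamma = products.mean(axis=0)
    psi = chain.psi.mean(axis=0)
    diag_gg = np.sum(gamma**2, axis=1)
    return VariancePartition(
        k=chain.k,
        genetic_from_loadings=_geometric_mean(diag_gg),
        genetic_total=_geometric_mean(diag_gg + psi),
        specific=_geometric_mean(psi),
        residual=_geometric_mean(chain.sigma_e2.mean(axis=0)),
    )


@dataclass(frozen=True)
class BiplotCoordinates:
    """Posterior-mean biplot coordinates with per-point credibility regions."""

    axes: tuple[int, int]
    loadings: pd.DataFrame  # environment, axis1, axis2
    scores: pd.DataFrame  # genotype, axis1, axis2
    loading_regions: list[CredRegion2D]
    score_regions: list[CredRegion2D]
    note: str


def biplot_coordinates(
    chain: ChainStore, axes: tuple[int, int] = (1, 2), prob: float = 0.95
) -> BiplotCoordinates:
    """Loading (lambda_a alpha_a) and score (f_a) biplot coordinates.

    Products are taken per draw (after the chain's sign alignment), so the
    coordinates are invariant to joint eigenvector/score sign flips.
    """
    a1, a2 = axes
    if chain.k < 2 or max(axes) > chain.k or min(axes) < 1:
        raise ValueError(f"axes {axes} need a chain fitted with k >= {max(axes)} (>= 2)")
    products = chain.alphas * chain.lambdas[:, None, :]  # (R, p, k)
    f = chain.f
    # re-apply the pivot-positive sign convention so that coordinates are
    # invariant to a joint (alpha_k, f_k) sign flip of the whole chain
    products = products.copy()
    f = f.copy()
    for kk in range(chain.k):
        mean_load = products[:, :, kk].mean(axis=0)
        pivot = int(np.argmax(np.abs(mean_load)))
        if mean_load[pivot] < 0:
            products[:, :, kk] *= -1
            f[:, :, kk] *= -1
    lx, ly = products[:, :, a1 - 1], products[:, :, a2 - 1]
    sx, sy = f[:, :, a1 - 1], f[:, :, a2 - 1]
    loading_regions = [
        credible_region_2d(lx[:, j], ly[:, j], prob, label=env)
        for j, env in enumerate(chain.environments)
    ]
    score_regions = [
        credible_region_2d(sx[:, i], sy[:, i], prob, label=g)
        for i, g in enumerate(chain.genotypes)
    ]
    loadings = pd.DataFrame({
        "environment": chain.environments,
        f"axis{a1}": lx.mean(axis=0),
        f"axis{a2}": ly.mean(axis=0),
    })
    scores = pd.DataFrame({
        "genotype": chain.genotypes,
        f"axis{a1}": sx.mean(axis=0),
        f"axis{a2}": sy.mean(axis=0),
    })
    if bool(np.all(loadings[f"axis{a1}"] > 0)):
        note = (
            "All first-axis environment loadings are positive: the main "
            "genotype effect is confounded with the interaction and the "
            "display reads like a GGE biplot (first axis ~ performance, "
            "second ~ stability)."
        )
    else:
        note = (
            "First-axis loadings change sign; interpret axes as interaction "
            "contrasts rather than as a GGE-style performance axis."
        )
    return BiplotCoordinates(
        axes=axes, loadings=loadings, scores=scores,
        loading_regions=loading_regions, score_regions=score_regions, note=note,
    )


def summarize_chain(chain: ChainStore, prob: float = 0.95) -> pd.DataFrame:
    """Per-parameter posterior mean, sd, MAP and HPD limits.

    Rows cover the residual variances, singular values, loading products
    lambda_k alpha_jk, specific variances and factor scores.
    """
    rows: list[dict] = []

    def add(name: str, draws: np.ndarray) -> None:
        lo, hi = hpd_interval(draws, prob)
        rows.append({
            "parameter": name,
            "PM": float(np.mean(draws)),
            "PSD": float(np.std(draws, ddof=1)),
            "MAP": map_estimate(draws),
            "LL": lo,
            "UL": hi,
        })

    for j, env in enumerate(chain.environments):
        add(f"sigma_e2[{env}]", chain.sigma_e2[:, j])
    for k in range(chain.k):
        add(f"lambda[{k + 1}]", chain.lambdas[:, k])
    products = chain.alphas * chain.lambdas[:, None, :]
    for k in range(chain.k):
        for j, env in enumerate(chain.environments):
            add(f"loading[{k + 1},{env}]", products[:, j, k])
    for j, env in enumerate(chain.environments):
        add(f"psi[{env}]", chain.psi[:, j])
    for k in range(chain.k):
        for i, g in enumerate(chain.genotypes):
            add(f"score[{k + 1},{g}]", chain.f[:, i, k])
    return pd.DataFrame(rows)
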