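"""Cell-deletion cross-validation, predictive metrics and factor-number selection.

Cross-validation deletes whole genotype x environment cells (all replicates)
in k equal folds -- k = 10, 3, 2 correspond to 10%, 33% and 50% missing-cell
scenarios -- under two feasibility constraints: every environment keeps at
least one observed cell and every genotype stays observed in at least one
environment.  Deleted cells are predicted by the posterior mean of
[environment fixed effect (averaged over its block cells) + sum_k
lambda_k alpha_jk f_ik + delta_ij] from a chain fitted to the training
records only.  Predictive quality is measured by PRESS (mean squared
prediction error) and the observed-vs-predicted Pearson correlation; model
orders are compared by PRESS, by the statistical efficiency
SE = PRESS_full / PRESS_k, and by AICM = 2(mean - variance) of the
per-draw log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import ChainStore, SamplerConfig, run_gibbs
from .met_data import METDataset
from .model import PriorSpec

__all__ = [
    "UndefinedCorrelationError",
    "FoldPlan",
    "CVResult",
    "make_cell_folds",
    "press",
    "prediction_correlation",
    "predict_deleted_cells",
    "statistical_efficiency",
    "aicm",
    "run_cv",
    "select_k",
    "marginal_blups",
    "score_blup_r2",
]

# per-fold fits use deliberately short chains; 15 fits must stay desk-scale
CV_ITERATIONS = 6000
CV_BURN_IN = 1000
CV_THIN = 2


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero variance in one input)."""


@dataclass(frozen=True)
class FoldPlan:
    """Random equal-size partition of observed cells into deletion folds."""

    n_folds: int
    folds: list[list[tuple[str, str]]]
    seed: int

    def __post_init__(self) -> None:
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    @property
    def deleted_cells(self) -> list[tuple[str, str]]:
        return [c for fold in self.folds for c in fold]


def make_cell_folds(
    data: METDataset, n_folds: int, seed: int = 0, max_retries: int = 1000
) -> FoldPlan:
    """Partition the observed genotype x environment cells into folds.

    Deterministic under ``seed``; reshuffles (bounded retries) until every
    training set satisfies the feasibility constraints, then raises an
    infeasibility error naming the most weakly connected genotype.
    """
    from .simulate import _training_ok

    observed = [
        (data.genotypes[i], data.environments[j])
        for i, j in zip(*np.nonzero(data.cell_table))
    ]
    if len(observed) < n_folds:
        raise ValueError(f"{len(observed)} observed cells < {n_folds} folds")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(len(observed))
        chunks = np.array_split(perm, n_folds)
        folds = [[observed[i] for i in chunk] for chunk in chunks]
        if all(_training_ok(data, set(fold)) for fold in folds):
            return FoldPlan(n_folds=n_folds, folds=folds, seed=seed)
    weakest = data.genotypes[int(np.argmin(data.cell_table.sum(axis=1)))]
    raise ValueError(
        f"no feasible {n_folds}-fold cell partition found in {max_retries} "
        f"attempts (genotype {weakest} is observed in too few environments)"
    )


def press(observed, predicted) -> float:
    """Mean squared prediction error (1/n) sum (y - yhat)^2."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    return float(np.mean((y - yhat) ** 2))


def prediction_correlation(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or len(y) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise UndefinedCorrelationError("zero variance in observed or predicted")
    return float(np.corrcoef(y, yhat)[0, 1])


def statistical_efficiency(press_full: float, press_k: float) -> float:
    """SE = PRESS of the full model over PRESS of the candidate."""
    if press_full <= 0 or press_k <= 0:
        raise ValueError("PRESS values must be positive")
    return press_full / press_k


def aicm(loglik_draws) -> float:
    """Monte-Carlo AIC, 2(lbar - s2_l), from retained log-likelihood draws."""
    ll = np.asarray(loglik_draws, dtype=float)
    if len(ll) < 2:
        raise ValueError("need at least 2 log-likelihood draws")
    return float(2.0 * (np.mean(ll) - np.var(ll, ddof=1)))


def predict_deleted_cells(
    chain: ChainStore, cells: list[tuple[str, str]]
) -> pd.DataFrame:
    """Posterior-mean predictions for deleted genotype x environment cells.

    The chain must come from a fit on the training records; each prediction
    averages, over retained draws, the environment's fixed effect (mean of
    its block cells), the factor reconstruction sum_k lambda_k alpha_jk f_ik,
    and the cell's specific effect.
    """
    gi = {g: i for i, g in enumerate(chain.genotypes)}
    ei = {e: j for j, e in enumerate(chain.environments)}
    for g, e in cells:
        if g not in gi:
            raise ValueError(f"genotype {g} absent from the training chain")
        if e not in ei:
            raise ValueError(f"environment {e} absent from the training chain")
    # per-draw mean fixed effect of each environment over its block cells
    env_cols = {
        j: [c for c, (env, _) in enumerate(chain.cell_labels) if env == e]
        for e, j in ei.items()
    }
    beta_env = np.column_stack([
        chain.beta[:, env_cols[j]].mean(axis=1) for j in range(len(ei))
    ])  # (R, p)
    products = chain.alphas * chain.lambdas[:, None, :]  # (R, p, k)
    delta = chain.delta.reshape(chain.retained, chain.m, chain.p)
    preds = []
    for g, e in cells:
        i, j = gi[g], ei[e]
        per_draw = (
            beta_env[:, j]
            + np.einsum("rk,rk->r", products[:, j, :], chain.f[:, i, :])
            + delta[:, i, j]
        )
        preds.append(float(per_draw.mean()))
    return pd.DataFrame({
        "genotype": [c[0] for c in cells],
        "environment": [c[1] for c in cells],
        "predicted": preds,
    })


@dataclass(frozen=True)
class CVResult:
    """Fold-level predictions and pooled predictive metrics."""

    scenario: str
    n_folds: int
    table: pd.DataFrame  # fold, genotype, environment, observed, predicted

    @property
    def pooled_press(self) -> float:
        return press(self.table["observed"], self.table["predicted"])

    @property
    def pooled_correlation(self) -> float:
        return prediction_correlation(self.table["observed"], self.table["predicted"])

    def per_fold(self) -> pd.DataFrame:
        rows = []
        for fold, grp in self.table.groupby("fold"):
            rows.append({
                "fold": fold,
                "n_deleted": len(grp),
                "press": press(grp["observed"], grp["predicted"]),
                "correlation": prediction_correlation(grp["observed"], grp["predicted"]),
            })
        return pd.DataFrame(rows)

    def mean_fold_correlation(self) -> float:
        return float(self.per_fold()["correlation"].mean())


def _fold_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _cell_means(data: METDataset, cells: list[tuple[str, str]]) -> np.ndarray:
    """Observed phenotypic mean of each cell (average over its replicates)."""
    grouped = data.records.groupby(["genotype", "environment"], sort=False)["value"].mean()
    return np.array([grouped[c] for c in cells])


def run_cv(
    data: METDataset,
    n_folds: int,
    seed: int = 0,
    k: int | None = None,
    iterations: int = CV_ITERATIONS,
    burn_in: int = CV_BURN_IN,
    thin: int = CV_THIN,
    priors: PriorSpec | None = None,
) -> CVResult:
    """Cell-deletion cross-validation with per-fold refitting.

    ``k=None`` fits the full-rank model (k = p, specific effects zero), the
    anchor for the statistical-efficiency ratio.  Observed cell values are
    the phenotypic means of the deleted replicates.
    """
    plan = make_cell_folds(data, n_folds, seed)
    full_rank = k is None or k == data.p
    k_eff = data.p if k is None else k
    seeds = _fold_seeds(seed, n_folds)
    frames = []
    for fold_idx, fold in enumerate(plan.folds):
        training = data.drop_cells(fold)
        config = SamplerConfig(
            k=k_eff, iterations=iterations, burn_in=burn_in, thin=thin,
            seed=seeds[fold_idx], full_rank=full_rank,
        )
        chain = run_gibbs(training, config, priors)
        pred = predict_deleted_cells(chain, fold)
        pred.insert(0, "fold", fold_idx + 1)
        pred["observed"] = _cell_means(data, fold)
        frames.append(pred)
    pct = {10: "10%", 3: "33%", 2: "50%"}.get(n_folds, f"1/{n_folds}")
    table = pd.concat(frames, ignore_index=True)
    return CVResult(scenario=pct, n_folds=n_folds, table=table)


def select_k(
    data: METDataset,
    candidate_orders: list[int],
    n_folds: int = 10,
    seed: int = 0,
    iterations: int = CV_ITERATIONS,
    burn_in: int = CV_BURN_IN,
    thin: int = CV_THIN,
    priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """Compare factor numbers by cross-validated PRESS/correlation/SE and AICM.

    Each candidate order is refitted per fold on the same fold plan; AICM
    comes from a full-data fit at the same chain settings.  Rank columns are
    reported per criterion; the criteria may disagree.
    """
    orders = sorted(set(candidate_orders))
    if any(not 1 <= k <= data.p for k in orders):
        raise ValueError(f"candidate orders must lie in 1..{data.p}")
    rows = []
    for k in orders:
        cv = run_cv(data, n_folds, seed=seed, k=k,
                    iterations=iterations, burn_in=burn_in, thin=thin,
                    priors=priors)
        config = SamplerConfig(
            k=k, iterations=iterations, burn_in=burn_in, thin=thin,
            seed=seed, full_rank=(k == data.p),
        )
        chain = run_gibbs(data, config, priors)
        rows.append({
            "k": k,
            "press": cv.pooled_press,
            "correlation": cv.pooled_correlation,
            "aicm": aicm(chain.loglik),
        })
    table = pd.DataFrame(rows)
    if data.p in orders:
        press_full = float(table.loc[table["k"] == data.p, "press"].iloc[0])
        aicm_full = float(table.loc[table["k"] == data.p, "aicm"].iloc[0])
        table["se"] = press_full / table["press"]
        table["delta_aicm"] = aicm_full - table["aicm"]
    table["rank_press"] = table["press"].rank(method="min").astype(int)
    table["rank_correlation"] = table["correlation"].rank(
        method="min", ascending=False).astype(int)
    table["rank_aicm"] = table["aicm"].rank(method="min", ascending=False).astype(int)
    return table


def marginal_blups(data: METDataset) -> pd.Series:
    """Shrunken genotype effects from the simple two-way mixed model.

    Fits y = environment-block cell (fixed) + genotype (random intercept,
    single variance) + residual by REML and returns the genotype BLUPs in
    the dataset's genotype order.  A zero genotype variance yields all-zero
    BLUPs.
    """
    import statsmodels.formula.api as smf

    if data.m < 2:
        raise ValueError("need at least 2 genotypes")
    df = data.records.copy()
    df["cell"] = df["environment"] + ":" + df["block"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ 0 + C(cell)", df, groups=df["genotype"])
        result = model.fit(reml=True)
        try:
            effects = result.random_effects
        except (ValueError, np.linalg.LinAlgError):
            # genotype variance estimated at zero: all effects shrink to 0
            return pd.Series(0.0, index=data.genotypes, name="blup")
    return pd.Series(
        [float(np.asarray(effects[g]).ravel()[0]) for g in data.genotypes],
        index=data.genotypes,
        name="blup",
    )


def score_blup_r2(chain: ChainStore, data: METDataset) -> float:
    """r^2 of the regression of first-factor posterior-mean scores on the
    marginal genotype BLUPs."""
    scores = chain.f[:, :, 0].mean(axis=0)
    blups = marginal_blups(data).to_numpy()
    return float(np.corrcoef(scores, blups)[0, 1] ** 2)
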