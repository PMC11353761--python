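"""Coefficient calibration: OLS, genetic algorithm, bootstrap CIs, metrics.

The area-law model is linear in its parameters, so ordinary least squares
is the exact RMSE minimizer and serves as the deterministic reference
fitter; the real-coded genetic algorithm reproduces the published
calibration protocol (fitness 1/RMSE, crossover 0.75, mutation 0.25,
bounds ±200/±100/±50/±50, 100 generations) and is validated against the
OLS optimum.  Confidence intervals come from percentile bootstrap over
resampled refits.

A scikit-learn estimator, :class:`AreaLawEntropyRegressor`, wraps both
fitters for use in pipelines and model selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .entropy_model import EntropyCoefficients
from .shapestats import SurfaceDescriptor

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationRecord",
    "FitResult",
    "GAConfig",
    "AreaLawEntropyRegressor",
    "design_row",
    "design_matrix",
    "fit_ols",
    "fit_ga",
    "bootstrap_ci",
    "rmse",
    "mape",
    "r2",
    "dcor",
    "pairwise_delta_rmse",
]

#: Parameter bounds of the published GA protocol: S0, a, b, c.
DEFAULT_BOUNDS = ((-200.0, 200.0), (-100.0, 100.0), (-50.0, 50.0), (-50.0, 50.0))

_SANITY_WINDOW = (100.0, 2000.0)
_EXPECTED_WINDOW = (190.0, 1040.0)


@dataclass
class CalibrationRecord:
    """One molecule: surface descriptor plus experimental entropy (J/mol·K)."""

    id: str
    descriptor: SurfaceDescriptor
    s_expt: float

    def __post_init__(self) -> None:
        lo, hi = _SANITY_WINDOW
        if not lo <= self.s_expt <= hi:
            raise ValueError(
                f"record {self.id!r}: s_expt={self.s_expt} J/mol·K outside sanity window {_SANITY_WINDOW}"
            )
        elo, ehi = _EXPECTED_WINDOW
        if not elo <= self.s_expt <= ehi:
            warnings.warn(
                f"record {self.id!r}: s_expt={self.s_expt} J/mol·K outside the typical "
                f"experimental range {_EXPECTED_WINDOW}",
                stacklevel=2,
            )


@dataclass
class FitResult:
    """A fitted coefficient set with its in-sample evaluation metrics."""

    coefficients: EntropyCoefficients
    rmse: float
    r2: float
    mape: float
    dcor: float
    n: int
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mape < 0 or self.r2 > 1 + 1e-12:
            raise ValueError("inconsistent fit metrics")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _pair(pred, obs):
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape or pred.size < 1:
        raise ValueError("pred and obs must be non-empty arrays of equal length")
    return pred, obs


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root mean square error, same units as the inputs."""
    pred, obs = _pair(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def mape(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean absolute percentage error, percent: mean of 100·|pred-obs|/obs."""
    pred, obs = _pair(pred, obs)
    if np.any(obs == 0):
        raise ValueError("mape undefined for zero observations")
    return float(np.mean(100.0 * np.abs(pred - obs) / np.abs(obs)))


def r2(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    pred, obs = _pair(pred, obs)
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("r2 undefined: observations have zero variance")
    return float(1.0 - np.sum((pred - obs) ** 2) / ss_tot)


def dcor(x: Sequence[float], y: Sequence[float]) -> float:
    """Distance correlation in [0, 1]; 0 only under independence (n >= 2).

    Double-centered Euclidean distance matrices (the classical biased
    V-statistic estimator).
    """
    x, y = _pair(x, y)
    if x.size < 2:
        raise ValueError("dcor needs n >= 2")

    def centred(v: np.ndarray) -> np.ndarray:
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()

    ax, ay = centred(x), centred(y)
    dcov2 = (ax * ay).mean()
    dvar_x = (ax * ax).mean()
    dvar_y = (ay * ay).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def pairwise_delta_rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """RMSE over all n(n-1)/2 unordered pair differences of pred vs obs.

    Relative-entropy evaluation: compares (pred_i - pred_j) against
    (obs_i - obs_j), so a constant offset in the predictions cancels.
    Only the errors e = pred - obs enter, through the identity
    sum_{i<j} (e_i - e_j)^2 = n·Σe² - (Σe)².
    """
    pred, obs = _pair(pred, obs)
    n = pred.size
    if n < 2:
        raise ValueError("pairwise_delta_rmse needs n >= 2")
    e = pred - obs
    ss_pairs = n * np.sum(e**2) - np.sum(e) ** 2
    return float(np.sqrt(ss_pairs / (n * (n - 1) / 2.0)))


# ---------------------------------------------------------------------------
# design matrix and fitters
# ---------------------------------------------------------------------------


def design_row(desc: SurfaceDescriptor) -> np.ndarray:
    """(1, area_spherical, sum_pos, sum_neg): prediction = coefficients · row."""
    return np.array([1.0, desc.area_spherical, desc.sum_pos, desc.sum_neg])


def design_matrix(records: Sequence[CalibrationRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([design_row(r.descriptor) for r in records])
    y = np.array([r.s_expt for r in records])
    return x, y


_COLUMN_NAMES = ("intercept", "area_spherical", "sum_pos", "sum_neg")


def _check_rank(x: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify (near-)collinear columns through the R diagonal of a QR
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [
            _COLUMN_NAMES[j] if j < len(_COLUMN_NAMES) else f"col{j}"
            for j in np.where(diag < 1e-10 * diag.max())[0]
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear column(s): {bad}"
        )


def _metrics(x: np.ndarray, y: np.ndarray, theta: np.ndarray) -> dict:
    pred = x @ theta
    return {
        "rmse": rmse(pred, y),
        "r2": r2(pred, y),
        "mape": mape(pred, y),
        "dcor": dcor(pred, y),
    }


def _coeffs_from_theta(theta: np.ndarray, model_tag: str) -> EntropyCoefficients:
    if model_tag == "area_deformation":
        s0, a, b, c = theta
        return EntropyCoefficients(model_tag, float(s0), float(a), float(b), float(c))
    s0, a = theta[:2]
    return EntropyCoefficients(model_tag, float(s0), float(a))


def fit_ols(
    records: Sequence[CalibrationRecord],
    model_tag: str = "area_deformation",
) -> FitResult:
    """Exact least-squares calibration of the linear area-law model."""
    if len(records) < 5:
        raise ValueError(f"need at least 5 records, got {len(records)}")
    x, y = design_matrix(records)
    x = _model_columns(x, records, model_tag)
    _check_rank(x)
    theta, *_ = np.linalg.lstsq(x, y, rcond=None)
    m = _metrics(x, y, theta)
    return FitResult(
        coefficients=_coeffs_from_theta(theta, model_tag),
        n=len(records),
        method="ols",
        **m,
    )


def _model_columns(
    x: np.ndarray, records: Sequence[CalibrationRecord], model_tag: str
) -> np.ndarray:
    if model_tag == "area_deformation":
        return x
    if model_tag == "area_only":
        return np.column_stack(
            [np.ones(len(records)), [r.descriptor.total_area for r in records]]
        )
    if model_tag == "volume_only":
        vols = [r.descriptor.total_volume for r in records]
        if any(v is None for v in vols):
            raise ValueError("volume_only fit requires descriptors with total_volume")
        return np.column_stack([np.ones(len(records)), vols])
    raise ValueError(f"unknown model_tag {model_tag!r}")


@dataclass
class GAConfig:
    """Real-coded GA settings; defaults follow the published protocol.

    The paper fixes crossover/mutation probabilities, bounds, generation
    count and the 100-250 population range; encoding, selection and
    elitism are implementation choices (tournament selection, 5% elitism,
    uniform crossover, Gaussian mutation whose per-gene step scales with
    the current population spread so the search refines as it converges).
    """

    population_size: int = 200
    generations: int = 100
    crossover_prob: float = 0.75
    mutation_prob: float = 0.25
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    tournament_size: int = 3
    elite_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def _ga_minimize_rmse(
    x: np.ndarray, y: np.ndarray, config: GAConfig, seed: int
) -> np.ndarray:
    """Maximize 1/RMSE of the linear model over the bounded parameter box."""
    rng = np.random.default_rng(seed)
    n_par = x.shape[1]
    lo = np.array([b[0] for b in config.bounds[:n_par]])
    hi = np.array([b[1] for b in config.bounds[:n_par]])
    pop = rng.uniform(lo, hi, size=(config.population_size, n_par))
    # seed one individual at the centre of the box for scale-free problems
    n_elite = max(1, int(round(config.elite_frac * config.population_size)))

    def cost(p: np.ndarray) -> np.ndarray:
        resid = x @ p.T - y[:, None]  # (n_obs, pop)
        return np.sqrt(np.mean(resid**2, axis=0))

    costs = cost(pop)
    for _ in range(config.generations):
        order = np.argsort(costs)
        pop, costs = pop[order], costs[order]
        elite = pop[:n_elite]
        # tournament selection over the whole population
        n_children = config.population_size - n_elite
        picks = rng.integers(
            0, config.population_size, size=(2, n_children, config.tournament_size)
        )
        parents_a = pop[picks[0].min(axis=1)]  # population sorted: lower index = fitter
        parents_b = pop[picks[1].min(axis=1)]
        # uniform crossover
        do_cross = rng.random(n_children) < config.crossover_prob
        mask = rng.random((n_children, n_par)) < 0.5
        children = np.where(mask, parents_a, parents_b)
        children[~do_cross] = parents_a[~do_cross]
        # Gaussian mutation, step scaled to the surviving population spread
        spread = np.maximum(pop[: config.population_size // 2].std(axis=0), 1e-12)
        mutate = rng.random((n_children, n_par)) < config.mutation_prob
        children = children + mutate * rng.normal(0.0, spread, size=(n_children, n_par))
        children = np.clip(children, lo, hi)
        pop = np.vstack([elite, children])
        costs = np.concatenate([costs[:n_elite], cost(children)])
    best = pop[np.argmin(costs)]
    if np.any(np.isclose(best, lo)) or np.any(np.isclose(best, hi)):
        logger.warning("GA best individual lies on a parameter bound: %s", best)
    return best


def fit_ga(
    records: Sequence[CalibrationRecord],
    config: GAConfig | None = None,
    seed: int = 2024,
    model_tag: str = "area_deformation",
) -> FitResult:
    """Genetic-algorithm calibration maximizing 1/RMSE (seeded, reproducible)."""
    if len(records) < 5:
        raise ValueError(f"need at least 5 records, got {len(records)}")
    config = config or GAConfig()
    x, y = design_matrix(records)
    x = _model_columns(x, records, model_tag)
    theta = _ga_minimize_rmse(x, y, config, seed)
    m = _metrics(x, y, theta)
    return FitResult(
        coefficients=_coeffs_from_theta(theta, model_tag),
        n=len(records),
        method="ga",
        seed=seed,
        **m,
    )


def bootstrap_ci(
    records: Sequence[CalibrationRecord],
    fitter: Callable[[Sequence[CalibrationRecord]], FitResult] = fit_ols,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 2024,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for (S0, a, b, c) from resampled refits.

    Replicates on which the fitter fails are dropped (error if > 20% fail).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    records = list(records)
    n = len(records)
    draws = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            res = fitter([records[i] for i in idx])
        except Exception as exc:  # rank-deficient resample, etc.
            failed += 1
            logger.warning("bootstrap replicate failed: %s", exc)
            continue
        co = res.coefficients
        draws.append([co.s0, co.a, co.b, co.c])
    if failed > 0.2 * n_boot:
        raise RuntimeError(f"{failed}/{n_boot} bootstrap replicates failed")
    draws = np.array(draws)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    return {
        name: (float(lo[j]), float(hi[j]))
        for j, name in enumerate(("s0", "a", "b", "c"))
    }


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------


class AreaLawEntropyRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn regressor for the area-law entropy calibration.

    Parameters
    ----------
    model : {'area_deformation', 'area_only', 'volume_only'}
        Which nested model to fit.  ``area_deformation`` expects
        ``X[:, (0, 1, 2)] = (area_spherical, sum_pos, sum_neg)``; the
        baselines expect a single column (total area or volume).
    method : {'ols', 'ga'}
        Deterministic least squares or the genetic-algorithm protocol.
    population_size, generations, crossover_prob, mutation_prob : GA settings.
    random_state : seed for the GA.

    Attributes
    ----------
    coef_ : ndarray of slopes (a[, b, c]).
    intercept_ : S0, J/mol·K.
    coefficients_ : the fitted :class:`EntropyCoefficients`.
    rmse_, r2_, mape_, dcor_ : in-sample metrics.
    """

    def __init__(
        self,
        model: str = "area_deformation",
        method: str = "ols",
        population_size: int = 200,
        generations: int = 100,
        crossover_prob: float = 0.75,
        mutation_prob: float = 0.25,
        random_state: int = 2024,
    ):
        self.model = model
        self.method = method
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.random_state = random_state

    def _expected_columns(self) -> int:
        return 3 if self.model == "area_deformation" else 1

    def _select_columns(self, X: np.ndarray) -> np.ndarray:
        """Accept either the model's own columns or the full 5-column
        descriptor layout (area_spherical, sum_pos, sum_neg, total_area,
        total_volume) produced by ``SurfaceDescriptorTransformer``."""
        if X.shape[1] == 5:
            if self.model == "area_deformation":
                return X[:, :3]
            return X[:, [3]] if self.model == "area_only" else X[:, [4]]
        return X

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        X = self._select_columns(X)
        if X.shape[1] != self._expected_columns():
            raise ValueError(
                f"model {self.model!r} expects {self._expected_columns()} feature column(s), "
                f"got {X.shape[1]}"
            )
        design = np.column_stack([np.ones(len(X)), X])
        _check_rank(design)
        if self.method == "ols":
            theta, *_ = np.linalg.lstsq(design, y, rcond=None)
        elif self.method == "ga":
            config = GAConfig(
                population_size=self.population_size,
                generations=self.generations,
                crossover_prob=self.crossover_prob,
                mutation_prob=self.mutation_prob,
            )
            theta = _ga_minimize_rmse(design, y, config, self.random_state)
        else:
            raise ValueError(f"method must be 'ols' or 'ga', got {self.method!r}")
        self.intercept_ = float(theta[0])
        self.coef_ = np.asarray(theta[1:], dtype=float)
        self.coefficients_ = _coeffs_from_theta(theta, self.model)
        m = _metrics(design, y, theta)
        self.rmse_ = m["rmse"]
        self.r2_ = m["r2"]
        self.mape_ = m["mape"]
        self.dcor_ = m["dcor"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = self._select_columns(check_array(X))
        return self.intercept_ + X @ self.coef_
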