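"""Phase 1: ant-colony wrapper selection of predictor stations.

The target station's yield is to be predicted from neighbouring stations'
histories; which neighbours to pool into the training set is a subset-
selection problem.  An ant colony searches it: each candidate station i
carries a pheromone trail tau_i and a heuristic desirability eta_i (the
absolute Pearson correlation of its series with the target's).  Every ant
builds a subset of ``n_features`` distinct stations by sequential
roulette-wheel draws with probability

    p_i  proportional to  tau_i^alpha * eta_i^beta

over the not-yet-chosen candidates.  Subsets are scored by the prediction
RMSE of a lag-1 model trained on the pooled subset and evaluated on the
target's own lag pairs (the wrapper cost).  Trails then evaporate and each
ant deposits Q / cost on the stations of its subset (classic Ant System),
so stations appearing in cheap subsets become more attractive.

Published settings: 10 ants, 20 iterations, tau_0 = 1, alpha = beta = 1.
The cost model defaults to an ordinary-least-squares lag-1 fit (fast and
deterministic — the wrapper only has to *rank* subsets); a small fixed-seed
ELM is available via ``cost_model="elm"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import YieldPanel, denormalize

__all__ = [
    "ACOConfig",
    "SelectionResult",
    "heuristic_information",
    "subset_cost",
    "select_stations",
    "roulette_subset",
]

_ETA_FLOOR = 1e-6


class ACOError(ValueError):
    pass


@dataclass(frozen=True)
class ACOConfig:
    """Colony settings; defaults follow the published study."""

    n_features: int
    n_ants: int = 10
    n_iterations: int = 20
    initial_pheromone: float = 1.0
    alpha: float = 1.0  # pheromone exponential weight
    beta: float = 1.0  # heuristic exponential weight
    evaporation_rate: float = 0.1
    deposit_scale: float | None = None  # Q; default: mean target yield
    cost_model: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ACOError("n_features must be >= 1")
        if self.n_ants < 1 or self.n_iterations < 1:
            raise ACOError("n_ants and n_iterations must be >= 1")
        if not 0.0 < self.evaporation_rate < 1.0:
            raise ACOError("evaporation_rate must lie in (0, 1)")
        if self.initial_pheromone <= 0:
            raise ACOError("initial pheromone must be positive")


@dataclass
class SelectionResult:
    target_station: str
    selected_stations: list[str]
    correlations: list[float]  # signed Pearson r with the target series
    best_cost_trace: list[float]  # best-ever RMSE after each iteration
    final_pheromone: np.ndarray
    candidates: list[str] = field(default_factory=list)
    config: ACOConfig | None = None

    def to_dict(self) -> dict:
        return {
            "target_station": self.target_station,
            "selected_stations": self.selected_stations,
            "correlations": self.correlations,
            "best_cost_trace": self.best_cost_trace,
            "final_pheromone": self.final_pheromone.tolist(),
            "candidates": self.candidates,
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def heuristic_information(panel: YieldPanel, target: str) -> np.ndarray:
    """eta_i = |r(candidate_i, target)| + epsilon over all non-target stations.

    The epsilon floor keeps zero-correlation stations selectable; a constant
    candidate series (undefined correlation) gets the bare floor with a
    warning.
    """
    t = panel.series(target)
    etas = []
    for sid in panel.station_ids:
        if sid == target:
            continue
        r = _pearson(panel.series(sid), t)
        if np.isnan(r):
            warnings.warn(
                f"correlation undefined for station {sid!r}; using floor",
                stacklevel=2,
            )
            etas.append(_ETA_FLOOR)
        else:
            etas.append(abs(r) + _ETA_FLOOR)
    return np.asarray(etas)


def subset_cost(
    panel: YieldPanel,
    target: str,
    subset: list[str],
    cost_model: str = "linear",
    seed: int = 0,
) -> float:
    """Wrapper cost of one candidate subset: lag-1 prediction RMSE (kg ha^-1).

    The subset's pooled, normalized lag-1 pairs train the cost model; the
    target station's own lag-1 pairs are predicted and the RMSE is reported
    in original units.
    """
    from . import pipeline  # deferred: pipeline imports this module

    if not subset:
        raise ACOError("subset must be non-empty")
    if target in subset:
        raise ACOError(f"subset must not contain the target {target!r}")

    ds = pipeline.assemble(
        panel, list(subset), lags=[1], bounds_scope="train", target=target
    )
    if cost_model == "linear":
        A = np.column_stack([ds.train_inputs, np.ones(len(ds.train_targets))])
        coef, *_ = np.linalg.lstsq(A, ds.train_targets, rcond=None)
        At = np.column_stack([ds.test_inputs, np.ones(len(ds.test_targets))])
        pred_n = At @ coef
    elif cost_model == "elm":
        from . import learners

        model = learners.fit_elm(
            ds.train_inputs, ds.train_targets, n_hidden=10,
            activation="sig", seed=seed, ridge=1e-8,
        )
        pred_n = learners.predict(model, ds.test_inputs)
    else:
        raise ACOError(f"unknown cost_model {cost_model!r}")

    pred = denormalize(pred_n, ds.bounds)
    obs = denormalize(ds.test_targets, ds.bounds)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def roulette_subset(
    rng: np.random.Generator,
    tau: np.ndarray,
    eta: np.ndarray,
    alpha: float,
    beta: float,
    k: int,
) -> list[int]:
    """Draw k distinct candidate indices by sequential roulette wheel."""
    weights = tau**alpha * eta**beta
    available = list(range(len(tau)))
    chosen: list[int] = []
    for _ in range(k):
        w = weights[available]
        total = w.sum()
        p = np.full(len(available), 1.0 / len(available)) if total <= 0 else w / total
        idx = rng.choice(len(available), p=p)
        chosen.append(available.pop(idx))
    return chosen


def select_stations(
    panel: YieldPanel, target: str, config: ACOConfig
) -> SelectionResult:
    """Run the colony and return the best-ever subset with its audit trail."""
    candidates = [s for s in panel.station_ids if s != target]
    if config.n_features > len(candidates):
        raise ACOError(
            f"n_features={config.n_features} exceeds {len(candidates)} candidates"
        )
    rng = np.random.default_rng(config.seed)
    eta = heuristic_information(panel, target)
    tau = np.full(len(candidates), float(config.initial_pheromone))
    target_series = panel.series(target)
    Q = (
        config.deposit_scale
        if config.deposit_scale is not None
        else float(np.nanmean(target_series))
    )

    cost_cache: dict[frozenset, float] = {}

    def costed(idx_subset: list[int]) -> float:
        key = frozenset(idx_subset)
        if key not in cost_cache:
            names = [candidates[i] for i in idx_subset]
            cost_cache[key] = subset_cost(
                panel, target, names, cost_model=config.cost_model, seed=config.seed
            )
        return cost_cache[key]

    best_cost = np.inf
    best_subset: list[int] = []
    trace: list[float] = []
    for _ in range(config.n_iterations):
        ant_subsets = [
            roulette_subset(rng, tau, eta, config.alpha, config.beta, config.n_features)
            for _ in range(config.n_ants)
        ]
        ant_costs = [costed(s) for s in ant_subsets]
        for s, c in zip(ant_subsets, ant_costs):
            if c < best_cost:
                best_cost, best_subset = c, sorted(s)
        tau *= 1.0 - config.evaporation_rate
        for s, c in zip(ant_subsets, ant_costs):
            deposit = Q / max(c, 1e-12)
            for i in s:
                tau[i] += deposit
        trace.append(best_cost)

    selected = [candidates[i] for i in best_subset]
    corrs = [_pearson(panel.series(s), target_series) for s in selected]
    return SelectionResult(
        target_station=target,
        selected_stations=selected,
        correlations=corrs,
        best_cost_trace=trace,
        final_pheromone=tau,
        candidates=candidates,
        config=config,
    )
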