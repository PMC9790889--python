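"""Hyperparameter search: coordinate descent and Bayesian optimization.

Both tuners maximize a user-supplied objective (typically cross-validated
accuracy as a function of the filter counts F1, D, F2).  Coordinate descent
sweeps the axes one at a time, exhaustively over integer/categorical choices;
Bayesian optimization fits a Gaussian-process surrogate (Matern 5/2 on
normalized coordinates) and proposes the maximizer of the expected-improvement
acquisition over a seeded candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

logger = logging.getLogger(__name__)

__all__ = [
    "SearchSpace", "TuningResult", "coordinate_descent", "bayesian_optimize",
]


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    kind: str                 # "integer" | "categorical" | "continuous"
    low: float = None
    high: float = None
    choices: tuple = None

    def validate(self) -> None:
        if self.kind in ("integer", "continuous"):
            if self.low is None or self.high is None or self.low > self.high:
                raise ValueError(f"{self.name}: bounds low <= high required")
        elif self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: choices must be non-empty")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def grid(self):
        """All admissible values (integer/categorical axes only)."""
        if self.kind == "integer":
            return list(range(int(self.low), int(self.high) + 1))
        if self.kind == "categorical":
            return list(self.choices)
        raise ValueError(f"{self.name}: continuous axis has no finite grid")


@dataclass(frozen=True)
class SearchSpace:
    parameters: tuple

    def __post_init__(self):
        for p in self.parameters:
            p.validate()

    @classmethod
    def from_dict(cls, spec: dict) -> "SearchSpace":
        """e.g. ``{"F1": [4, 8, 16], "D": (1, 4), "x": {"low":0,"high":10}}``.

        Lists/tuples-of-values become categorical axes, 2-tuples of ints become
        integer ranges, dicts with low/high become continuous axes.
        """
        params = []
        for name, v in spec.items():
            if isinstance(v, dict):
                params.append(ParameterSpec(name, v.get("kind", "continuous"),
                                            low=v.get("low"), high=v.get("high"),
                                            choices=tuple(v.get("choices", ()))
                                            or None))
            elif isinstance(v, tuple) and len(v) == 2 and all(
                    isinstance(i, (int, np.integer)) for i in v):
                params.append(ParameterSpec(name, "integer", low=v[0], high=v[1]))
            else:
                params.append(ParameterSpec(name, "categorical",
                                            choices=tuple(v)))
        return cls(tuple(params))

    @property
    def names(self):
        return [p.name for p in self.parameters]


@dataclass
class TuningResult:
    best_config: dict
    best_score: float
    history: list                     # (config, score) in evaluation order
    method: str
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        finite = [s for _, s in self.history if np.isfinite(s)]
        if finite and not np.isclose(self.best_score, max(finite)):
            raise AssertionError("best score must be the history maximum")


def _safe_eval(objective, config: dict):
    try:
        return float(objective(config))
    except Exception as exc:  # noqa: BLE001 - scored as -inf, search continues
        logger.warning("objective failed on %s: %s", config, exc)
        return float("-inf")


def coordinate_descent(space: SearchSpace, objective, init: dict = None,
                       n_sweeps: int = 1) -> TuningResult:
    """Axis-by-axis maximization over integer/categorical grids.

    Each sweep optimizes every parameter in turn, holding the others at their
    current values and updating immediately, so after N axis optimizations the
    whole vector has been refreshed.  Accepted scores never decrease.
    """
    grids = {p.name: p.grid() for p in space.parameters}
    if init is None:
        current = {name: g[0] for name, g in grids.items()}
    else:
        current = dict(init)
        for name, g in grids.items():
            if current.get(name) not in g:
                raise ValueError(f"init value for {name!r} outside the space")
    history = []
    best = _safe_eval(objective, current)
    history.append((dict(current), best))
    for sweep in range(n_sweeps):
        for name in space.names:
            axis_best_val, axis_best_score = current[name], best
            for value in grids[name]:
                if value == current[name]:
                    continue
                candidate = dict(current, **{name: value})
                score = _safe_eval(objective, candidate)
                history.append((candidate, score))
                if score > axis_best_score:
                    axis_best_val, axis_best_score = value, score
            current[name] = axis_best_val
            best = axis_best_score
        logger.info("sweep %d: best %s -> %.4f", sweep + 1, current, best)
    return TuningResult(best_config=dict(current), best_score=best,
                        history=history, method="coordinate_descent",
                        metadata={"n_sweeps": n_sweeps})


def _to_unit(space: SearchSpace, config: dict) -> np.ndarray:
    x = []
    for p in space.parameters:
        if p.kind == "categorical":
            x.append(p.choices.index(config[p.name]) / max(len(p.choices) - 1, 1))
        else:
            span = p.high - p.low
            x.append((config[p.name] - p.low) / span if span else 0.5)
    return np.array(x)


def _from_unit(space: SearchSpace, x: np.ndarray) -> dict:
    config = {}
    for p, xi in zip(space.parameters, x):
        if p.kind == "categorical":
            config[p.name] = p.choices[int(round(xi * (len(p.choices) - 1)))]
        else:
            v = p.low + xi * (p.high - p.low)
            config[p.name] = int(round(v)) if p.kind == "integer" else float(v)
    return config


def bayesian_optimize(space: SearchSpace, objective, n_iter: int = 20,
                      n_init: int = 5, seed: int = 0, xi: float = 0.01,
                      n_candidates: int = 512) -> TuningResult:
    """GP-surrogate search with expected-improvement acquisition.

    ``n_init`` seeded random evaluations initialize the surrogate; each of the
    ``n_iter`` rounds refits the GP and evaluates the candidate maximizing EI
    over a fresh seeded candidate set (integer axes handled by continuous
    relaxation and rounding at evaluation).  When all observed scores are
    equal the surrogate is uninformative and the round falls back to random
    sampling with a warning.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    rng = np.random.default_rng(seed)
    dim = len(space.parameters)
    xs, ys, history = [], [], []

    def evaluate(xu: np.ndarray):
        config = _from_unit(space, xu)
        score = _safe_eval(objective, config)
        xs.append(xu)
        ys.append(score)
        history.append((config, score))

    for _ in range(n_init):
        evaluate(rng.random(dim))
    kernel = ConstantKernel(1.0) * Matern(length_scale=0.3 * np.ones(dim),
                                          length_scale_bounds=(1e-2, 1e2),
                                          nu=2.5)
    for _ in range(n_iter):
        y = np.array(ys)
        finite = np.isfinite(y)
        cand = rng.random((n_candidates, dim))
        if finite.sum() >= 2 and not np.allclose(y[finite], y[finite][0]):
            gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-8,
                                          normalize_y=True,
                                          random_state=int(seed) % (2 ** 31))
            X = np.array(xs)[finite]
            yv = y[finite]
            gp.fit(X, yv)
            mu, sd = gp.predict(cand, return_std=True)
            best = yv.max()
            sd = np.maximum(sd, 1e-12)
            z = (mu - best - xi) / sd
            ei = (mu - best - xi) * norm.cdf(z) + sd * norm.pdf(z)
            nxt = cand[int(np.argmax(ei))]
        else:
            logger.warning("degenerate surrogate; falling back to random "
                           "sampling")
            nxt = cand[0]
        evaluate(nxt)
    best_idx = int(np.nanargmax([s if np.isfinite(s) else -np.inf for s in ys]))
    result = TuningResult(
        best_config=history[best_idx][0], best_score=ys[best_idx],
        history=history, method="bayesian_optimization",
        metadata={"n_iter": n_iter, "n_init": n_init, "seed": seed, "xi": xi,
                  "acquisition": "expected_improvement"},
    )
    result.validate()
    return result
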