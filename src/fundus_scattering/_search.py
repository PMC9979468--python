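"""Seeded sequential model-based (Bayesian) hyperparameter search.

A compact minimizer over mixed log-continuous/categorical spaces: an initial
seeded random design, then a Gaussian-process surrogate (Matern 5/2 on the
unit-cube encoding) with expected-improvement acquisition optimized over a
seeded candidate pool.  A pure random-search mode is selectable.  Everything
is driven by one ``numpy`` Generator, so a fixed seed reproduces the whole
trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern


@dataclass(frozen=True)
class Real:
    """A log-uniform continuous dimension."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"{self.name}: need 0 < low < high for a log-uniform range")

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    def encode(self, value: float) -> list[float]:
        return [(np.log(value) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))]

    @property
    def width(self) -> int:
        return 1


@dataclass(frozen=True)
class Categorical:
    """An unordered choice dimension (one-hot encoded for the surrogate)."""

    name: str
    choices: tuple

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.integers(len(self.choices)))]

    def encode(self, value) -> list[float]:
        return [1.0 if c == value else 0.0 for c in self.choices]

    @property
    def width(self) -> int:
        return len(self.choices)


def _draw(space: Sequence, rng: np.random.Generator) -> dict:
    return {dim.name: dim.sample(rng) for dim in space}


def _encode(space: Sequence, params: dict) -> np.ndarray:
    out: list[float] = []
    for dim in space:
        out.extend(dim.encode(params[dim.name]))
    return np.asarray(out)


@dataclass
class SearchResult:
    best_params: dict
    best_value: float
    trials: list[tuple[dict, float]]


def minimize(
    objective: Callable[[dict], float],
    space: Sequence[Real | Categorical],
    n_calls: int = 30,
    n_initial: int = 10,
    seed: int = 0,
    method: str = "bayes",
    n_candidates: int = 256,
) -> SearchResult:
    """Minimize ``objective`` over ``space`` with ``n_calls`` evaluations."""
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    if method not in ("bayes", "random"):
        raise ValueError(f"unknown search method {method!r}")
    rng = np.random.default_rng(seed)
    n_initial = min(max(n_initial, 2), n_calls)

    trials: list[tuple[dict, float]] = []
    for _ in range(n_initial if method == "bayes" else n_calls):
        params = _draw(space, rng)
        trials.append((params, float(objective(params))))

    if method == "bayes":
        while len(trials) < n_calls:
            x = np.stack([_encode(space, p) for p, _ in trials])
            y = np.asarray([v for _, v in trials])
            gp = GaussianProcessRegressor(
                kernel=Matern(
                    length_scale=np.full(x.shape[1], 0.5),
                    length_scale_bounds=(1e-2, 1e2),
                    nu=2.5,
                ),
                alpha=1e-6,
                normalize_y=True,
                optimizer=None if len(trials) < 4 else "fmin_l_bfgs_b",
                random_state=0,
            )
            with warnings.catch_warnings():
                # a flat objective drives the length scale to its bound; the
                # surrogate is still usable for ranking candidates
                warnings.filterwarnings("ignore", message=".*length_scale.*")
                gp.fit(x, y)
            best = y.min()
            cands = [_draw(space, rng) for _ in range(n_candidates)]
            xc = np.stack([_encode(space, p) for p in cands])
            mu, sd = gp.predict(xc, return_std=True)
            sd = np.maximum(sd, 1e-12)
            imp = best - mu - 0.01
            ei = imp * norm.cdf(imp / sd) + sd * norm.pdf(imp / sd)
            params = cands[int(np.argmax(ei))]
            trials.append((params, float(objective(params))))

    best_params, best_value = min(trials, key=lambda t: t[1])
    return SearchResult(dict(best_params), best_value, trials)
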