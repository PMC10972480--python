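"""Sequential model-based (Bayesian) optimization over small search spaces.

A Gaussian-process surrogate with a Matern-5/2 kernel models the objective
on the unit hypercube; candidates are scored by expected improvement and the
best of a random candidate pool is evaluated next. This is deliberately
minimal — a handful of continuous/integer dimensions and tens of trials —
which is the regime hyperparameter tuning here lives in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Mapping

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class Dimension:
    """One search dimension: float, int, or log-scaled variants."""

    name: str
    low: float
    high: float
    kind: str = "float"  # float | int | logfloat | logint

    def __post_init__(self) -> None:
        if self.kind not in ("float", "int", "logfloat", "logint"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.low > self.high:
            raise ValueError(f"{self.name}: low > high")
        if self.kind.startswith("log") and self.low <= 0:
            raise ValueError(f"{self.name}: log dimension needs low > 0")

    def decode(self, u: float) -> float | int:
        """Map a unit-interval coordinate to the native scale."""
        u = float(np.clip(u, 0.0, 1.0))
        if self.kind.startswith("log"):
            val = np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
        else:
            val = self.low + u * (self.high - self.low)
        if self.kind.endswith("int"):
            return int(np.clip(round(val), self.low, self.high))
        return float(val)

    def encode(self, value: float) -> float:
        """Inverse of :meth:`decode` (clipped to the unit interval)."""
        if self.high == self.low:
            return 0.0
        if self.kind.startswith("log"):
            u = (np.log(value) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))
        else:
            u = (value - self.low) / (self.high - self.low)
        return float(np.clip(u, 0.0, 1.0))


@dataclass
class Trial:
    params: dict[str, Any]
    score: float


def maximize(
    objective: Callable[[Mapping[str, Any]], float],
    space: list[Dimension],
    n_trials: int,
    seed: int = 0,
    n_candidates: int = 256,
    initial: list[Mapping[str, Any]] | None = None,
) -> tuple[dict[str, Any], list[Trial]]:
    """Maximize ``objective`` over ``space`` with GP expected improvement.

    ``initial`` points (e.g. a model family's default configuration) are
    evaluated first; the next ``min(n_trials, max(4, d + 1))`` points are
    random exploration; subsequent points maximize EI over a random
    candidate pool. Deterministic under ``seed``. Returns the best
    parameters and the full trial log (length exactly ``n_trials``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    d = len(space)
    if d == 0:
        raise ValueError("empty search space")

    def decode(u: np.ndarray) -> dict[str, Any]:
        return {dim.name: dim.decode(u[i]) for i, dim in enumerate(space)}

    seeded = [
        np.array([dim.encode(pt[dim.name]) for dim in space])
        for pt in (initial or [])
    ][:n_trials]
    n_init = min(n_trials, len(seeded) + max(4, d + 1))
    U: list[np.ndarray] = []
    trials: list[Trial] = []

    for t in range(n_trials):
        if t < len(seeded):
            u = seeded[t]
        elif t < n_init:
            u = rng.random(d)
        else:
            X = np.vstack(U)
            y = np.array([tr.score for tr in trials])
            kernel = (
                ConstantKernel(1.0, (1e-3, 1e3))
                * Matern(length_scale=np.full(d, 0.3), nu=2.5,
                         length_scale_bounds=(1e-2, 1e2))
                + WhiteKernel(1e-4, (1e-8, 1e-1))
            )
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31 - 1))
            )
            gp.fit(X, y)
            cand = rng.random((n_candidates, d))
            mu, sd = gp.predict(cand, return_std=True)
            best = y.max()
            sd = np.maximum(sd, 1e-12)
            z = (mu - best) / sd
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        params = decode(u)
        score = float(objective(params))
        U.append(u)
        trials.append(Trial(params=params, score=score))

    best_trial = max(trials, key=lambda tr: tr.score)
    return dict(best_trial.params), trials
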