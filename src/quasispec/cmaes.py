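"""Compact (mu/mu_w, lambda) CMA-ES with box constraints by clipping.

Covariance matrix adaptation evolution strategy in its standard form:
weighted recombination of the best half of the population, cumulative
step-size adaptation (CSA), rank-one plus rank-mu covariance update, lazy
eigendecomposition.  Candidates are clipped into the box before evaluation
and before the distribution update, which matches the physical bound on
transparency spectra.  The implementation targets the moderate-dimension
(w ~ 48), small-budget regime of the per-pixel inverse problem; it accepts a
batch objective so a whole population is evaluated in one vectorized call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CMAES", "CMAResult", "minimize"]


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    n_evals: int
    reached: bool          # True if fun <= target within the budget
    n_iter: int


class CMAES:
    """One CMA-ES run on a box-constrained batch objective."""

    def __init__(self, x0: np.ndarray, sigma0: float,
                 rng: np.random.Generator,
                 popsize: int | None = None,
                 bounds: tuple[float, float] = (0.0, 1.0)):
        self.n = len(x0)
        n = self.n
        self.rng = rng
        self.lo, self.hi = bounds
        self.mean = np.clip(np.asarray(x0, dtype=float), self.lo, self.hi)
        self.sigma = float(sigma0)

        self.lam = popsize or (4 + int(3 * np.log(n)))
        self.mu = self.lam // 2
        w = np.log(self.lam / 2 + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights ** 2)

        # strategy parameters (Hansen's defaults)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = (1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1)
                      + self.cs)
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self._eigen_stale = 0
        self._eigen_every = max(1, int(1 / (10 * n * (self.c1 + self.cmu))))

    def _update_eigen(self) -> None:
        if self._eigen_stale < self._eigen_every:
            return
        self._eigen_stale = 0
        self.C = np.triu(self.C) + np.triu(self.C, 1).T
        d2, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(d2, 1e-20))

    def ask(self) -> np.ndarray:
        """Sample a population, clipped into the box; shape (lam, n)."""
        self._update_eigen()
        z = self.rng.standard_normal((self.lam, self.n))
        y = z * self.D
        x = self.mean + self.sigma * (y @ self.B.T)
        return np.clip(x, self.lo, self.hi)

    def tell(self, x: np.ndarray, f: np.ndarray) -> None:
        order = np.argsort(f)
        xsel = x[order[:self.mu]]
        # clipped samples re-expressed as steps from the old mean
        y = (xsel - self.mean) / self.sigma
        y_w = self.weights @ y
        old_mean = self.mean
        self.mean = self.mean + self.sigma * y_w

        inv_d = 1.0 / self.D
        c_inv_sqrt_yw = self.B @ (inv_d * (self.B.T @ y_w))
        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * c_inv_sqrt_yw)
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * (self._gen + 1)))
                < (1.4 + 2 / (self.n + 1)) * self.chi_n)
        self.pc = ((1 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff)
                   * y_w)

        rank1 = np.outer(self.pc, self.pc)
        delta_hsig = (1 - hsig) * self.cc * (2 - self.cc)
        rank_mu = (y.T * self.weights) @ y
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (rank1 + delta_hsig * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chi_n - 1))
        self.sigma = float(np.clip(self.sigma, 1e-12, 1e3))
        self._eigen_stale += 1

    _gen = 0

    def optimize(self, objective: Callable[[np.ndarray], np.ndarray],
                 budget: int, target: float = -np.inf) -> CMAResult:
        """Minimize a batch objective within an evaluation budget.

        ``objective`` maps an (m, n) array of candidates to m values.  Stops
        as soon as the best value so far is <= ``target`` or the budget is
        exhausted; returns the best-ever candidate.
        """
        best_x = self.mean.copy()
        best_f = np.inf
        n_evals = 0
        self._gen = 0
        while n_evals < budget:
            x = self.ask()
            f = np.asarray(objective(x), dtype=float)
            n_evals += len(f)
            i = int(np.argmin(f))
            if f[i] < best_f:
                best_f = float(f[i])
                best_x = x[i].copy()
            if best_f <= target:
                return CMAResult(best_x, best_f, n_evals, True, self._gen + 1)
            self.tell(x, f)
            self._gen += 1
        return CMAResult(best_x, best_f, n_evals, best_f <= target, self._gen)


def minimize(objective: Callable[[np.ndarray], np.ndarray],
             x0: np.ndarray, sigma0: float, budget: int,
             target: float = -np.inf,
             seed: int | np.random.Generator = 0,
             popsize: int | None = None,
             bounds: tuple[float, float] = (0.0, 1.0)) -> CMAResult:
    """Convenience wrapper: one seeded CMA-ES run."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    es = CMAES(x0, sigma0, rng, popsize=popsize, bounds=bounds)
    return es.optimize(objective, budget, target)
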