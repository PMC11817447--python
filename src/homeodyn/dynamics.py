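"""Simulation and eigen-analysis of the linear feedback system dx/dt = G x.

The state vector x(t) holds the relative change of each factor from its
day-1 baseline.  Integration uses explicit Euler (the model's native
scheme); the analytic eigensolution x(t) = sum_i c0_i exp(lambda_i t) v_i
provides closed-form trajectories and the basis for stability
classification: the system is homeostatic iff every eigenvalue of G has
negative real part.

Days 1-54 are simulated but masked in reported outputs: early postnatal
dynamics confound growth with regulation and the model is only trusted
from early adulthood (day 55) onwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .ontology import FACTORS, GainMatrix, IncompleteMatrixError

__all__ = [
    "Trajectory",
    "EigenSystem",
    "StabilityReport",
    "NonDiagonalizableError",
    "REPORT_START_DAY",
    "DIVERGENCE_BOUND",
    "simulate",
    "eigensystem",
    "analytic_states",
    "classify_stability",
    "doubling_time",
]

#: First day included in reported outputs (days 1-54 masked).
REPORT_START_DAY: int = 55

#: Max-norm bound beyond which a trajectory is declared divergent.
DIVERGENCE_BOUND: float = 1e12

#: Tolerance on Re(lambda) separating stable / marginal / unstable.
_STABILITY_EPS: float = 1e-9


class NonDiagonalizableError(np.linalg.LinAlgError):
    """The gain matrix is (numerically) defective; no eigensolution."""


def _as_array(G: GainMatrix | np.ndarray) -> np.ndarray:
    if isinstance(G, GainMatrix):
        return G.require_complete()
    A = np.asarray(G, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"gain matrix must be square, got {A.shape}")
    if not np.all(np.isfinite(A)):
        raise IncompleteMatrixError("gain matrix contains non-finite entries")
    return A


@dataclass
class Trajectory:
    """Factor states on a day grid starting at day 1.

    ``reporting_mask`` is False for days before day 55.  If the simulation
    diverged, ``diverged_day`` records the first day the max-norm exceeded
    the divergence bound and the grid is truncated there.
    """

    days: np.ndarray
    states: np.ndarray
    reporting_mask: np.ndarray
    diverged_day: float | None = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.states) or len(self.days) != len(
            self.reporting_mask
        ):
            raise ValueError("days, states and reporting_mask lengths differ")

    @property
    def diverged(self) -> bool:
        return self.diverged_day is not None

    def state_at(self, day: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.days - day)))
        if abs(self.days[idx] - day) > 1e-9:
            raise ValueError(f"day {day} is not on the trajectory grid")
        return self.states[idx]

    def window(self, start: float, end: float) -> "Trajectory":
        sel = (self.days >= start - 1e-9) & (self.days <= end + 1e-9)
        return Trajectory(
            self.days[sel], self.states[sel], self.reporting_mask[sel], self.diverged_day
        )

    def reported(self) -> "Trajectory":
        sel = self.reporting_mask
        return Trajectory(
            self.days[sel], self.states[sel], self.reporting_mask[sel], self.diverged_day
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in FACTORS[: self.states.shape[1]]]
        if self.states.shape[1] != len(cols):
            cols = [f"x{i}" for i in range(self.states.shape[1])]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "day", self.days)
        df["reported"] = self.reporting_mask
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    G: GainMatrix | np.ndarray,
    x0: np.ndarray | None = None,
    t_end: float = 200.0,
    dt: float = 1.0,
    divergence_bound: float = DIVERGENCE_BOUND,
) -> Trajectory:
    """Integrate dx/dt = G x by explicit Euler from day 1 to ``t_end``.

    The update is ``x(t + dt) = x(t) + dt * G @ x(t)``.  The initial state
    (default: the all-ones vector — states are relative changes with a
    baseline of 1, and the origin would be a fixed point) is the baseline
    at t = 0; states are reported on the day grid 1, 1+dt, ... up to
    ``t_end``, so the state at day d approximates x0 * exp(G d).
    """
    A = _as_array(G)
    n = A.shape[0]
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.ones(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (n,):
        raise ValueError(f"x0 must have shape ({n},)")

    total_steps = int(np.round(t_end / dt))
    first_kept = int(np.ceil(1.0 / dt - 1e-9))
    days = dt * np.arange(first_kept, total_steps + 1)
    states = np.empty((len(days), n))
    diverged_day = None
    stepper = np.eye(n) + dt * A
    kept = 0
    for k in range(1, total_steps + 1):
        x = stepper @ x
        if k >= first_kept:
            states[kept] = x
            kept += 1
            if np.max(np.abs(x)) > divergence_bound:
                diverged_day = float(dt * k)
                days = days[:kept]
                states = states[:kept]
                break
    mask = days >= REPORT_START_DAY
    return Trajectory(days, states, mask, diverged_day)


@dataclass
class EigenSystem:
    """Eigendecomposition of G together with initial-condition coefficients.

    ``vectors[:, i]`` is the eigenvector of ``lambdas[i]``; ``coeffs`` are
    the c0_i with V @ c0 = x(0), so the analytic trajectory is
    x(t) = sum_i c0_i exp(lambda_i t) v_i.
    """

    lambdas: np.ndarray
    vectors: np.ndarray
    coeffs: np.ndarray

    @property
    def max_real(self) -> float:
        return float(np.max(self.lambdas.real))


def eigensystem(
    G: GainMatrix | np.ndarray,
    x0: np.ndarray | None = None,
    cond_limit: float = 1e12,
) -> EigenSystem:
    """Analytic eigensolution of dx/dt = G x for initial state ``x0``.

    Raises :class:`NonDiagonalizableError` if the eigenvector matrix is
    numerically singular (defective G); the matrix is never perturbed
    silently.
    """
    A = _as_array(G)
    n = A.shape[0]
    x = np.ones(n) if x0 is None else np.asarray(x0, dtype=float)
    lam, V = np.linalg.eig(A)
    if np.linalg.cond(V) > cond_limit:
        raise NonDiagonalizableError(
            "gain matrix is numerically non-diagonalizable "
            f"(cond(V) > {cond_limit:g})"
        )
    c0 = np.linalg.solve(V, x.astype(complex))
    resid = np.max(np.abs(V @ c0 - x))
    if resid > 1e-8 * (1.0 + np.max(np.abs(x))):
        raise NonDiagonalizableError(
            f"eigenbasis reconstruction residual {resid:g} exceeds tolerance"
        )
    return EigenSystem(lam, V, c0)


def analytic_states(E: EigenSystem, days: np.ndarray) -> np.ndarray:
    """Evaluate the analytic solution at the given days (baseline x0 at t=0)."""
    t = np.asarray(days, dtype=float)
    # states[k] = sum_i c0_i exp(lam_i t_k) v_i
    phases = np.exp(np.outer(t, E.lambdas))  # (T, n)
    return np.real(phases * E.coeffs @ E.vectors.T)


class StabilityReport(NamedTuple):
    label: str  # stable | marginal | unstable
    mode: str  # oscillatory | non_oscillatory
    max_real: float


def classify_stability(
    G: GainMatrix | np.ndarray, eps: float = _STABILITY_EPS
) -> StabilityReport:
    """Classify homeostatic stability from the spectrum of G.

    Stable iff max Re(lambda) < 0 (within ``eps``); the mode is
    oscillatory iff some eigenvalue attaining the maximal real part (within
    ``eps``) has nonzero imaginary part.
    """
    A = _as_array(G)
    lam = np.linalg.eigvals(A)
    max_real = float(np.max(lam.real))
    if max_real > eps:
        label = "unstable"
    elif max_real < -eps:
        label = "stable"
    else:
        label = "marginal"
    dominant = lam[lam.real >= max_real - eps]
    mode = "oscillatory" if np.any(np.abs(dominant.imag) > eps) else "non_oscillatory"
    return StabilityReport(label, mode, max_real)


def doubling_time(growth_rate: float) -> float:
    """Amplitude doubling time ln(2)/r (days) of a mode growing at rate r."""
    if growth_rate <= 0:
        raise ValueError("doubling time is defined for positive growth rates")
    return float(np.log(2.0) / growth_rate)
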