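"""In silico combination-treatment search for the ALS gain matrix.

Two complementary strategies:

* **Factor treatments** multiply the states of three chosen factors at
  the presymptomatic / symptomatic / post-symptomatic intervention days
  (1, 109, 125).  The nine multipliers (3 factors x 3 days), bounded by
  the effect size e to [1-e, 1+e], are optimised by differential
  evolution against a wild-type reference trajectory using a log-cosh
  fitness over days 140-200.
* **Gain treatments** modulate gain-matrix entries directly: a one-way
  treatment targets one diagonal entry, a two-way treatment the
  symmetric off-diagonal pair {(i,j),(j,i)}.  Entries are bounded to
  c-fold the original magnitude (c = 5, 10, 15) and DE minimises the
  spectral abscissa max Re(lambda); the treatment stabilises iff the
  minimum is negative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .dynamics import Trajectory, simulate
from .ontology import FACTORS, GainMatrix

__all__ = [
    "DEConfig",
    "FactorTreatment",
    "GainTreatment",
    "TreatmentResult",
    "INTERVENTION_DAYS",
    "FITNESS_WINDOW",
    "DEFAULT_EFFECT_SIZES",
    "DEFAULT_GAIN_CAPS",
    "enumerate_factor_triples",
    "logcosh_fitness",
    "simulate_with_factor_treatment",
    "de_optimize_factor_treatment",
    "screen_factor_treatments",
    "rank_factor_treatments",
    "factor_frequency_top_k",
    "enumerate_gain_treatments",
    "de_optimize_gain_treatment",
    "evaluate_gain_treatments",
    "count_stable_gain_treatments",
]

#: Presymptomatic, symptomatic and post-symptomatic intervention days.
INTERVENTION_DAYS: tuple[int, ...] = (1, 109, 125)

#: Day window over which treated trajectories are scored against WT.
FITNESS_WINDOW: tuple[float, float] = (140.0, 200.0)

#: The five factor-treatment effect sizes (fractional modulation bounds).
DEFAULT_EFFECT_SIZES: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00, 1.25)

#: Gain-treatment maximum effect caps (fold modulation of |g0|).
DEFAULT_GAIN_CAPS: tuple[float, ...] = (5.0, 10.0, 15.0)


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution knobs (scipy rand/1/bin engine)."""

    popsize: int = 15
    maxiter: int = 200
    tol: float = 1e-8
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    polish: bool = True


@dataclass
class FactorTreatment:
    """Three factors modulated multiplicatively at the intervention days.

    ``multipliers[d, k]`` scales the state of the k-th treated factor at
    the d-th intervention day; all multipliers lie in [1-e, 1+e] for
    effect size e.
    """

    factors: tuple
    effect_size: float
    intervention_days: tuple[int, ...] = INTERVENTION_DAYS
    multipliers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        if len(set(self.factors)) != 3:
            raise ValueError("a factor treatment targets exactly 3 distinct factors")
        if not 0 < self.effect_size <= 1.5:
            raise ValueError("effect_size must lie in (0, 1.5]")
        if self.multipliers is None:
            self.multipliers = np.ones((len(self.intervention_days), 3))
        else:
            self.multipliers = np.asarray(self.multipliers, dtype=float)
            lo, hi = 1 - self.effect_size, 1 + self.effect_size
            if self.multipliers.shape != (len(self.intervention_days), 3):
                raise ValueError("multipliers must be (n_days, 3)")
            if np.any(self.multipliers < lo - 1e-9) or np.any(self.multipliers > hi + 1e-9):
                raise ValueError(f"multipliers must lie in [{lo}, {hi}]")


@dataclass
class GainTreatment:
    """One-way (diagonal) or two-way (off-diagonal pair) gain modulation."""

    kind: str  # "one_way" | "two_way"
    entries: tuple[tuple[int, int], ...]
    max_effect: float = 5.0
    modulated_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "one_way":
            if len(self.entries) != 1 or self.entries[0][0] != self.entries[0][1]:
                raise ValueError("one_way treatment targets a single diagonal entry")
        elif self.kind == "two_way":
            if len(self.entries) != 2:
                raise ValueError("two_way treatment targets exactly two entries")
            (i, j), (j2, i2) = self.entries
            if i == j or (i, j) != (i2, j2):
                raise ValueError("two_way entries must be the pair (i,j),(j,i), i != j")
        else:
            raise ValueError(f"unknown treatment kind {self.kind!r}")


@dataclass
class TreatmentResult:
    """Outcome of one optimised treatment.

    ``fitness`` is the log-cosh score (factor treatments);
    ``max_real_eig`` the minimised spectral abscissa (gain treatments).
    ``improvement_ratio`` is untreated fitness / treated fitness.
    """

    treatment: FactorTreatment | GainTreatment
    stable: bool
    fitness: float | None = None
    untreated_fitness: float | None = None
    improvement_ratio: float | None = None
    max_real_eig: float | None = None
    converged: bool = True
    feasible: bool = True
    message: str = ""


# --------------------------------------------------------------------------
# factor treatments
# --------------------------------------------------------------------------

def enumerate_factor_triples(factors: Sequence = FACTORS) -> list[tuple]:
    """All unordered 3-subsets of the factors, lexicographic by index."""
    return list(itertools.combinations(factors, 3))


def _log_cosh(y: np.ndarray) -> np.ndarray:
    # log(cosh(y)) = |y| + log1p(exp(-2|y|)) - log 2, overflow-safe
    a = np.abs(y)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


def logcosh_fitness(
    treated: Trajectory,
    wt_ref: Trajectory,
    window: tuple[float, float] = FITNESS_WINDOW,
) -> float:
    """Mean log-cosh deviation from the WT reference over the fitness window.

    Zero iff the trajectories agree on the window; symmetric in its
    arguments (log cosh is even).
    """
    a = treated.window(*window)
    b = wt_ref.window(*window)
    if len(a.days) != len(b.days) or not np.allclose(a.days, b.days, atol=1e-9):
        raise ValueError("trajectories are not on the same day grid over the window")
    if len(a.days) == 0:
        raise ValueError(f"trajectories do not cover the window {window}")
    return float(np.mean(_log_cosh(a.states - b.states)))


def simulate_with_factor_treatment(
    G_als: GainMatrix | np.ndarray,
    treatment: FactorTreatment,
    t_end: float = 200.0,
    dt: float = 1.0,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Euler integration with state multipliers applied at intervention days.

    At each intervention day the treated factors' current states are
    multiplied by the treatment's multipliers before the next Euler step,
    so an intervention cannot affect states before its own day.
    """
    A = G_als.require_complete() if isinstance(G_als, GainMatrix) else np.asarray(G_als, float)
    n = A.shape[0]
    x = np.ones(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    f_idx = np.array([f.index if hasattr(f, "index") else int(f) for f in treatment.factors])

    total_steps = int(np.round(t_end / dt))
    first_kept = int(np.ceil(1.0 / dt - 1e-9))
    days = dt * np.arange(first_kept, total_steps + 1)
    states = np.empty((len(days), n))
    stepper = np.eye(n) + dt * A
    # map each intervention day to the first grid step at/after it
    pending = {
        int(np.ceil(day / dt - 1e-9)): treatment.multipliers[d]
        for d, day in enumerate(treatment.intervention_days)
    }
    diverged_day = None
    kept = 0
    for k in range(1, total_steps + 1):
        x = stepper @ x
        if k in pending:  # modulate the factor values reached at this day
            x[f_idx] = x[f_idx] * pending[k]
        if k >= first_kept:
            states[kept] = x
            kept += 1
            if np.max(np.abs(x)) > 1e12:
                diverged_day = float(dt * k)
                days = days[:kept]
                states = states[:kept]
                break
    mask = days >= 55.0
    return Trajectory(days, states, mask, diverged_day)


def de_optimize_factor_treatment(
    G_als: GainMatrix | np.ndarray,
    triple: tuple,
    effect_size: float,
    wt_ref: Trajectory,
    config: DEConfig | None = None,
    seed: int = 0,
    t_end: float = 200.0,
    dt: float = 1.0,
) -> TreatmentResult:
    """Optimise the nine multipliers of one factor triple by DE.

    The identity treatment (all multipliers 1) is always inside the
    bounds and is seeded into the initial population, so the optimised
    fitness never exceeds the untreated fitness.
    """
    config = config or DEConfig()
    n_days = len(INTERVENTION_DAYS)
    d = n_days * 3

    untreated = simulate(G_als, t_end=t_end, dt=dt)
    untreated_fit = logcosh_fitness(untreated, wt_ref)

    def objective(theta: np.ndarray) -> float:
        tr = FactorTreatment(triple, effect_size, multipliers=theta.reshape(n_days, 3))
        traj = simulate_with_factor_treatment(G_als, tr, t_end=t_end, dt=dt)
        if traj.diverged:
            return 1e12
        try:
            return logcosh_fitness(traj, wt_ref)
        except ValueError:
            return 1e12

    if effect_size < 1e-12:
        best_theta, best_fit, converged = np.ones(d), untreated_fit, True
    else:
        lo, hi = 1 - effect_size, 1 + effect_size
        res = differential_evolution(
            objective,
            bounds=[(lo, hi)] * d,
            x0=np.ones(d),
            seed=seed,
            popsize=config.popsize,
            maxiter=config.maxiter,
            tol=config.tol,
            mutation=config.mutation,
            recombination=config.recombination,
            polish=config.polish,
        )
        best_theta, best_fit, converged = res.x, float(res.fun), bool(res.success)
        if untreated_fit < best_fit:  # identity is feasible; never do worse
            best_theta, best_fit = np.ones(d), untreated_fit

    treatment = FactorTreatment(
        triple, max(effect_size, 1e-12), multipliers=best_theta.reshape(n_days, 3)
    )
    ratio = untreated_fit / best_fit if best_fit > 0 else np.inf
    return TreatmentResult(
        treatment=treatment,
        stable=bool(best_fit < untreated_fit),
        fitness=best_fit,
        untreated_fitness=untreated_fit,
        improvement_ratio=float(ratio),
        converged=converged,
        message="" if converged else "DE did not converge; best found returned",
    )


def screen_factor_treatments(
    G_als: GainMatrix | np.ndarray,
    wt_ref: Trajectory,
    triples: Iterable[tuple] | None = None,
    effect_sizes: Sequence[float] = DEFAULT_EFFECT_SIZES,
    config: DEConfig | None = None,
    seed: int = 0,
    t_end: float = 200.0,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Fitness table: one row per triple, one column per effect size."""
    triples = list(triples) if triples is not None else enumerate_factor_triples()
    rows = {}
    for t_i, triple in enumerate(triples):
        key = _triple_key(triple)
        rows[key] = {}
        for e_i, e in enumerate(effect_sizes):
            res = de_optimize_factor_treatment(
                G_als, triple, e, wt_ref, config,
                seed=seed + 1000 * t_i + e_i, t_end=t_end, dt=dt,
            )
            rows[key][e] = res.fitness
    df = pd.DataFrame(rows).T
    df.index.name = "triple"
    return df


def _triple_key(triple: tuple) -> str:
    names = [f.name if hasattr(f, "name") else str(f) for f in triple]
    return "+".join(names)


def rank_factor_treatments(fitness_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate ranking: rank per effect size, order by rank sum.

    Within each effect size treatments are ranked by fitness ascending
    (ties get the mean rank).  The final order is by rank sum ascending,
    ties broken lexicographically by triple key.
    """
    if fitness_table.isna().any().any():
        raise ValueError("fitness table has missing cells; evaluate all triples first")
    ranks = fitness_table.rank(axis=0, method="average")
    out = ranks.add_prefix("rank_es_")
    out["rank_sum"] = ranks.sum(axis=1)
    order = np.lexsort((out.index.to_numpy().astype(str), out["rank_sum"].to_numpy()))
    out = out.iloc[order]
    out["aggregate_rank"] = np.arange(1, len(out) + 1)
    return out


def factor_frequency_top_k(ranking: pd.DataFrame, k: int = 30) -> pd.DataFrame:
    """Membership counts of each factor among the top-k ranked triples."""
    if len(ranking) < k:
        raise ValueError(f"ranking has {len(ranking)} rows, need at least {k}")
    counts = {f.name: 0 for f in FACTORS}
    for key in ranking.index[:k]:
        for name in str(key).split("+"):
            counts[name] = counts.get(name, 0) + 1
    df = pd.DataFrame({"count": pd.Series(counts)})
    df["share"] = df["count"] / (3 * k)
    return df


# --------------------------------------------------------------------------
# gain treatments
# --------------------------------------------------------------------------

def enumerate_gain_treatments(n: int = len(FACTORS)) -> list[GainTreatment]:
    """The 14 one-way plus C(14,2)=91 two-way candidate templates."""
    out = [GainTreatment("one_way", ((i, i),)) for i in range(n)]
    out += [
        GainTreatment("two_way", ((i, j), (j, i)))
        for i, j in itertools.combinations(range(n), 2)
    ]
    return out


def de_optimize_gain_treatment(
    G_als: GainMatrix | np.ndarray,
    template: GainTreatment,
    max_effect: float,
    config: DEConfig | None = None,
    seed: int = 0,
    x0_init: np.ndarray | None = None,
) -> TreatmentResult:
    """Minimise max Re(lambda) over the template's entries by DE.

    Entry (i,j) with original value g0 is bounded to
    [-c|g0|, +c|g0|] for cap c (sign reversal permitted).  A zero
    original value degenerates the bounds to {0}: the treatment is
    reported infeasible.  ``x0_init`` warm-starts the DE population
    (used to realise exact stability nesting across caps).
    """
    config = config or DEConfig()
    A = G_als.require_complete() if isinstance(G_als, GainMatrix) else np.asarray(G_als, float)
    entries = template.entries
    g0 = np.array([A[i, j] for i, j in entries])
    if np.any(g0 == 0):
        return TreatmentResult(
            treatment=GainTreatment(template.kind, entries, max_effect),
            stable=False,
            max_real_eig=float(np.max(np.linalg.eigvals(A).real)),
            feasible=False,
            message="zero baseline gain: modulation bounds are degenerate",
        )
    bounds = [(-max_effect * abs(g), max_effect * abs(g)) for g in g0]

    def objective(theta: np.ndarray) -> float:
        M = A.copy()
        for (i, j), v in zip(entries, theta):
            M[i, j] = v
        return float(np.max(np.linalg.eigvals(M).real))

    x0 = np.clip(x0_init if x0_init is not None else g0,
                 [b[0] for b in bounds], [b[1] for b in bounds])
    res = differential_evolution(
        objective,
        bounds=bounds,
        x0=x0,
        seed=seed,
        popsize=config.popsize,
        maxiter=config.maxiter,
        tol=config.tol,
        mutation=config.mutation,
        recombination=config.recombination,
        polish=config.polish,
    )
    best = min(float(res.fun), objective(x0))
    best_x = res.x if float(res.fun) <= objective(x0) else x0
    treatment = GainTreatment(template.kind, entries, max_effect, np.asarray(best_x))
    return TreatmentResult(
        treatment=treatment,
        stable=bool(best < 0),
        max_real_eig=best,
        converged=bool(res.success),
        message="" if res.success else "DE did not converge; best found returned",
    )


def evaluate_gain_treatments(
    G_als: GainMatrix | np.ndarray,
    caps: Sequence[float] = DEFAULT_GAIN_CAPS,
    config: DEConfig | None = None,
    seed: int = 0,
) -> dict[float, list[TreatmentResult]]:
    """Optimise every candidate template at every effect cap.

    Caps are processed in increasing order and each larger cap's DE is
    warm-started from the smaller cap's optimum (whose bounds nest inside
    the larger ones), so any template stable at a smaller cap is stable
    at every larger cap — the search-space inclusion property holds
    exactly.
    """
    templates = enumerate_gain_treatments()
    caps = sorted(caps)
    results: dict[float, list[TreatmentResult]] = {c: [] for c in caps}
    for t_i, template in enumerate(templates):
        warm = None
        for c in caps:
            res = de_optimize_gain_treatment(
                G_als, template, c, config, seed=seed + 97 * t_i, x0_init=warm
            )
            if res.feasible:
                warm = res.treatment.modulated_values
            results[c].append(res)
    return results


def count_stable_gain_treatments(
    results: dict[float, list[TreatmentResult]]
) -> dict[float, int]:
    """Number of stabilising templates per effect cap (non-decreasing in cap)."""
    return {c: sum(r.stable for r in rs) for c, rs in sorted(results.items())}
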