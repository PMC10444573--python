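"""Elitist evolutionary fitting of the reduced model's native parameters.

The algorithm matches, condition by pump-maximum condition, the burst
duration, interburst interval and the extrema of the voltage and [Na+]_i
waveforms between a target set and the simulated model, using a sum of
squared differences in which the paired peak/trough terms are averaged.
Each generation consists of mutants of the single best individual (noise
with standard deviation 2.5% of each parameter value); the best-ever
individual is retained, so the best cost never increases.  The
dynamic-clamp (injected) current parameters are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reduced_model import ReducedModelParams, measure_2d_cycle, simulate_2d

__all__ = [
    "ConditionSummary", "FitTarget", "Individual", "EAConfig",
    "DEFAULT_OPT_PARAMS", "cost", "mutate", "evolve",
    "summarize_condition", "target_from_params",
]

#: Native-current parameters targeted by the optimizer: leak components,
#: h-, fast-Na+-, native-persistent-Na+- and persistent-K+-current maximal
#: conductances, and the half-activation/steepness of the native persistent
#: Na+ and persistent K+ activations.
DEFAULT_OPT_PARAMS = (
    "g_leak_na", "g_leak_k", "g_h", "g_naf", "g_nap_native",
    "b_nap_native", "a_nap_native", "g_k2", "b_k2",
)

_POSITIVE = ("g_leak_na", "g_leak_k", "g_h", "g_naf", "g_nap_native", "g_k2")


@dataclass
class ConditionSummary:
    """Waveform summary of one pump-maximum condition."""

    bd: float
    ibi: float
    v_peak: float
    v_trough: float
    na_peak: float
    na_trough: float


@dataclass
class FitTarget:
    """Target summaries keyed by pump maximum (nA)."""

    conditions: dict  # {ipump_max: ConditionSummary}

    def __post_init__(self):
        for imax, c in self.conditions.items():
            if c.bd <= 0 or c.ibi <= 0:
                raise ValueError(f"non-positive duration at imax={imax}")
            if c.v_peak <= c.v_trough or c.na_peak <= c.na_trough:
                raise ValueError(f"peak below trough at imax={imax}")


@dataclass
class Individual:
    values: dict          # parameter name -> value
    cost: float = np.inf

    def apply(self, base: ReducedModelParams) -> ReducedModelParams:
        return base.with_(**self.values)


@dataclass
class EAConfig:
    pop_size: int = 16
    generations: int = 100
    mutation_scale: float = 0.025
    seed: int = 0
    early_stop_gens: int = 15
    early_stop_tol: float = 1e-6
    sim_duration: float = 40.0
    sim_transient: float = 15.0
    sim_method: str = "rk4"
    param_names: tuple = DEFAULT_OPT_PARAMS

    def __post_init__(self):
        if self.pop_size < 2 or self.generations < 1:
            raise ValueError("need pop_size >= 2 and generations >= 1")
        if self.mutation_scale <= 0:
            raise ValueError("mutation_scale must be positive")


def cost(simulated: dict, target: FitTarget) -> float:
    """Sum over conditions of squared timing and averaged extrema mismatches.

    Units are mixed (s^2, V^2, M^2) and summed with unit weights, as the
    cost is defined.
    """
    if set(simulated) != set(target.conditions):
        raise ValueError("simulated and target condition sets differ")
    total = 0.0
    for imax, tgt in target.conditions.items():
        sim = simulated[imax]
        total += (tgt.bd - sim.bd) ** 2
        total += (tgt.ibi - sim.ibi) ** 2
        total += ((tgt.v_peak - sim.v_peak) ** 2
                  + (tgt.v_trough - sim.v_trough) ** 2) / 2.0
        total += ((tgt.na_peak - sim.na_peak) ** 2
                  + (tgt.na_trough - sim.na_trough) ** 2) / 2.0
    return total


def mutate(parent: Individual, scale: float, rng: np.random.Generator) -> Individual:
    """Gaussian perturbation, SD = ``scale`` times each parameter magnitude.

    Conductance proposals are resampled until positive.
    """
    child = {}
    for name, value in parent.values.items():
        sd = scale * abs(value)
        new = rng.normal(value, sd)
        if name in _POSITIVE:
            while new <= 0.0:
                new = rng.normal(value, sd)
        child[name] = float(new)
    return Individual(child)


def summarize_condition(params: ReducedModelParams, ipump_max: float,
                        duration: float = 40.0,
                        transient: float = 15.0,
                        method: str = "lsoda") -> ConditionSummary:
    """Simulate one condition and summarize its steady oscillation."""
    trace = simulate_2d(params.with_(ipump_max=float(ipump_max)), duration,
                        method=method)
    cyc = measure_2d_cycle(trace, transient=transient)
    return ConditionSummary(
        bd=cyc.bd, ibi=cyc.ibi,
        v_peak=cyc.v_peak, v_trough=cyc.v_trough,
        na_peak=cyc.na_peak, na_trough=cyc.na_trough,
    )


def target_from_params(params: ReducedModelParams, imax_list,
                       duration: float = 40.0,
                       transient: float = 15.0,
                       method: str = "rk4") -> FitTarget:
    """Self-generated target: summaries of the model itself per condition."""
    return FitTarget({
        float(imax): summarize_condition(params, imax, duration, transient,
                                         method)
        for imax in imax_list
    })


def _evaluate(ind: Individual, base: ReducedModelParams, target: FitTarget,
              cfg: EAConfig) -> float:
    try:
        params = ind.apply(base)
        sims = {
            imax: summarize_condition(params, imax, cfg.sim_duration,
                                      cfg.sim_transient, cfg.sim_method)
            for imax in target.conditions
        }
        return cost(sims, target)
    except (RuntimeError, ValueError, FloatingPointError):
        return np.inf


@dataclass
class FitResult:
    best: Individual
    history: np.ndarray   # best-ever cost per generation (non-increasing)
    n_generations: int
    config: EAConfig = field(repr=False, default=None)


def evolve(target: FitTarget, base: ReducedModelParams,
           config: EAConfig | None = None) -> FitResult:
    """Run the elitist evolutionary fit; fully reproducible given the seed."""
    cfg = config or EAConfig()
    rng = np.random.default_rng(cfg.seed)
    parent = Individual({n: float(getattr(base, n)) for n in cfg.param_names})
    parent.cost = _evaluate(parent, base, target, cfg)
    best = parent
    history = []
    stalled = 0
    for gen in range(cfg.generations):
        population = [mutate(best, cfg.mutation_scale, rng)
                      for _ in range(cfg.pop_size)]
        for ind in population:
            ind.cost = _evaluate(ind, base, target, cfg)
        gen_best = min(population, key=lambda i: i.cost)
        if gen_best.cost < best.cost - cfg.early_stop_tol:
            stalled = 0
        else:
            stalled += 1
        if gen_best.cost < best.cost:
            best = gen_best
        history.append(best.cost)
        if stalled >= cfg.early_stop_gens:
            break
    return FitResult(best=best, history=np.asarray(history),
                     n_generations=len(history), config=cfg)
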