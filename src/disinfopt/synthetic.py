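"""Synthetic disinfection experiments with a known ground-truth surface.

The generator draws per-replicate contamination counts from a binomial
dose-response model: each of the ``seeds_per_rep`` seeds in a replicate
stays contaminated with probability

    p(x) = p0 * exp(-(alpha * naocl + beta * h2o2) * time**gamma),

first-order kill kinetics in dose × time.  Defaults mimic the observed
kill pattern of the packaged experiment — an untreated control at 100 %
contamination, NaOCl clearing contamination at ~5 % by 15 min, H2O2 only
weakly effective at up to 30 % — so that model fitting and optimization
can be tested against a surface whose true minimum is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import (
    ExperimentTable,
    ReplicateObservation,
    Treatment,
    TreatmentSummary,
    replicate_mean_se,
)
from .ga import GAConfig, run_ga
from .grnn import fit_grnn

__all__ = ["SurfaceParams", "Design", "contamination_probability",
           "simulate_experiment", "recover_optimum_check", "table1_design"]


@dataclass(frozen=True)
class SurfaceParams:
    """Ground-truth contamination surface parameters.

    baseline_contamination: probability an untreated seed is contaminated.
    potency_naocl / potency_h2o2: kill rates per (% · min); NaOCl is the
    stronger agent by default.  time_exponent shapes the time response
    (1 = first-order kinetics).
    """

    baseline_contamination: float = 1.0
    potency_naocl: float = 0.035
    potency_h2o2: float = 0.0005
    time_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_contamination <= 1:
            raise ValueError("baseline_contamination must be in [0, 1]")
        if self.potency_naocl < 0 or self.potency_h2o2 < 0:
            raise ValueError("potencies must be >= 0")
        if self.time_exponent < 0:
            raise ValueError("time_exponent must be >= 0")


@dataclass(frozen=True)
class Design:
    """A factorial design: treatments × replicates of seeds."""

    treatments: tuple[Treatment, ...]
    n_reps: int = 3
    seeds_per_rep: int = 5


def table1_design() -> Design:
    """The 19-treatment layout of the packaged experiment."""
    from .dataset import load_table1

    return Design(tuple(s.treatment for s in load_table1()))


def contamination_probability(treatment: Treatment, params: SurfaceParams) -> float:
    """True per-seed contamination probability under the kill-kinetics model."""
    dose = (params.potency_naocl * treatment.naocl
            + params.potency_h2o2 * treatment.h2o2)
    t = float(treatment.time) ** params.time_exponent if treatment.time > 0 else (
        1.0 if params.time_exponent == 0 else 0.0)
    # time = 0 contributes no exposure (t^gamma = 0 for gamma > 0)
    p = params.baseline_contamination * np.exp(-dose * t)
    return float(np.clip(p, 0.0, 1.0))


def simulate_experiment(
    design: Design, params: SurfaceParams
) -> tuple[ExperimentTable, list[ReplicateObservation]]:
    """Draw a full experiment; replicate % = 100/seeds × Binomial(seeds, p).

    Summaries use the same mean/SE conventions as the dataset module, so
    generated tables round-trip through replicate reconstruction.
    Deterministic per ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    step = 100.0 / design.seeds_per_rep
    summaries: list[TreatmentSummary] = []
    observations: list[ReplicateObservation] = []
    for t in design.treatments:
        p = contamination_probability(t, params)
        counts = rng.binomial(design.seeds_per_rep, p, size=design.n_reps)
        values = [step * int(c) for c in counts]
        observations.extend(ReplicateObservation(t, v) for v in values)
        mean, se = replicate_mean_se(values)
        summaries.append(
            TreatmentSummary(t, round(mean, 1), round(se, 2),
                             n_reps=design.n_reps,
                             seeds_per_rep=design.seeds_per_rep)
        )
    return ExperimentTable(summaries), observations


def _envelope_min_probability(design: Design, params: SurfaceParams,
                              bounds) -> float:
    """Minimum true contamination probability over the search box (grid scan)."""
    grids = [np.linspace(lo, hi, 25) for lo, hi in bounds]
    best = np.inf
    for n in grids[0]:
        for h in grids[1]:
            for t in grids[2]:
                best = min(best, contamination_probability(Treatment(n, h, t), params))
    return float(best)


def recover_optimum_check(
    params: SurfaceParams,
    ga_config: GAConfig,
    design: Design | None = None,
    tolerance: float = 0.02,
) -> tuple[bool, dict]:
    """End-to-end harness: simulate → fit GRNN → GA → check the optimum.

    Succeeds iff the true contamination probability at the GA optimum is
    within ``tolerance`` of the minimum achievable over the search box.
    Returns (success, report).
    """
    if design is None:
        design = table1_design()
    _, observations = simulate_experiment(design, params)
    model = fit_grnn(observations)
    result = run_ga(lambda X: model.predict(X), ga_config)
    opt = Treatment(*np.clip(result.best, 0, None))
    true_p = contamination_probability(opt, params)
    env_min = _envelope_min_probability(design, params, ga_config.bounds)
    success = true_p <= env_min + tolerance
    report = {
        "optimum": result.best.tolist(),
        "predicted_contamination_pct": result.best_objective,
        "true_probability_at_optimum": true_p,
        "envelope_min_probability": env_min,
        "tolerance": tolerance,
        "success": success,
        "sigma": model.sigma,
        "seed": params.seed,
    }
    return success, report
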