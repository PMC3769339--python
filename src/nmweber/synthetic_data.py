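"""Seeded simulation of 2AFC sugar-discrimination experiments.

Generates synthetic data with the statistical structure the analysis
assumes, at two levels of resolution:

* :func:`simulate_performance` draws per-condition binomial choice counts
  whose success probability follows the lapse-aware near-miss Weibull
  psychometric model — the generative model the fitting routines invert.
* :func:`simulate_visits` emits a full visit-level log per session: a
  strictly alternating 100-visit forced-sampling phase (50 visits per
  feeder) followed by free choice visits, with lapses optionally directed
  toward one side to emulate positional bias.

The default experimental design (:func:`default_conditions`) is the
two-group, 15-condition protocol with a 20% w/w standard, every condition
presented twice on consecutive sessions with the feeder sides swapped, and
100 analysed choice visits per presentation (200 per condition).

All randomness flows from the scenario seed through a single
``numpy.random.Generator``; identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .choice_data import ConditionSpec, PerformanceRecord, VisitRecord
from .exceptions import DomainError
from .psychometric import PsychometricParams, predict_performance, sigmoid_core
from .intensity import near_miss_intensity

__all__ = [
    "SimulationScenario",
    "RecoveryReport",
    "SPECIES_PRESETS",
    "default_conditions",
    "session_id",
    "session_condition_map",
    "simulate_performance",
    "simulate_visits",
    "recovery_experiment",
]

# 15-condition sequences of the two subject groups; standard 20% w/w.
_GROUP_SEQUENCES = {
    1: (12.5, 18.6, 25.0, 29.0, 8.0, 21.5, 32.0, 30.0, 13.3, 20.0, 16.0, 50.0, 23.5, 13.8, 17.0),
    2: (20.0, 30.0, 8.0, 18.6, 13.3, 50.0, 16.0, 13.8, 32.0, 29.0, 17.0, 25.0, 23.5, 21.5, 12.5),
}

#: Psychometric parameter tuples for the nectar-feeding taxa whose pooled
#: discrimination data the cross-species analysis covers.  ``m`` and ``s``
#: are on the scaled near-miss intensity axis of each preset's ``scale``.
SPECIES_PRESETS: Mapping[str, PsychometricParams] = {
    "G_soricina": PsychometricParams(m=0.12, s=4.4, lapse=0.11, beta=2.0, scale=10.0),
    "G_commissarisi": PsychometricParams(m=0.14, s=9.7, lapse=0.06, beta=1.4, scale=1.0),
    "Trochilidae": PsychometricParams(m=0.14, s=4.3, lapse=0.19, beta=2.0, scale=10.0),
    "B_impatiens": PsychometricParams(m=0.23, s=4.1, lapse=0.25, beta=0.3, scale=0.1),
    "A_m_ligustica": PsychometricParams(m=0.35, s=1.9, lapse=0.07, beta=0.3, scale=0.1),
}


def default_conditions(group: int = 1) -> list[ConditionSpec]:
    """The 15-condition 2AFC design of subject group 1 or 2.

    Test concentrations are symmetric around the 20% w/w standard in
    relative intensity; both groups use the same condition multiset in a
    different order.  Each condition is presented twice with the test-feeder
    side swapped between presentations; starting sides alternate along the
    sequence so left and right starts are balanced.
    """
    if group not in _GROUP_SEQUENCES:
        raise DomainError(f"unknown group {group}; expected 1 or 2")
    conditions = []
    for idx, test in enumerate(_GROUP_SEQUENCES[group], start=1):
        first = "left" if idx % 2 == 1 else "right"
        second = "right" if first == "left" else "left"
        conditions.append(
            ConditionSpec(
                sequence_index=idx,
                test_conc=test,
                standard_conc=20.0,
                n_presentations=2,
                positions=(first, second),
            )
        )
    return conditions


@dataclass(frozen=True)
class SimulationScenario:
    """A complete specification of one simulated experiment.

    ``position_bias`` shifts lapse visits toward the left feeder: a lapse
    goes left with probability ``0.5 + position_bias``.  Because feeder
    sides are counterbalanced across the two presentations of each
    condition, side-directed lapses still average out to the psychometric
    model's expectation at the condition level.

    ``heterogeneity`` optionally draws per-individual truths by jittering
    m and s on the log scale and the lapse rate on the logit scale
    (``{"log_m_sd", "log_s_sd", "logit_lapse_sd"}``).
    """

    params: PsychometricParams
    conditions: tuple[ConditionSpec, ...] = field(
        default_factory=lambda: tuple(default_conditions(1))
    )
    n_choice_visits: int = 100
    n_individuals: int = 1
    position_bias: float = 0.0
    seed: int = 0
    heterogeneity: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_choice_visits < 1:
            raise DomainError("n_choice_visits must be >= 1")
        if self.n_individuals < 1:
            raise DomainError("n_individuals must be >= 1")
        if not 0.0 <= self.position_bias <= 0.5:
            raise DomainError(f"position_bias {self.position_bias} outside [0, 0.5]")

    def individual_ids(self) -> list[str]:
        return [f"ind{i + 1:02d}" for i in range(self.n_individuals)]

    def individual_params(self) -> dict[str, PsychometricParams]:
        """Per-individual truth parameters (jittered when heterogeneity is on)."""
        ids = self.individual_ids()
        if not self.heterogeneity:
            return {ind: self.params for ind in ids}
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 3]))
        out = {}
        h = self.heterogeneity
        for ind in ids:
            m = self.params.m * math.exp(rng.normal(0.0, h.get("log_m_sd", 0.0)))
            s = self.params.s * math.exp(rng.normal(0.0, h.get("log_s_sd", 0.0)))
            logit = math.log(self.params.lapse / (1 - self.params.lapse)) if self.params.lapse > 0 else -6.0
            lapse = 1.0 / (1.0 + math.exp(-(logit + rng.normal(0.0, h.get("logit_lapse_sd", 0.0)))))
            out[ind] = replace(self.params, m=m, s=s, lapse=min(lapse, 0.499))
        return out


def session_id(individual: str, condition: ConditionSpec, presentation: int) -> str:
    """Deterministic session identifier for one presentation of a condition."""
    return f"{individual}-c{condition.sequence_index:02d}-p{presentation + 1}"


def session_condition_map(scenario: SimulationScenario) -> dict[str, ConditionSpec]:
    """session_id -> ConditionSpec for every session the scenario generates."""
    out = {}
    for ind in scenario.individual_ids():
        for cond in scenario.conditions:
            for pres in range(cond.n_presentations):
                out[session_id(ind, cond, pres)] = cond
    return out


def simulate_performance(scenario: SimulationScenario) -> list[PerformanceRecord]:
    """Per-condition binomial choice counts under the truth parameters.

    For each condition, ``n_total = n_presentations * n_choice_visits``
    choices are drawn with success probability given by the psychometric
    model; with several individuals, counts are per-individual records
    concatenated in individual order (pool them explicitly if desired).
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    truths = scenario.individual_params()
    records = []
    for ind in scenario.individual_ids():
        truth = truths[ind]
        for cond in scenario.conditions:
            p = predict_performance(cond.x, cond.a, truth)
            n_total = cond.n_presentations * scenario.n_choice_visits
            n_high = int(rng.binomial(n_total, p))
            records.append(
                PerformanceRecord(
                    x=cond.x, a=cond.a, n_high=n_high, n_total=n_total,
                    meta={"individual_id": ind, "sequence_index": cond.sequence_index,
                          "true_p": p},
                )
            )
    return records


def simulate_visits(scenario: SimulationScenario) -> list[VisitRecord]:
    """Visit-level log for every individual, condition and presentation.

    Each session holds exactly 100 strictly alternating forced-sampling
    visits (50 per feeder, test feeder first) followed by
    ``n_choice_visits`` free choices.  A choice visit is a lapse with
    probability equal to the truth lapse rate; lapses go to the left feeder
    with probability ``0.5 + position_bias``, other visits follow a
    Bernoulli draw at the lapse-free psychometric probability
    ``0.5 + 0.5 F(i)`` of selecting the higher-concentration feeder.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    truths = scenario.individual_params()
    visits: list[VisitRecord] = []
    for ind in scenario.individual_ids():
        truth = truths[ind]
        t = 0.0
        for cond in scenario.conditions:
            i = near_miss_intensity(cond.x, cond.a, truth.beta, truth.scale)
            p_high_core = 0.5 + 0.5 * sigmoid_core(i, truth.m, truth.s)
            higher_role = cond.higher_role
            for pres in range(cond.n_presentations):
                sid = session_id(ind, cond, pres)
                test_side = cond.positions[pres]
                side_of = {"test": test_side,
                           "standard": "right" if test_side == "left" else "left"}
                role_of_side = {v: k for k, v in side_of.items()}
                # forced alternation: 50 samplings per feeder, test first
                for v in range(100):
                    role = "test" if v % 2 == 0 else "standard"
                    t += 1.0
                    visits.append(VisitRecord(t, ind, sid, "alternation", role, side_of[role]))
                for _ in range(scenario.n_choice_visits):
                    t += 1.0
                    if rng.random() < truth.lapse:
                        side = "left" if rng.random() < 0.5 + scenario.position_bias else "right"
                        role = role_of_side[side]
                    else:
                        goes_high = rng.random() < p_high_core
                        role = higher_role if goes_high else (
                            "standard" if higher_role == "test" else "test"
                        )
                        side = side_of[role]
                    visits.append(VisitRecord(t, ind, sid, "choice", role, side))
    return visits


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate of a repeated simulate-and-refit experiment."""

    estimates: pd.DataFrame  # one row per replicate
    bias: Mapping[str, float]
    rmse: Mapping[str, float]
    beta_ci_coverage: float
    n_weber_preferred: int
    n_near_miss_preferred: int
    n_undecided: int
    n_reps: int
    truth: PsychometricParams

    def to_dict(self) -> dict:
        return {
            "bias": dict(self.bias),
            "rmse": dict(self.rmse),
            "beta_ci_coverage": self.beta_ci_coverage,
            "n_weber_preferred": self.n_weber_preferred,
            "n_near_miss_preferred": self.n_near_miss_preferred,
            "n_undecided": self.n_undecided,
            "n_reps": self.n_reps,
            "truth": {
                "m": self.truth.m, "s": self.truth.s, "lapse": self.truth.lapse,
                "beta": self.truth.beta, "scale": self.truth.scale,
            },
        }


def recovery_experiment(
    truth: PsychometricParams,
    design: Sequence[ConditionSpec] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    n_choice_visits: int = 100,
    delta_aic_rule: float = 2.0,
) -> RecoveryReport:
    """Repeatedly simulate the design under ``truth`` and refit both models.

    Each replicate draws binomial performance data, fits the psychometric
    model with the exponent free and fixed at 1, and runs the nested
    comparison.  The report aggregates per-parameter bias and RMSE of the
    free fit, coverage of the 95% beta confidence interval, and how often
    each model is preferred at the ``|delta AIC| > delta_aic_rule`` rule
    (``delta_aic > rule`` counts for the near-miss model, ``< rule`` for
    Weber's law, per the conventional evidence threshold).
    """
    from .fitting import compare_nested, fit_nls

    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    if design is None:
        design = default_conditions(1)
    rows = []
    covered = 0
    n_ci = 0
    n_weber = n_near = n_und = 0
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31 - 1)
    for rep, rep_seed in enumerate(rep_seeds):
        scenario = SimulationScenario(
            params=truth,
            conditions=tuple(design),
            n_choice_visits=n_choice_visits,
            seed=int(rep_seed),
        )
        records = simulate_performance(scenario)
        free = fit_nls(records, beta_mode="free", scale=truth.scale)
        fixed = fit_nls(records, beta_mode=1.0, scale=truth.scale)
        cmp_ = compare_nested(free, fixed)
        if cmp_.delta_aic > delta_aic_rule:
            n_near += 1
        elif cmp_.delta_aic < delta_aic_rule:
            n_weber += 1
        else:
            n_und += 1
        if free.beta_ci is not None:
            n_ci += 1
            if free.beta_ci[0] <= truth.beta <= free.beta_ci[1]:
                covered += 1
        p = free.params
        rows.append(
            {
                "rep": rep, "seed": int(rep_seed),
                "m": p.m, "s": p.s, "lapse": p.lapse, "beta": p.beta,
                "beta_ci_low": free.beta_ci[0] if free.beta_ci else np.nan,
                "beta_ci_high": free.beta_ci[1] if free.beta_ci else np.nan,
                "rss_free": free.rss, "rss_fixed": fixed.rss,
                "delta_aic": cmp_.delta_aic, "f_stat": cmp_.f_stat,
                "p_value": cmp_.p_value, "converged": free.converged,
            }
        )
    est = pd.DataFrame(rows)
    true_vals = {"m": truth.m, "s": truth.s, "lapse": truth.lapse, "beta": truth.beta}
    bias = {k: float(est[k].mean() - v) for k, v in true_vals.items()}
    rmse = {k: float(np.sqrt(np.mean((est[k] - v) ** 2))) for k, v in true_vals.items()}
    return RecoveryReport(
        estimates=est,
        bias=bias,
        rmse=rmse,
        beta_ci_coverage=covered / n_ci if n_ci else float("nan"),
        n_weber_preferred=n_weber,
        n_near_miss_preferred=n_near,
        n_undecided=n_und,
        n_reps=n_reps,
        truth=truth,
    )
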