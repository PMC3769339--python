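"""High-level workflows: per-individual study analysis and cross-species reanalysis.

Two orchestrated procedures sit on top of the library modules:

``run_individual_analysis``
    For each individual: split its performance records into LOW and HIGH
    sets around the standard concentration, fit the psychometric model per
    set (Bayesian by default), compare the set-wise parameters across
    individuals with paired t tests, and fit the full data by least squares
    with the near-miss exponent fixed at 1 and free, summarising the nested
    comparison per individual.

``run_species_reanalysis``
    For each species' pooled performance table: free-exponent fit with
    confidence interval, assignment of a shared "round" exponent to groups
    whose intervals allow it (threshold and slope are only comparable
    between groups fitted at the same exponent), refit at the assigned
    exponent, and preference-curve extrapolation at chosen standards.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from . import __version__
from .choice_data import PerformanceRecord, split_high_low
from .exceptions import EmptyDataError, NmweberError
from .fitting import (
    PriorSpec,
    compare_nested,
    fit_bayes,
    fit_nls,
    paired_param_test,
)
from .psychometric import preference_curve

__all__ = [
    "StudyConfig",
    "run_individual_analysis",
    "run_species_reanalysis",
    "assign_round_beta",
]

DEFAULT_BETA_CANDIDATES = (0.3, 1.0, 1.4, 2.0)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration shared by the two analysis workflows."""

    standard_conc: float = 20.0
    max_choice_visits: int = 100
    exclusions: tuple[tuple[str, float], ...] = ()  # (individual_id, test_conc)
    beta_mode: str = "both"  # "both", "free", or a fixed value as str
    set_fit_method: Literal["bayes", "nls"] = "bayes"
    set_beta: float = 1.0
    set_scale: float = 1.0
    priors: PriorSpec = field(default_factory=PriorSpec)
    n_samples: int = 5000
    n_burn: int = 1000
    seed: int = 0
    zero_substitute: float | None = None
    beta_candidates: tuple[float, ...] = DEFAULT_BETA_CANDIDATES
    preference_standards: tuple[float, ...] = (10.0, 25.0, 50.0)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _apply_exclusions(
    individual: str,
    records: Sequence[PerformanceRecord],
    config: StudyConfig,
) -> list[PerformanceRecord]:
    """Drop explicitly listed (individual, test concentration) conditions.

    A record's test concentration is whichever of its two concentrations is
    not the standard (the standard itself for the equal pair).  Exclusions
    are always explicit configuration — never automatic outlier hunting.
    """
    out = []
    for rec in records:
        test = rec.x if rec.a == config.standard_conc else rec.a
        if rec.x == rec.a:
            test = config.standard_conc
        if any(ind == individual and abs(t - test) < 1e-9 for ind, t in config.exclusions):
            continue
        out.append(rec)
    return out


def _fit_one_set(
    records: Sequence[PerformanceRecord],
    config: StudyConfig,
    seed: int,
) -> dict:
    """Fit one LOW or HIGH set, returning point estimates plus diagnostics."""
    if config.set_fit_method == "bayes":
        summary = fit_bayes(
            records,
            priors=config.priors,
            n_samples=config.n_samples,
            n_burn=config.n_burn,
            seed=seed,
            beta=config.set_beta,
            scale=config.set_scale,
            zero_substitute=config.zero_substitute,
        )
        return {
            "method": "bayes",
            "m": summary.mean["m"],
            "s": summary.mean["s"],
            "lapse": summary.mean["lapse"],
            "posterior": summary.to_dict(),
        }
    fit = fit_nls(
        records,
        beta_mode=config.set_beta,
        scale=config.set_scale,
        zero_substitute=config.zero_substitute,
    )
    return {
        "method": "nls",
        "m": fit.params.m,
        "s": fit.params.s,
        "lapse": fit.params.lapse,
        "fit": fit.to_dict(),
    }


def run_individual_analysis(
    data: Mapping[str, Sequence[PerformanceRecord]],
    config: StudyConfig | None = None,
) -> dict:
    """Per-individual psychometric workflow over a cohort.

    Parameters
    ----------
    data : mapping
        individual_id -> performance records (all involving the standard).
    config : StudyConfig

    Returns
    -------
    dict with per-individual set fits and model comparisons, cohort-level
    paired t tests on (threshold, slope, lapse) between the LOW and HIGH
    sets, and run metadata.  Individuals whose analysis fails are reported
    under ``errors`` without aborting the rest.
    """
    if config is None:
        config = StudyConfig()
    if not data:
        raise EmptyDataError("no individuals supplied")
    per_individual: dict[str, dict] = {}
    errors: dict[str, str] = {}
    low_params: dict[str, dict] = {}
    high_params: dict[str, dict] = {}
    for idx, (individual, records) in enumerate(sorted(data.items())):
        try:
            records = _apply_exclusions(individual, list(records), config)
            if not records:
                raise EmptyDataError("all records excluded")
            low, high = split_high_low(records, config.standard_conc)
            if not low or not high:
                raise EmptyDataError(
                    f"empty {'LOW' if not low else 'HIGH'} set for {individual}"
                )
            seed_lo = (config.seed * 1000003 + 2 * idx) % (2**31 - 1)
            seed_hi = (config.seed * 1000003 + 2 * idx + 1) % (2**31 - 1)
            low_fit = _fit_one_set(low, config, seed_lo)
            high_fit = _fit_one_set(high, config, seed_hi)
            low_params[individual] = low_fit
            high_params[individual] = high_fit

            entry: dict = {"low": low_fit, "high": high_fit,
                           "n_low": len(low), "n_high_set": len(high)}
            if config.beta_mode in ("both", "free"):
                free = fit_nls(records, beta_mode="free",
                               zero_substitute=config.zero_substitute)
                entry["nls_free"] = free.to_dict()
            if config.beta_mode == "both":
                fixed = fit_nls(records, beta_mode=1.0,
                                zero_substitute=config.zero_substitute)
                entry["nls_weber"] = fixed.to_dict()
                entry["comparison"] = compare_nested(free, fixed).to_dict()
            elif config.beta_mode != "free":
                fixed = fit_nls(records, beta_mode=float(config.beta_mode),
                                zero_substitute=config.zero_substitute)
                entry["nls_fixed"] = fixed.to_dict()
            per_individual[individual] = entry
        except NmweberError as exc:
            errors[individual] = f"{type(exc).__name__}: {exc}"

    paired: dict[str, dict] = {}
    shared = [ind for ind in low_params if ind in high_params]
    if len(shared) >= 2:
        for param in ("m", "s", "lapse"):
            paired[param] = paired_param_test(
                [low_params[ind][param] for ind in shared],
                [high_params[ind][param] for ind in shared],
            )
    betas = [
        per_individual[ind]["nls_free"]["beta"]
        for ind in per_individual
        if "nls_free" in per_individual[ind]
    ]
    return {
        "individuals": per_individual,
        "paired_tests": paired,
        "mean_beta": float(np.mean(betas)) if betas else None,
        "se_beta": float(np.std(betas, ddof=1) / np.sqrt(len(betas))) if len(betas) > 1 else None,
        "errors": errors,
        "meta": _run_meta(config),
    }


def assign_round_beta(
    fits: Mapping[str, dict],
    candidates: Sequence[float] = DEFAULT_BETA_CANDIDATES,
) -> dict:
    """Assign a shared 'round' exponent to groups whose 95% CIs allow it.

    Threshold and slope are only comparable between groups fitted at the
    same exponent, so groups whose confidence intervals all span a common
    candidate value are assigned that value.  When no candidate is shared
    by every group, each group gets the in-CI candidate nearest its point
    estimate.  A group whose CI contains several candidates is flagged as
    ambiguous rather than silently resolved.
    """
    cis = {k: v["beta_ci"] for k, v in fits.items()}
    estimates = {k: v["beta"] for k, v in fits.items()}
    in_ci = {
        k: [c for c in candidates if ci is not None and ci[0] <= c <= ci[1]]
        for k, ci in cis.items()
    }
    shared = [c for c in candidates if all(c in v for v in in_ci.values())]
    assignment: dict[str, float | None] = {}
    ambiguity: dict[str, list[float]] = {}
    if shared:
        # prefer the shared candidate minimising summed distance to estimates
        best = min(shared, key=lambda c: sum(abs(estimates[k] - c) for k in fits))
        assignment = {k: best for k in fits}
        if len(shared) > 1:
            ambiguity["__shared__"] = shared
    else:
        for k in fits:
            if in_ci[k]:
                assignment[k] = min(in_ci[k], key=lambda c: abs(estimates[k] - c))
                if len(in_ci[k]) > 1:
                    ambiguity[k] = in_ci[k]
            else:
                assignment[k] = None
    return {"assignment": assignment, "in_ci": in_ci, "ambiguous": ambiguity}


def run_species_reanalysis(
    data: Mapping[str, Sequence[PerformanceRecord]],
    config: StudyConfig | None = None,
    scales: Mapping[str, float] | None = None,
) -> dict:
    """Cross-species pooled reanalysis.

    Parameters
    ----------
    data : mapping
        species -> pooled performance records.
    config : StudyConfig
    scales : mapping, optional
        species -> intensity display factor used for the refit at the
        assigned exponent (default 1 for every species).
    """
    if config is None:
        config = StudyConfig()
    if not data:
        raise EmptyDataError("no species supplied")
    scales = dict(scales or {})
    species_fits: dict[str, dict] = {}
    errors: dict[str, str] = {}
    for species, records in sorted(data.items()):
        try:
            free = fit_nls(list(records), beta_mode="free",
                           zero_substitute=config.zero_substitute)
            fixed = fit_nls(list(records), beta_mode=1.0,
                            zero_substitute=config.zero_substitute)
            cmp_ = compare_nested(free, fixed)
            species_fits[species] = {
                "beta": free.params.beta,
                "beta_ci": list(free.beta_ci) if free.beta_ci else None,
                "aic": free.aic,
                "delta_aic": cmp_.delta_aic,
                "f_stat": cmp_.f_stat,
                "p_value": cmp_.p_value,
                "free_fit": free.to_dict(),
            }
        except NmweberError as exc:
            errors[species] = f"{type(exc).__name__}: {exc}"

    rounding = assign_round_beta(species_fits, config.beta_candidates) if species_fits else {
        "assignment": {}, "in_ci": {}, "ambiguous": {}}
    refits: dict[str, dict] = {}
    curves: dict[str, dict[str, list]] = {}
    for species, assigned in rounding["assignment"].items():
        if assigned is None:
            errors.setdefault(species, "no candidate exponent inside the 95% CI")
            continue
        scale = scales.get(species, 1.0)
        refit = fit_nls(list(data[species]), beta_mode=assigned, scale=scale,
                        zero_substitute=config.zero_substitute)
        refits[species] = refit.to_dict()
        params = refit.params
        curves[species] = {}
        for std in config.preference_standards:
            grid = np.linspace(max(std / 10.0, 1.0), min(2.0 * std, 70.0), 61)
            table = preference_curve(std, grid, params)
            curves[species][f"standard_{std:g}"] = table.to_dict(orient="list")
    return {
        "species": species_fits,
        "beta_rounding": rounding,
        "refits": refits,
        "preference_curves": curves,
        "errors": errors,
        "meta": _run_meta(config),
    }


def _run_meta(config: StudyConfig) -> dict:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
    }


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a report bundle to deterministic JSON (sorted keys)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
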