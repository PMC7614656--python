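"""Factorial simulation harness and performance measures.

A scenario is one cell of the factorial design {case I, II, III} x
{MCAR, MAR1, MAR2} x {simple, complex}.  For each replicate the harness
generates a calibrated trial, masks z2/z3 under the missingness mechanism,
applies every configured missing-data method, and records the estimate, its
model SE and its CI.  Replicate seeds are spawned from the master seed, so
replicates are independent, reproducible, and safe to parallelize.

Performance measures over N_rep replicates, with Monte Carlo standard errors:

* bias      = mean(est) - true;                   MCSE = empSE / sqrt(N)
* empSE     = SD(est);                            MCSE = empSE / sqrt(2(N-1))
* modSE     = sqrt(mean(se^2));                   MCSE by the delta method
* coverage  = fraction of CIs containing true;    MCSE = sqrt(c(1-c)/N)

Failed replicates (e.g. perfect prediction in a stratified imputation) are
recorded with their failure reason and excluded from the summaries, with
``n_converged`` reported; a method failing in more than 10% of replicates
raises a harness error summarizing the causes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logit

import warnings

from .analysis import METHODS, analyze_with_method
from .composite import complex_composite, simple_composite
from .dgm import DEFAULT_ARM_TARGETS, DEFAULT_PAIRWISE, case_params, simulate_trial
from .errors import CompmiError, DomainError
from .mi import ImputationSpec
from .missingness import PRESETS, apply_missingness

__all__ = ["ScenarioConfig", "run_scenario", "performance", "scenario_grid"]

_DEFINITIONS = {"simple": simple_composite, "complex": complex_composite}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario and its execution profile.

    The default profile (N_rep = 500) is a scaled-down run sized for routine
    verification; the full design uses N_rep = 2000 per scenario.  ``m`` and
    ``burnin`` control the MI methods; the scaled profile uses 8/8 and the
    full profile 25/20 (see the methods documentation).
    """

    case: str = "I"
    mechanism: str = "MCAR"
    definition: str = "simple"
    n_sample: int = 2000
    n_rep: int = 500
    methods: tuple[str, ...] = METHODS
    p_x: float = 0.5
    targets: tuple[float, float] = DEFAULT_ARM_TARGETS
    pairwise: tuple[float, float] = DEFAULT_PAIRWISE
    m: int = 8
    burnin: int = 8
    augment: bool = True
    confidence_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sample < 2 or self.n_rep < 2:
            raise DomainError("n_sample and n_rep must each be at least 2")
        if self.mechanism not in PRESETS:
            raise DomainError(f"unknown mechanism {self.mechanism!r}")
        if self.definition not in _DEFINITIONS:
            raise DomainError(f"unknown definition {self.definition!r}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise DomainError(f"unknown methods {sorted(unknown)}")

    @property
    def true_beta_x(self) -> float:
        """True treatment log odds ratio implied by the arm targets."""
        return float(logit(self.targets[1]) - logit(self.targets[0]))

    @property
    def true_beta_0(self) -> float:
        return float(logit(self.targets[0]))


def run_scenario(config: ScenarioConfig) -> pd.DataFrame:
    """Run all replicates of one scenario; returns a long-format table with
    one row per (replicate, method)."""
    definition = _DEFINITIONS[config.definition]()
    params_ctrl, params_trt = case_params(
        config.case, config.definition, config.targets, config.pairwise
    )
    mech = PRESETS[config.mechanism]
    master = np.random.SeedSequence(config.seed)
    rows = []
    failures: dict[str, list[str]] = {m: [] for m in config.methods}
    for rep, child in enumerate(master.spawn(config.n_rep)):
        trial_seed, mask_seed, mi_seed = child.spawn(3)
        full = simulate_trial(
            config.n_sample, config.p_x, params_ctrl, params_trt,
            config.definition, seed=trial_seed,
        )
        masked = apply_missingness(full, mech, mech, seed=mask_seed)
        for mi_stream, method in zip(mi_seed.spawn(len(config.methods)), config.methods):
            spec = ImputationSpec(
                m=config.m,
                burnin=config.burnin,
                augment=config.augment,
                seed=mi_stream,
            )
            source = full if method == "Full" else masked
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = analyze_with_method(
                        source, definition, method, model="logit", spec=spec,
                        confidence_level=config.confidence_level,
                    )
            except CompmiError as exc:
                failures[method].append(str(exc))
                rows.append(
                    dict(replicate=rep, method=method, estimate=np.nan, se=np.nan,
                         ci_low=np.nan, ci_high=np.nan, n_analyzed=0,
                         error=str(exc))
                )
                continue
            rows.append(
                dict(replicate=rep, method=method, estimate=res.estimate,
                     se=res.se, ci_low=res.ci_low, ci_high=res.ci_high,
                     n_analyzed=res.n_analyzed, error="")
            )
    for method, errs in failures.items():
        if len(errs) > 0.10 * config.n_rep:
            sample = "; ".join(sorted(set(errs))[:3])
            raise CompmiError(
                f"method {method} failed in {len(errs)}/{config.n_rep} "
                f"replicates — systematic failure. Causes include: {sample}"
            )
    return pd.DataFrame(rows)


def performance(results: pd.DataFrame, true_value: float) -> pd.DataFrame:
    """Summarize replicate-level results into per-method performance measures.

    Expects the long-format output of :func:`run_scenario`; non-converged
    replicates (NaN estimates) are excluded per method and counted in
    ``n_converged``.
    """
    summaries = []
    for method, grp in results.groupby("method", sort=False):
        ok = grp.loc[np.isfinite(grp["estimate"])]
        n = len(ok)
        if n < 2:
            raise DomainError(
                f"method {method}: fewer than 2 converged replicates"
            )
        est = ok["estimate"].to_numpy()
        se = ok["se"].to_numpy()
        covered = (ok["ci_low"] <= true_value) & (true_value <= ok["ci_high"])
        bias = est.mean() - true_value
        empse = est.std(ddof=1)
        modse = float(np.sqrt((se**2).mean()))
        cov = float(covered.mean())
        var_of_var = (se**2).var(ddof=1) if n > 1 else np.nan
        summaries.append(
            dict(
                method=method,
                n_converged=n,
                bias=bias,
                bias_mcse=empse / np.sqrt(n),
                empse=empse,
                empse_mcse=empse / np.sqrt(2 * (n - 1)),
                modse=modse,
                modse_mcse=float(np.sqrt(var_of_var / (4 * n * modse**2))),
                coverage=cov,
                coverage_mcse=float(np.sqrt(cov * (1 - cov) / n)),
            )
        )
    return pd.DataFrame(summaries)


def scenario_grid(base: ScenarioConfig) -> list[ScenarioConfig]:
    """The full factorial: 3 cases x 3 mechanisms x 2 definitions, each with
    a distinct seed spawned from the base seed."""
    combos = list(
        itertools.product(("I", "II", "III"), ("MCAR", "MAR1", "MAR2"), ("simple", "complex"))
    )
    seeds = np.random.SeedSequence(base.seed).generate_state(len(combos))
    return [
        replace(base, case=c, mechanism=m, definition=d, seed=int(s) % (2**31))
        for (c, m, d), s in zip(combos, seeds)
    ]
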