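"""Synthetic aggregate trial generator with known ground truth.

Trials are simulated at the individual-patient level and then aggregated,
so the summary-level structure the analysis assumes (change SDs, the
baseline/follow-up correlation, binomial event counts) is emergent rather
than asserted: per patient a correlated (baseline, follow-up) pair is drawn
with correlation ``r_true``, the follow-up mean shifted by the trial
baseline effect ``mu_i`` plus the treatment's basic parameter ``d_k``; the
arm is then summarised by its n, means and SDs exactly as a publication
would report it.  Binary outcomes draw events from
``Binomial(n, expit(mu_i + d_k))``.

:func:`make_base_case_network` emulates the structure of the studied
networks: three two-arm, open-label, 52-week phase-3 trials, each comparing
one weekly LAGH (lonapegsomatropin, somatrogon, somapacitan) with daily
somatropin, with arm sizes matching the published trials (56-132 analysed
patients per arm) and default true effects equal to the published direct
mean differences, so that end-to-end runs resemble the reported analysis.
Optional flags add the two sensitivity-analysis trials (LB03002, and a
second somatrogon trial).  Dropout, dose titration and visit-window jitter
are not simulated.

Every public call takes an explicit seed (or Generator); identical seeds
give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import expit

from .study_data import (
    ANALYSIS_WEEK,
    ArmRecord,
    BinaryArmSummary,
    ContinuousArmSummary,
    REFERENCE_TREATMENT,
    TrialRecord,
)

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TrialSimSpec:
    """Design of one simulated trial.

    ``mu`` is the trial-level expected change in the reference arm (the
    nuisance baseline of the arm-based model); ``sd`` the within-arm SD of
    both the baseline and follow-up measurements; ``baseline_mean`` the
    population mean at baseline; ``p0`` the reference-arm event probability
    for binary outcomes.
    """

    trial_id: str
    treatments: tuple[str, ...]
    n_per_arm: tuple[int, ...]
    mu: float = 0.0
    sd: float = 1.0
    baseline_mean: float = 0.0
    p0: float = 0.05

    def __post_init__(self):
        if len(self.treatments) != len(self.n_per_arm):
            raise ValueError("one n per treatment arm required")
        if len(self.treatments) < 2:
            raise ValueError("a trial needs at least 2 arms")
        if any(n < 1 for n in self.n_per_arm):
            raise ValueError("n must be >= 1 in every arm")
        if not self.sd > 0:
            raise ValueError("sd must be > 0")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Global design: true basic parameters, correlation, trial specs."""

    true_d: Mapping[str, float]
    trials: tuple[TrialSimSpec, ...]
    r_true: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.r_true <= 1.0:
            raise ValueError("|r_true| must be <= 1")


def simulate_continuous_trial(
    spec: TrialSimSpec,
    true_d: Mapping[str, float],
    outcome: str,
    r_true: float = 0.6,
    seed: RngLike = 0,
) -> TrialRecord:
    """Simulate one trial for one continuous outcome (see module docs)."""
    if not -1.0 <= r_true <= 1.0:
        raise ValueError("|r_true| must be <= 1")
    rng = _rng(seed)
    cov = spec.sd**2 * np.array([[1.0, r_true], [r_true, 1.0]])
    chol = np.linalg.cholesky(cov)
    arms = []
    for treat, n in zip(spec.treatments, spec.n_per_arm):
        shift = spec.mu + true_d.get(treat, 0.0)
        z = rng.standard_normal((n, 2)) @ chol.T
        baseline = spec.baseline_mean + z[:, 0]
        followup = spec.baseline_mean + shift + z[:, 1]
        change = followup - baseline
        ddof = 1 if n > 1 else 0
        summary = ContinuousArmSummary(
            n=n,
            baseline_mean=float(baseline.mean()),
            baseline_sd=float(baseline.std(ddof=ddof)) or None,
            followup_mean=float(followup.mean()),
            followup_sd=float(followup.std(ddof=ddof)) or None,
            change_mean=float(change.mean()),
            change_sd=float(change.std(ddof=ddof)) or None,
        )
        arms.append(ArmRecord(treat, {outcome: summary},
                              provenance={outcome: "synthetic"}))
    return TrialRecord(spec.trial_id, ANALYSIS_WEEK, arms)


def simulate_binary_trial(
    spec: TrialSimSpec,
    true_log_or: Mapping[str, float],
    outcome: str = "sae",
    seed: RngLike = 0,
) -> TrialRecord:
    """Simulate one trial for one binary outcome: events ~ Binomial with
    logit(p) = logit(p0) + d_k."""
    rng = _rng(seed)
    base_logit = math.log(spec.p0 / (1.0 - spec.p0))
    arms = []
    for treat, n in zip(spec.treatments, spec.n_per_arm):
        p = float(expit(base_logit + true_log_or.get(treat, 0.0)))
        events = int(rng.binomial(n, p))
        arms.append(ArmRecord(treat, {outcome: BinaryArmSummary(n, events)},
                              provenance={outcome: "synthetic"}))
    return TrialRecord(spec.trial_id, ANALYSIS_WEEK, arms)


def _merge(records: Sequence[TrialRecord]) -> TrialRecord:
    """Merge single-outcome simulations of the same trial design."""
    base = records[0]
    merged = TrialRecord(base.trial_id, base.week,
                         [ArmRecord(a.treatment) for a in base.arms])
    for rec in records:
        for arm in rec.arms:
            target = merged.arm(arm.treatment)
            target.outcomes.update(arm.outcomes)
            target.provenance.update(arm.provenance)
    return merged


# Published direct mean differences vs daily somatropin (the defaults that
# make end-to-end synthetic runs resemble the reported base case); the
# somapacitan values follow from consistency between the published contrasts.
PUBLISHED_EFFECTS: dict[str, dict[str, float]] = {
    "ahv": {"lonapegsomatropin": 0.90, "somatrogon": 0.30,
            "somapacitan": -0.60, "lb03002": 0.40},
    "height_sds": {"lonapegsomatropin": 0.14, "somatrogon": 0.05,
                   "somapacitan": -0.16, "lb03002": 0.05},
    "igf1_sds": {"lonapegsomatropin": 0.86, "somatrogon": 1.57,
                 "somapacitan": 0.03, "lb03002": 0.20},
    "ba_ca_ratio": {"lonapegsomatropin": 0.01, "somatrogon": 0.01,
                    "somapacitan": 0.00, "lb03002": 0.08},
    "sae": {"lonapegsomatropin": 0.0, "somatrogon": 0.0,
            "somapacitan": 0.0, "lb03002": 0.0},
}

_OUTCOME_PARAMS = {
    # outcome: (sd, baseline_mean, reference-arm mu)
    "ahv": (2.2, 0.0, 10.4),
    "height_sds": (0.5, -2.9, 0.95),
    "igf1_sds": (1.0, -2.0, 1.1),
    "ba_ca_ratio": (0.12, 0.65, 0.06),
}

_BASE_DESIGNS = [
    ("thornton2021", ("lonapegsomatropin", REFERENCE_TREATMENT), (105, 56)),
    ("deal2022", ("somatrogon", REFERENCE_TREATMENT), (109, 115)),
    ("miller2022", ("somapacitan", REFERENCE_TREATMENT), (132, 68)),
]
_SA1_DESIGN = ("khadilkar2007", ("lb03002", REFERENCE_TREATMENT), (91, 87))
_SA2_DESIGN = ("horikawa2022", ("somatrogon", REFERENCE_TREATMENT), (22, 22))


def make_base_case_network(
    seed: RngLike = 0,
    sa1: bool = False,
    sa2: bool = False,
    outcomes: Sequence[str] = ("ahv", "height_sds", "igf1_sds",
                               "ba_ca_ratio", "sae"),
    true_effects: Optional[Mapping[str, Mapping[str, float]]] = None,
    r_true: float = 0.6,
) -> list[TrialRecord]:
    """Base-case-shaped star network of synthetic two-arm trials.

    Returns three trials (four with ``sa1`` or ``sa2``) carrying the
    requested outcomes; true contrasts default to the published direct
    estimates (:data:`PUBLISHED_EFFECTS`) and can be overridden per
    outcome.
    """
    rng = _rng(seed)
    effects = dict(PUBLISHED_EFFECTS)
    if true_effects:
        effects.update({k: dict(v) for k, v in true_effects.items()})
    designs = list(_BASE_DESIGNS)
    if sa1:
        designs.append(_SA1_DESIGN)
    if sa2:
        designs.append(_SA2_DESIGN)
    trials = []
    for trial_id, treats, ns in designs:
        parts = []
        for outcome in outcomes:
            if outcome == "sae":
                spec = TrialSimSpec(trial_id, treats, ns, p0=0.05)
                parts.append(simulate_binary_trial(spec, effects["sae"],
                                                   "sae", rng))
            else:
                sd, b0, mu = _OUTCOME_PARAMS[outcome]
                spec = TrialSimSpec(trial_id, treats, ns, mu=mu, sd=sd,
                                    baseline_mean=b0)
                parts.append(simulate_continuous_trial(
                    spec, effects[outcome], outcome, r_true, rng))
        trials.append(_merge(parts))
    return trials


def two_arm_trial_from_direct(
    trial_id: str,
    treatment: str,
    md: float,
    se: float,
    reference: str = REFERENCE_TREATMENT,
    n_per_arm: int = 100,
    baseline: float = 0.0,
    outcome: str = "igf1_sds",
) -> TrialRecord:
    """Deterministic two-arm trial whose sample direct estimate is exact.

    Arm change means are ``baseline + md`` (treatment) and ``baseline``
    (reference); the common change SD is chosen so the mean-difference
    standard error equals ``se``.  Used to rebuild networks from published
    trial-level estimates when arm-level data are unavailable.
    """
    if not se > 0:
        raise ValueError("se must be > 0")
    sd = se / math.sqrt(2.0 / n_per_arm)
    def arm(treat, mean):
        return ArmRecord(treat, {outcome: ContinuousArmSummary(
            n=n_per_arm, change_mean=mean, change_sd=sd)},
            provenance={outcome: "derived"})
    return TrialRecord(trial_id, ANALYSIS_WEEK,
                       [arm(treatment, baseline + md), arm(reference, baseline)])
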