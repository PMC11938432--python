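"""Bayesian fixed-effects network meta-analysis engine.

The model follows the arm-based generalized linear modelling formulation of
evidence synthesis: for arm ``k`` of trial ``i`` with treatment ``t_ik``,

* continuous outcomes (identity link, mean differences)::

      y_ik ~ Normal(mu_i + d[t_ik] - d[t_i1], se_ik^2)

* binary outcomes (logit link, odds ratios)::

      r_ik ~ Binomial(n_ik, p_ik),   logit(p_ik) = mu_i + d[t_ik] - d[t_i1]

with trial baselines ``mu_i`` as nuisance parameters, basic parameters
``d_k`` relative to the network reference (``d[reference] = 0``), and the
consistency assumption that every contrast is a difference of basic
parameters.  Effects are fixed: one true relative effect per contrast, no
between-study heterogeneity.  Priors are vague normals, ``Normal(0, 100^2)``
by default on both ``d_k`` and ``mu_i`` on the model scale.

The public surface is statsmodels-shaped: build a
:class:`NetworkMetaAnalysis` from an evidence network (or directly from
trial records), call :meth:`~NetworkMetaAnalysis.fit`, and read estimates,
credible intervals, rankings and the summary table off the returned
:class:`NMAResults`.  The module-level :func:`fit_continuous`,
:func:`fit_binary`, :func:`summarize` and :func:`frequentist_oracle` expose
the same machinery functionally.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import preprocessing
from ._mcmc import gibbs_continuous, metropolis_binary
from .exceptions import (
    ConvergenceError,
    DisconnectedNetworkError,
    SingularNetworkError,
    ValidationError,
)
from .network import EvidenceNetwork, build_network, connected_components
from .preprocessing import CorrelationEstimate, DirectEstimate
from .study_data import (
    DEFAULT_DIRECTIONS,
    REFERENCE_TREATMENT,
    Scenario,
    TrialRecord,
)

MEAN_DIFFERENCE = "mean-difference"
ODDS_RATIO = "odds-ratio"

#: convergence gate applied after sampling
RHAT_LIMIT = 1.05
ESS_FLOOR = 400.0


@dataclass(frozen=True)
class NmaModelSpec:
    """Likelihood choice, priors and sampler settings for one fit."""

    outcome_kind: str  # "continuous" | "binary"
    effects: str = "fixed"
    prior_sd_d: float = 100.0
    prior_sd_mu: float = 100.0
    chains: int = 4
    iterations: int = 20_000
    burn_in: int = 5_000
    seed: int = 0

    def __post_init__(self):
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.effects != "fixed":
            raise ValueError("only fixed-effects models are supported")
        if not (self.prior_sd_d > 0 and self.prior_sd_mu > 0):
            raise ValueError("prior SDs must be > 0")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("require 0 <= burn_in < iterations")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus per-parameter convergence diagnostics.

    ``d`` has shape ``(chains, kept, K)`` with the reference in column 0
    (identically zero); ``mu`` has shape ``(chains, kept, T)``.
    """

    treatments: tuple[str, ...]
    trial_ids: tuple[str, ...]
    reference: str
    d: np.ndarray
    mu: np.ndarray
    diagnostics: pd.DataFrame
    scale: str = MEAN_DIFFERENCE

    @property
    def stacked_d(self) -> np.ndarray:
        """Draws pooled over chains, shape ``(chains * kept, K)``."""
        return self.d.reshape(-1, self.d.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.d.shape[0] * self.d.shape[1]

    def contrast_draws(self, a: str, b: str) -> np.ndarray:
        """Per-draw ``d_a - d_b`` on the model (linear) scale."""
        ia, ib = self.treatments.index(a.lower()), self.treatments.index(b.lower())
        s = self.stacked_d
        return s[:, ia] - s[:, ib]

    def converged(self, rhat_limit: float = RHAT_LIMIT,
                  ess_floor: float = ESS_FLOOR) -> bool:
        dd = self.diagnostics
        basic = dd[dd["parameter"].str.startswith("d_")]
        return bool((basic["rhat"] <= rhat_limit).all()
                    and (basic["ess"] >= ess_floor).all())


@dataclass(frozen=True)
class EffectEstimate:
    """Posterior median and central 95% credible interval for a contrast."""

    contrast: tuple[str, str]
    scale: str
    point: float
    cri_lower: float
    cri_upper: float

    def __post_init__(self):
        if not self.cri_lower <= self.point <= self.cri_upper:
            raise ValueError("point estimate outside its credible interval")
        if self.scale == ODDS_RATIO and self.cri_lower <= 0:
            raise ValueError("odds-ratio estimates must be strictly positive")

    @property
    def null_value(self) -> float:
        return 1.0 if self.scale == ODDS_RATIO else 0.0

    @property
    def significant(self) -> bool:
        """True iff the 95% CrI excludes the null (0 for MD, 1 for OR)."""
        return not (self.cri_lower <= self.null_value <= self.cri_upper)


def _diagnostics(d: np.ndarray, mu: np.ndarray,
                 treatments: Sequence[str],
                 trial_ids: Sequence[str]) -> pd.DataFrame:
    import arviz as az

    names = [f"d_{t}" for t in treatments[1:]] + [f"mu_{t}" for t in trial_ids]
    stacked = np.concatenate([d[:, :, 1:], mu], axis=2)
    ds = az.convert_to_dataset(stacked)
    rhat = np.atleast_1d(az.rhat(ds)["x"].values)
    ess = np.atleast_1d(az.ess(ds)["x"].values)
    return pd.DataFrame({"parameter": names, "rhat": rhat, "ess": ess})


def _index_arms(data: pd.DataFrame, treatments: Sequence[str],
                reference: str) -> tuple:
    """Map arm rows to integer trial/treatment indices; the baseline
    treatment of a trial is the reference if present, else its first
    treatment in network order."""
    order = {t: i for i, t in enumerate(treatments)}
    trial_ids = list(dict.fromkeys(data["trial_id"]))
    trial_pos = {t: i for i, t in enumerate(trial_ids)}
    trial_idx = data["trial_id"].map(trial_pos).to_numpy()
    treat_idx = data["treatment"].map(order).to_numpy()
    if np.any(pd.isna(treat_idx)):
        bad = sorted(set(data["treatment"]) - set(order))
        raise ValidationError(f"arm treatments not in network: {bad}")
    base_of_trial = np.empty(len(trial_ids), dtype=np.intp)
    for t, i in trial_pos.items():
        arms = treat_idx[trial_idx == i]
        base_of_trial[i] = arms.min()
    return trial_ids, trial_idx, treat_idx.astype(np.intp), base_of_trial


def _check_network(net: EvidenceNetwork) -> None:
    comps = connected_components(net)
    if len(comps) != 1:
        raise DisconnectedNetworkError(
            f"evidence network for {net.outcome!r} has {len(comps)} "
            "components; analysis requires a single connected network"
        )
    if net.reference not in net.nodes:
        raise DisconnectedNetworkError(
            f"reference treatment {net.reference!r} absent from network"
        )


def fit_continuous(net: EvidenceNetwork, data: pd.DataFrame,
                   spec: NmaModelSpec,
                   check_convergence: bool = True) -> PosteriorDraws:
    """Fit the normal identity-link fixed-effects model.

    ``data`` holds one row per arm with columns ``trial_id``, ``treatment``,
    ``y`` (analysed change mean) and ``se`` (its standard error).  Fails
    loudly (:class:`ConvergenceError`) if any basic parameter's split-R-hat
    exceeds 1.05 or its effective sample size falls below 400.
    """
    _check_network(net)
    if (data["se"] <= 0).any():
        raise ValidationError("all arm standard errors must be > 0")
    treatments = net.nodes
    trial_ids, trial_idx, treat_idx, base = _index_arms(data, treatments,
                                                        net.reference)
    d, mu = gibbs_continuous(
        data["y"].to_numpy(), data["se"].to_numpy(),
        trial_idx, treat_idx, base,
        len(trial_ids), len(treatments),
        spec.prior_sd_d, spec.prior_sd_mu,
        spec.chains, spec.iterations, spec.burn_in, spec.seed,
    )
    draws = PosteriorDraws(
        treatments=tuple(treatments), trial_ids=tuple(trial_ids),
        reference=net.reference, d=d, mu=mu,
        diagnostics=_diagnostics(d, mu, treatments, trial_ids),
        scale=MEAN_DIFFERENCE,
    )
    if check_convergence:
        _gate(draws)
    return draws


def fit_binary(net: EvidenceNetwork, data: pd.DataFrame,
               spec: NmaModelSpec,
               check_convergence: bool = True) -> PosteriorDraws:
    """Fit the binomial-logit fixed-effects model (draws on log-odds scale).

    Zero-event arms are handled by the likelihood itself — no continuity
    correction is applied anywhere.
    """
    _check_network(net)
    if (data["events"] > data["n"]).any() or (data["events"] < 0).any():
        raise ValidationError("events must lie in [0, n] for every arm")
    treatments = net.nodes
    trial_ids, trial_idx, treat_idx, base = _index_arms(data, treatments,
                                                        net.reference)
    d, mu = metropolis_binary(
        data["events"].to_numpy(), data["n"].to_numpy(),
        trial_idx, treat_idx, base,
        len(trial_ids), len(treatments),
        spec.prior_sd_d, spec.prior_sd_mu,
        spec.chains, spec.iterations, spec.burn_in, spec.seed,
    )
    draws = PosteriorDraws(
        treatments=tuple(treatments), trial_ids=tuple(trial_ids),
        reference=net.reference, d=d, mu=mu,
        diagnostics=_diagnostics(d, mu, treatments, trial_ids),
        scale=ODDS_RATIO,
    )
    if check_convergence:
        _gate(draws)
    return draws


def _gate(draws: PosteriorDraws) -> None:
    if not draws.converged():
        dd = draws.diagnostics
        basic = dd[dd["parameter"].str.startswith("d_")]
        bad = basic[(basic["rhat"] > RHAT_LIMIT) | (basic["ess"] < ESS_FLOOR)]
        raise ConvergenceError(
            "MCMC failed the convergence gate "
            f"(R-hat <= {RHAT_LIMIT}, ESS >= {ESS_FLOOR}):\n"
            + bad.to_string(index=False)
        )


def summarize(draws: PosteriorDraws,
              scale: Optional[str] = None) -> list[EffectEstimate]:
    """All ordered pairwise contrasts as posterior median + 95% CrI.

    Contrast antisymmetry holds exactly, draw by draw: MD(A,B) = -MD(B,A)
    and OR(A,B) = 1/OR(B,A), because both directions summarise the same
    draws.
    """
    scale = scale or draws.scale
    out = []
    for a in draws.treatments:
        for b in draws.treatments:
            if a == b:
                continue
            x = draws.contrast_draws(a, b)
            lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
            if scale == ODDS_RATIO:
                lo, med, hi = math.exp(lo), math.exp(med), math.exp(hi)
            out.append(EffectEstimate((a, b), scale, float(med),
                                      float(lo), float(hi)))
    return out


@dataclass(frozen=True)
class OracleEstimate:
    contrast: tuple[str, str]
    point: float
    se: float
    lower: float
    upper: float


def frequentist_oracle(
    net_or_treatments,
    direct_estimates: Sequence[DirectEstimate],
    reference: Optional[str] = None,
    level: float = 0.95,
) -> dict[tuple[str, str], OracleEstimate]:
    """Inverse-variance (weighted least squares) network estimator.

    The fixed-effects consistency model on normal direct estimates is a
    linear model in the basic parameters; its WLS solution equals the
    Bayesian posterior in the vague-prior limit, which is what makes this
    an independent validation oracle.  For a star network it reduces to
    ``indirect(A, B) = direct(A, ref) - direct(B, ref)`` with summed
    variances.
    """
    if isinstance(net_or_treatments, EvidenceNetwork):
        treatments = list(net_or_treatments.nodes)
        reference = reference or net_or_treatments.reference
    else:
        treatments = list(net_or_treatments)
        reference = reference or treatments[0]
    free = [t for t in treatments if t != reference]
    pos = {t: i for i, t in enumerate(free)}
    X = np.zeros((len(direct_estimates), len(free)))
    y = np.empty(len(direct_estimates))
    w = np.empty(len(direct_estimates))
    for r, est in enumerate(direct_estimates):
        a, b = est.contrast
        if a != reference:
            X[r, pos[a]] = 1.0
        if b != reference:
            X[r, pos[b]] = -1.0
        y[r] = est.md
        w[r] = 1.0 / est.se**2
    xtwx = (X.T * w) @ X
    if np.linalg.matrix_rank(xtwx) < len(free):
        raise SingularNetworkError(
            "design is rank deficient: some treatments are not identified"
        )
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T * w) @ y
    z = norm.ppf(0.5 + level / 2.0)
    full = dict(zip(free, beta))
    full[reference] = 0.0
    var = {t: cov[pos[t], pos[t]] if t != reference else 0.0 for t in treatments}
    out = {}
    for a in treatments:
        for b in treatments:
            if a == b:
                continue
            point = full[a] - full[b]
            if a == reference or b == reference:
                v = var[a] + var[b]
            else:
                v = (cov[pos[a], pos[a]] + cov[pos[b], pos[b]]
                     - 2.0 * cov[pos[a], pos[b]])
            se = math.sqrt(v)
            out[(a, b)] = OracleEstimate((a, b), point, se,
                                         point - z * se, point + z * se)
    return out


class NetworkMetaAnalysis:
    """Fixed-effects Bayesian NMA model bound to data.

    Parameters
    ----------
    network : EvidenceNetwork
        Connected evidence network containing the reference treatment.
    arm_data : pandas.DataFrame
        One row per arm; ``trial_id``, ``treatment`` plus ``y``/``se``
        (continuous) or ``events``/``n`` (binary).
    outcome_kind : {"continuous", "binary"}
    prior_sd_d, prior_sd_mu : float
        Prior SDs of the basic parameters and trial baselines on the model
        scale (outcome units, or log-odds for binary outcomes).

    Examples
    --------
    >>> from ghnma import datasets, NetworkMetaAnalysis
    >>> trials = datasets.load_base_case()
    >>> model = NetworkMetaAnalysis.from_trials(trials, outcome="igf1_sds")
    >>> res = model.fit(seed=7)          # doctest: +SKIP
    >>> res.effect("somatrogon", "lonapegsomatropin")  # doctest: +SKIP
    """

    def __init__(self, network: EvidenceNetwork, arm_data: pd.DataFrame,
                 outcome_kind: str, prior_sd_d: float = 100.0,
                 prior_sd_mu: float = 100.0):
        _check_network(network)
        self.network = network
        self.arm_data = arm_data.reset_index(drop=True)
        self.outcome_kind = outcome_kind
        self.prior_sd_d = prior_sd_d
        self.prior_sd_mu = prior_sd_mu

    @classmethod
    def from_trials(
        cls,
        trials: Sequence[TrialRecord],
        outcome: str,
        scenario: Optional[Scenario] = None,
        correlation: Optional[CorrelationEstimate] = None,
        reference: str = REFERENCE_TREATMENT,
        **priors,
    ) -> "NetworkMetaAnalysis":
        """Build the model from trial records: construct the evidence
        network for the scenario (default: all supplied trials), then derive
        the arm-level likelihood inputs, imputing change SDs through
        ``correlation`` where needed."""
        if scenario is None:
            scenario = Scenario.custom((t.trial_id for t in trials), "custom")
        net = build_network(trials, outcome, scenario, reference=reference)
        if outcome == "sae":
            table = preprocessing.binary_arm_table(net.trials, outcome)
            kind = "binary"
        else:
            table = preprocessing.continuous_arm_table(net.trials, outcome,
                                                       correlation)
            kind = "continuous"
        model = cls(net, table.data, kind, **priors)
        model.preprocessing_ledger = table.ledger_frame()
        return model

    def fit(self, chains: int = 4, iterations: int = 20_000,
            burn_in: int = 5_000, seed: int = 0,
            check_convergence: bool = True) -> "NMAResults":
        spec = NmaModelSpec(
            outcome_kind=self.outcome_kind,
            prior_sd_d=self.prior_sd_d, prior_sd_mu=self.prior_sd_mu,
            chains=chains, iterations=iterations, burn_in=burn_in, seed=seed,
        )
        fitter = fit_continuous if self.outcome_kind == "continuous" else fit_binary
        draws = fitter(self.network, self.arm_data, spec,
                       check_convergence=check_convergence)
        return NMAResults(self, spec, draws)


class NMAResults:
    """Posterior summaries, diagnostics and rankings of a fitted NMA."""

    def __init__(self, model: NetworkMetaAnalysis, spec: NmaModelSpec,
                 draws: PosteriorDraws):
        self.model = model
        self.spec = spec
        self.draws = draws
        self.treatments = draws.treatments
        self.reference = draws.reference
        self.scale = draws.scale

    # -- estimates ---------------------------------------------------------
    def effect(self, a: str, b: str) -> EffectEstimate:
        """Posterior median + 95% CrI for the contrast A vs B (A minus B on
        the linear scale; A/B as an odds ratio)."""
        a, b = a.lower(), b.lower()
        for t in (a, b):
            if t not in self.treatments:
                raise KeyError(f"unknown treatment {t!r}")
        x = self.draws.contrast_draws(a, b)
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        if self.scale == ODDS_RATIO:
            lo, med, hi = math.exp(lo), math.exp(med), math.exp(hi)
        return EffectEstimate((a, b), self.scale, float(med), float(lo),
                              float(hi))

    def contrasts(self) -> list[EffectEstimate]:
        return summarize(self.draws)

    def vs_reference(self) -> pd.DataFrame:
        rows = []
        for t in self.treatments:
            if t == self.reference:
                continue
            e = self.effect(t, self.reference)
            rows.append({
                "treatment": t, "point": e.point,
                "cri_lower": e.cri_lower, "cri_upper": e.cri_upper,
                "significant": e.significant,
            })
        return pd.DataFrame(rows)

    # -- rankings ----------------------------------------------------------
    def ranking(self, direction: Optional[str] = None):
        from .ranking import RankingResult

        outcome = self.model.network.outcome
        if direction is None:
            direction = DEFAULT_DIRECTIONS.get(outcome, "higher")
        return RankingResult.from_draws(self.draws, direction, outcome=outcome)

    def league_table(self):
        from .reporting import league_table

        return league_table(self)

    # -- diagnostics & reporting ------------------------------------------
    @property
    def diagnostics(self) -> pd.DataFrame:
        return self.draws.diagnostics

    def summary(self) -> str:
        """Human-readable fit summary: model, diagnostics, contrasts vs
        the reference."""
        net = self.model.network
        lines = [
            "Fixed-effects Bayesian network meta-analysis",
            "=" * 52,
            f"Outcome:    {net.outcome}   Scenario: {net.scenario.name}",
            f"Scale:      {self.scale}",
            f"Trials:     {len(net.trials)}   Treatments: {len(self.treatments)}"
            f"   Reference: {self.reference}",
            f"Sampler:    {self.spec.chains} chains x {self.spec.iterations} "
            f"iterations ({self.spec.burn_in} burn-in), seed {self.spec.seed}",
            f"Retained:   {self.draws.n_draws} draws"
            f"   max R-hat {self.diagnostics['rhat'].max():.4f}"
            f"   min ESS {self.diagnostics['ess'].min():.0f}",
            "-" * 52,
            f"{'contrast vs ' + self.reference:<28}{'median':>8}{'2.5%':>8}{'97.5%':>8}",
        ]
        for t in self.treatments:
            if t == self.reference:
                continue
            e = self.effect(t, self.reference)
            star = " *" if e.significant else ""
            lines.append(f"{t:<28}{e.point:>8.3f}{e.cri_lower:>8.3f}"
                         f"{e.cri_upper:>8.3f}{star}")
        lines.append("-" * 52)
        lines.append("* 95% CrI excludes the null "
                     f"({1 if self.scale == ODDS_RATIO else 0})")
        return "\n".join(lines)

    def draws_frame(self) -> pd.DataFrame:
        """One row per retained draw: chain, draw, d_<treatment>..."""
        chains, kept, K = self.draws.d.shape
        idx = pd.MultiIndex.from_product(
            [range(chains), range(kept)], names=["chain", "draw"]
        )
        cols = {f"d_{t}": self.draws.d[:, :, i].ravel()
                for i, t in enumerate(self.treatments)}
        return pd.DataFrame(cols, index=idx).reset_index()

    def save_draws(self, path: Union[str, Path]) -> None:
        self.draws_frame().to_csv(path, index=False)

    def manifest(self, input_files: Sequence[Union[str, Path]] = ()) -> dict:
        """Run manifest: spec echo, seed, diagnostics and input hashes."""
        hashes = {}
        for f in input_files:
            p = Path(f)
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return {
            "outcome": self.model.network.outcome,
            "scenario": self.model.network.scenario.name,
            "spec": {k: getattr(self.spec, k) for k in (
                "outcome_kind", "effects", "prior_sd_d", "prior_sd_mu",
                "chains", "iterations", "burn_in", "seed")},
            "diagnostics": {
                "max_rhat": float(self.diagnostics["rhat"].max()),
                "min_ess": float(self.diagnostics["ess"].min()),
            },
            "input_sha256": hashes,
        }

    def save_manifest(self, path: Union[str, Path],
                      input_files: Sequence[Union[str, Path]] = ()) -> None:
        Path(path).write_text(json.dumps(self.manifest(input_files), indent=2),
                              encoding="utf-8")
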