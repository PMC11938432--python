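"""Report artifacts: league tables, forest-plot data, pipeline driver.

Figures are derived displays only; every table is emitted as data (CSV)
first, and the optional matplotlib rendering is never the source of truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import preprocessing
from .exceptions import ValidationError
from .model import (
    EffectEstimate,
    MEAN_DIFFERENCE,
    NMAResults,
    NetworkMetaAnalysis,
    ODDS_RATIO,
)
from .study_data import (
    DEFAULT_DIRECTIONS,
    OUTCOMES,
    REFERENCE_TREATMENT,
    Scenario,
    read_trials,
    validate_trials,
)
from .synthetic import make_base_case_network

log = logging.getLogger("ghnma")


def flag_significance(est: EffectEstimate) -> bool:
    """True iff the 95% CrI excludes the null (0 for MD, 1 for OR)."""
    return est.significant


@dataclass
class LeagueTable:
    """All pairwise contrasts arranged as a K x K matrix.

    ``points[i, j]`` is the effect of treatment i vs treatment j (MD, or OR
    for binary outcomes), so the table is antisymmetric under transposition:
    points negate on the MD scale and invert on the OR scale.
    """

    treatments: tuple[str, ...]
    scale: str
    points: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def significant(self, a: str, b: str) -> bool:
        i = self.treatments.index(a.lower())
        j = self.treatments.index(b.lower())
        null = 1.0 if self.scale == ODDS_RATIO else 0.0
        return not (self.lower[i, j] <= null <= self.upper[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Display form: diagonal holds treatment names, cells show
        "point (lower, upper)" with a '*' when significant."""
        K = len(self.treatments)
        cells = []
        for i in range(K):
            row = []
            for j in range(K):
                if i == j:
                    row.append(self.treatments[i])
                    continue
                star = "*" if self.significant(self.treatments[i],
                                               self.treatments[j]) else ""
                row.append(f"{self.points[i, j]:.2f} "
                           f"({self.lower[i, j]:.2f}, {self.upper[i, j]:.2f}){star}")
            cells.append(row)
        return pd.DataFrame(cells, columns=self.treatments,
                            index=self.treatments)


def league_table(source: Union[NMAResults, Sequence[EffectEstimate]],
                 treatments: Optional[Sequence[str]] = None) -> LeagueTable:
    """Build the league table from fitted results or a list of estimates."""
    if isinstance(source, NMAResults):
        estimates = source.contrasts()
        treatments = treatments or source.treatments
        scale = source.scale
    else:
        estimates = list(source)
        scale = estimates[0].scale
        if treatments is None:
            treatments = sorted({t for e in estimates for t in e.contrast})
    treatments = tuple(t.lower() for t in treatments)
    K = len(treatments)
    neutral = 1.0 if scale == ODDS_RATIO else 0.0
    points = np.full((K, K), neutral)
    lower = np.full((K, K), neutral)
    upper = np.full((K, K), neutral)
    pos = {t: i for i, t in enumerate(treatments)}
    for e in estimates:
        a, b = e.contrast
        i, j = pos[a], pos[b]
        points[i, j] = e.point
        lower[i, j] = e.cri_lower
        upper[i, j] = e.cri_upper
    return LeagueTable(treatments, scale, points, lower, upper)


def league_table_from_draws_frame(frame: pd.DataFrame,
                                  scale: str = MEAN_DIFFERENCE) -> LeagueTable:
    """Rebuild a league table from an exported draws CSV (columns ``d_*``)."""
    cols = [c for c in frame.columns if c.startswith("d_")]
    treatments = tuple(c[2:] for c in cols)
    d = frame[cols].to_numpy()
    K = len(treatments)
    neutral = 1.0 if scale == ODDS_RATIO else 0.0
    points = np.full((K, K), neutral)
    lower = np.full((K, K), neutral)
    upper = np.full((K, K), neutral)
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            x = d[:, i] - d[:, j]
            lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
            if scale == ODDS_RATIO:
                lo, med, hi = np.exp(lo), np.exp(med), np.exp(hi)
            points[i, j], lower[i, j], upper[i, j] = med, lo, hi
    return LeagueTable(treatments, scale, points, lower, upper)


def forest_data(results: NMAResults) -> pd.DataFrame:
    """Contrast, point and CrI for every comparison vs the reference —
    the data behind a forest plot."""
    rows = []
    for t in results.treatments:
        if t == results.reference:
            continue
        e = results.effect(t, results.reference)
        rows.append({
            "contrast": f"{t} vs {results.reference}",
            "point": e.point, "cri_lower": e.cri_lower,
            "cri_upper": e.cri_upper, "significant": e.significant,
        })
    return pd.DataFrame(rows)


def plot_forest(results: NMAResults, path: Union[str, Path]) -> None:
    """Optional rendered forest plot (derived from :func:`forest_data`)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = forest_data(results)
    fig, ax = plt.subplots(figsize=(6, 0.6 * max(len(df), 2) + 1))
    ypos = np.arange(len(df))[::-1]
    ax.errorbar(df["point"], ypos,
                xerr=[df["point"] - df["cri_lower"],
                      df["cri_upper"] - df["point"]],
                fmt="s", color="black", capsize=3)
    ax.axvline(1.0 if results.scale == ODDS_RATIO else 0.0,
               color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(df["contrast"])
    ax.set_xlabel(results.scale)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_config(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def run_pipeline(config: Union[dict, str, Path], outdir: Union[str, Path],
                 seed: int = 0) -> Path:
    """Run the full analysis described by a JSON config.

    Config keys: ``input_csv`` (path) or ``synthetic`` (kwargs for
    :func:`make_base_case_network`); ``scenario`` (base | sa1 | sa2 |
    list of trial ids); ``outcomes`` (default: all analysable); ``model``
    (chains/iterations/burn_in/prior SDs); ``reference``; ``directions``
    (per-outcome ranking direction overrides); ``correlation_r`` (fallback
    when no complete SD triples are present in the data).

    Writes, per outcome: network edge list and DOT file, estimate and
    ranking tables, league table, draws CSV and a run manifest.  Raises the
    stage-specific error (validation / feasibility / convergence) instead
    of silently skipping.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    input_files: list[Path] = []
    if "input_csv" in config:
        path = Path(config["input_csv"])
        trials = read_trials(path)
        input_files.append(path)
    elif "synthetic" in config:
        trials = make_base_case_network(seed=seed, **(config["synthetic"] or {}))
    else:
        raise ValidationError("config needs 'input_csv' or 'synthetic'")
    violations = validate_trials(trials)
    if violations:
        raise ValidationError(
            "input failed validation:\n" + "\n".join(map(str, violations))
        )

    scen_cfg = config.get("scenario", "base")
    scenario = (Scenario.named(scen_cfg) if isinstance(scen_cfg, str)
                else Scenario.custom(scen_cfg))
    outcomes = config.get("outcomes", list(OUTCOMES))
    reference = config.get("reference", REFERENCE_TREATMENT)
    directions = {**DEFAULT_DIRECTIONS, **config.get("directions", {})}
    model_cfg = config.get("model", {})
    priors = {k: model_cfg[k] for k in ("prior_sd_d", "prior_sd_mu")
              if k in model_cfg}
    fit_kw = {k: model_cfg[k] for k in ("chains", "iterations", "burn_in")
              if k in model_cfg}

    triples = preprocessing.collect_correlation_triples(trials)
    if triples:
        corr = preprocessing.estimate_correlation(triples)
    elif "correlation_r" in config:
        corr = preprocessing.CorrelationEstimate(config["correlation_r"], 1)
    else:
        corr = None

    for outcome in outcomes:
        log.info("fitting outcome=%s scenario=%s", outcome, scenario.name)
        model = NetworkMetaAnalysis.from_trials(
            trials, outcome, scenario, correlation=corr,
            reference=reference, **priors,
        )
        res = model.fit(seed=seed, **fit_kw)
        stem = f"{scenario.name}_{outcome}"
        model.network.to_edgelist_csv(outdir / f"{stem}_network.csv")
        (outdir / f"{stem}_network.dot").write_text(model.network.to_dot(),
                                                    encoding="utf-8")
        est = pd.DataFrame([{
            "treatment_a": e.contrast[0], "treatment_b": e.contrast[1],
            "scale": e.scale, "point": e.point,
            "cri_lower": e.cri_lower, "cri_upper": e.cri_upper,
            "significant": e.significant,
        } for e in res.contrasts()])
        est.to_csv(outdir / f"{stem}_estimates.csv", index=False)
        res.ranking(directions.get(outcome)).to_frame().to_csv(
            outdir / f"{stem}_ranking.csv", index=False)
        res.league_table().to_frame().to_csv(outdir / f"{stem}_league.csv")
        forest_data(res).to_csv(outdir / f"{stem}_forest.csv", index=False)
        res.save_draws(outdir / f"{stem}_draws.csv")
        res.save_manifest(outdir / f"{stem}_manifest.json", input_files)
        log.info("  max R-hat %.4f, min ESS %.0f",
                 res.diagnostics["rhat"].max(), res.diagnostics["ess"].min())
    return outdir
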