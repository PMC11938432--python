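"""Bundled fixtures reconstructing the published evidence networks.

The source publication does not deposit the arm-level 52-week table it
analysed, so these fixtures are reconstructions: arm-level cells are
synthetic values constrained so that each trial's direct contrast reproduces
the published trial-level estimate (rows tagged ``derived``), or plausible
synthetic values where nothing was published (tagged ``synthetic``);
baseline columns carry published Table values.  ``direct_estimates.csv``
holds the published contrasts themselves (mean difference with 95% CrI)
plus the contrasts derivable from them by star-network consistency.

Regenerate the synthetic arm cells with
``python -m ghnma.cli simulate --seed <s> --out <csv>``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .preprocessing import DirectEstimate, se_from_interval
from .study_data import TrialRecord, read_trials


def _data_path(name: str) -> Path:
    return Path(resources.files("ghnma").joinpath("data", name))


def load_base_case() -> list[TrialRecord]:
    """The three-trial base-case network (lonapegsomatropin, somatrogon,
    somapacitan, each vs daily somatropin)."""
    return read_trials(_data_path("base_case.csv"))


def load_sa1() -> list[TrialRecord]:
    """Base case plus the LB03002 trial (sensitivity analysis 1)."""
    return read_trials(_data_path("sa1.csv"))


def load_sa2() -> list[TrialRecord]:
    """Base case plus the second somatrogon trial (sensitivity analysis 2)."""
    return read_trials(_data_path("sa2.csv"))


def load_direct_estimates() -> pd.DataFrame:
    """Published trial-level and network contrasts (MD, 95% CrI, SE)."""
    return pd.read_csv(_data_path("direct_estimates.csv"))


def direct_estimate(outcome: str, treatment_a: str,
                    treatment_b: str) -> DirectEstimate:
    """Look up one bundled contrast as a :class:`DirectEstimate`; the SE is
    reconstructed from the CrI width where only the interval is published."""
    df = load_direct_estimates()
    row = df[(df["outcome"] == outcome)
             & (df["treatment_a"] == treatment_a)
             & (df["treatment_b"] == treatment_b)]
    if row.empty:
        raise KeyError(f"no bundled estimate for {outcome}: "
                       f"{treatment_a} vs {treatment_b}")
    r = row.iloc[0]
    if pd.notna(r.get("cri_lower")) and pd.notna(r.get("cri_upper")):
        se = se_from_interval(r["cri_lower"], r["cri_upper"])
        source = "reconstructed-from-interval"
    else:
        se = float(r["se"])
        source = "reconstructed-from-interval"
    return DirectEstimate(
        trial_id=str(r["trial_id"]) if pd.notna(r["trial_id"]) else "",
        contrast=(treatment_a, treatment_b),
        md=float(r["md"]), se=se, source=source,
    )
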