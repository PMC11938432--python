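"""Domain types and CSV I/O for aggregate growth-hormone trial summaries.

The unit of input is an arm-level aggregate summary: for one trial, one
treatment arm and one outcome, either a continuous summary (sample size plus
mean/SD at baseline, follow-up and/or for the change from baseline) or a
binary summary (events out of n, used for serious adverse events).  Trials
are phase-3, two-arm, open-label studies of one long-acting growth hormone
(LAGH) vs daily somatropin in treatment-naive pediatric growth hormone
deficiency, reported at a single 52-week time point; the data model also
accepts multi-arm trials.

CSV schema (comma-separated, UTF-8, "." decimal)::

    trial_id, week, treatment, outcome, n,
    baseline_mean, baseline_sd, followup_mean, followup_sd,
    change_mean, change_sd, events [, approved, provenance]

``outcome`` is one of ``ahv`` (annualized height velocity, cm/year),
``height_sds`` (height SD score change), ``igf1_sds`` (weekly-average IGF-1
SDS change), ``ba_ca_ratio`` (bone age-to-chronological age ratio change) or
``sae`` (serious adverse events, binary).  For ``ahv`` the ``change_mean`` /
``change_sd`` columns carry the 52-week annualized value itself (the analysed
quantity), since the outcome is not a change from baseline.

Missing values are empty cells; ``0`` is always a legal value and never a
missing marker.  The optional ``approved`` flag records whether the arm's
dose is a regulator-approved dose (a feasibility criterion that is data, not
something the package can derive), and ``provenance`` tags each row's summary
as ``printed`` (transcribed from a publication), ``derived`` (reconstructed
from published estimates) or ``synthetic`` (simulated or invented).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .exceptions import ParseError, ValidationError

OUTCOMES = ("ahv", "height_sds", "igf1_sds", "ba_ca_ratio", "sae")
CONTINUOUS_OUTCOMES = ("ahv", "height_sds", "igf1_sds", "ba_ca_ratio")
BINARY_OUTCOMES = ("sae",)

#: The single time point used for analysis (weeks).
ANALYSIS_WEEK = 52

#: Default ranking direction per outcome: growth outcomes are benefits
#: (higher is better); SAEs are harms; bone-age advancement defaults to
#: lower-better but is configurable.
DEFAULT_DIRECTIONS = {
    "ahv": "higher",
    "height_sds": "higher",
    "igf1_sds": "higher",
    "ba_ca_ratio": "lower",
    "sae": "lower",
}

REFERENCE_TREATMENT = "daily_somatropin"

#: Display labels for the treatments of the shipped networks.
TREATMENT_LABELS = {
    "daily_somatropin": "Daily somatropin",
    "lonapegsomatropin": "Lonapegsomatropin",
    "somapacitan": "Somapacitan",
    "somatrogon": "Somatrogon",
    "lb03002": "LB03002",
}

_CSV_COLUMNS = [
    "trial_id", "week", "treatment", "outcome", "n",
    "baseline_mean", "baseline_sd", "followup_mean", "followup_sd",
    "change_mean", "change_sd", "events",
]
_OPTIONAL_COLUMNS = ["approved", "provenance"]


@dataclass(frozen=True)
class Treatment:
    """A treatment node of the evidence network."""

    id: str
    label: str = ""
    is_reference: bool = False

    def __post_init__(self):
        object.__setattr__(self, "id", self.id.lower())
        if not self.label:
            object.__setattr__(
                self, "label", TREATMENT_LABELS.get(self.id, self.id)
            )


@dataclass
class ContinuousArmSummary:
    """Aggregate summary of a continuous outcome in one arm.

    At least one of the change pair (``change_mean``/``change_sd``) or both
    baseline and follow-up pairs must be present; a missing ``change_sd``
    can be imputed downstream from baseline/follow-up SDs and a correlation.
    """

    n: int
    baseline_mean: Optional[float] = None
    baseline_sd: Optional[float] = None
    followup_mean: Optional[float] = None
    followup_sd: Optional[float] = None
    change_mean: Optional[float] = None
    change_sd: Optional[float] = None

    def has_change_pair(self) -> bool:
        return self.change_mean is not None and self.change_sd is not None

    def has_raw_pairs(self) -> bool:
        return None not in (
            self.baseline_mean, self.baseline_sd,
            self.followup_mean, self.followup_sd,
        )


@dataclass
class BinaryArmSummary:
    """Event count summary of a binary outcome in one arm."""

    n: int
    events: int


ArmSummary = Union[ContinuousArmSummary, BinaryArmSummary]


@dataclass
class ArmRecord:
    """One treatment arm of a trial with its per-outcome summaries."""

    treatment: str
    outcomes: dict[str, ArmSummary] = field(default_factory=dict)
    approved: bool = True
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.treatment = self.treatment.lower()


@dataclass
class TrialRecord:
    """Arm-level aggregate record of one randomized trial."""

    trial_id: str
    week: int
    arms: list[ArmRecord] = field(default_factory=list)

    def __post_init__(self):
        self.trial_id = self.trial_id.lower()

    def arm(self, treatment: str) -> ArmRecord:
        treatment = treatment.lower()
        for a in self.arms:
            if a.treatment == treatment:
                return a
        raise KeyError(f"trial {self.trial_id} has no arm {treatment}")

    def treatments(self) -> list[str]:
        return [a.treatment for a in self.arms]

    def outcomes(self) -> set[str]:
        out: set[str] = set()
        for a in self.arms:
            out.update(a.outcomes)
        return out


# Trial sets of the shipped analytic scenarios.  The base case holds the
# three globally run trials judged similar enough to combine; each
# sensitivity analysis adds exactly one further trial.
BASE_TRIALS = frozenset({"thornton2021", "deal2022", "miller2022"})
SA1_TRIALS = BASE_TRIALS | {"khadilkar2007"}
SA2_TRIALS = BASE_TRIALS | {"horikawa2022"}


@dataclass(frozen=True)
class Scenario:
    """A named analytic scenario: which trials enter the network."""

    name: str
    trial_ids: frozenset[str]

    @classmethod
    def base(cls) -> "Scenario":
        return cls("base", BASE_TRIALS)

    @classmethod
    def sa1(cls) -> "Scenario":
        return cls("sa1", SA1_TRIALS)

    @classmethod
    def sa2(cls) -> "Scenario":
        return cls("sa2", SA2_TRIALS)

    @classmethod
    def custom(cls, trial_ids: Iterable[str], name: str = "custom") -> "Scenario":
        return cls(name, frozenset(t.lower() for t in trial_ids))

    @classmethod
    def named(cls, name: str) -> "Scenario":
        try:
            return {"base": cls.base, "sa1": cls.sa1, "sa2": cls.sa2}[name]()
        except KeyError:
            raise ValueError(f"unknown scenario name: {name!r}") from None


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_record`."""

    trial_id: str
    treatment: Optional[str]
    fieldname: str
    message: str

    def __str__(self) -> str:
        where = self.trial_id + (f"/{self.treatment}" if self.treatment else "")
        return f"{where}: {self.fieldname}: {self.message}"


def _parse_float(cell: str, row_no: int, col: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"row {row_no}: cannot parse {col}={cell!r} as a number")


def _parse_int(cell: str, row_no: int, col: str) -> Optional[int]:
    v = _parse_float(cell, row_no, col)
    if v is None:
        return None
    if v != int(v):
        raise ParseError(f"row {row_no}: {col}={cell!r} is not an integer")
    return int(v)


def read_trials(path: Union[str, Path]) -> list[TrialRecord]:
    """Read arm-level trial summaries from a schema CSV.

    Returns one :class:`TrialRecord` per distinct ``trial_id`` (order of
    first appearance).  Empty cells become ``None``, never 0.  Raises
    :class:`ParseError` for malformed rows (naming the row number) and
    :class:`ValidationError` for duplicate (trial, treatment, outcome)
    entries or ``events > n``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path.name}: missing required columns: {missing}")
        trials: dict[str, TrialRecord] = {}
        seen: set[tuple[str, str, str]] = set()
        for row_no, row in enumerate(reader, start=2):  # 1 is the header
            trial_id = (row["trial_id"] or "").strip().lower()
            treatment = (row["treatment"] or "").strip().lower()
            outcome = (row["outcome"] or "").strip().lower()
            if not trial_id or not treatment:
                raise ParseError(f"row {row_no}: empty trial_id or treatment")
            if outcome not in OUTCOMES:
                raise ParseError(f"row {row_no}: unknown outcome {outcome!r}")
            week = _parse_int(row["week"], row_no, "week")
            if week is None:
                raise ParseError(f"row {row_no}: week is required")
            n = _parse_int(row["n"], row_no, "n")
            if n is None:
                raise ParseError(f"row {row_no}: n is required")

            key = (trial_id, treatment, outcome)
            if key in seen:
                raise ValidationError(
                    f"row {row_no}: duplicate entry for trial {trial_id}, "
                    f"treatment {treatment}, outcome {outcome}"
                )
            seen.add(key)

            rec = trials.get(trial_id)
            if rec is None:
                rec = trials[trial_id] = TrialRecord(trial_id, week)
            elif rec.week != week:
                raise ValidationError(
                    f"row {row_no}: trial {trial_id} has inconsistent weeks "
                    f"({rec.week} vs {week})"
                )
            try:
                arm = rec.arm(treatment)
            except KeyError:
                arm = ArmRecord(treatment)
                rec.arms.append(arm)
            approved = (row.get("approved") or "").strip().lower()
            if approved:
                arm.approved = approved not in ("0", "false", "no")
            prov = (row.get("provenance") or "").strip().lower()
            if prov:
                arm.provenance[outcome] = prov

            if outcome in BINARY_OUTCOMES:
                events = _parse_int(row["events"], row_no, "events")
                if events is None:
                    raise ParseError(f"row {row_no}: events is required for {outcome}")
                if events > n or events < 0:
                    raise ValidationError(
                        f"row {row_no}: events={events} outside [0, n={n}]"
                    )
                arm.outcomes[outcome] = BinaryArmSummary(n=n, events=events)
            else:
                arm.outcomes[outcome] = ContinuousArmSummary(
                    n=n,
                    baseline_mean=_parse_float(row["baseline_mean"], row_no, "baseline_mean"),
                    baseline_sd=_parse_float(row["baseline_sd"], row_no, "baseline_sd"),
                    followup_mean=_parse_float(row["followup_mean"], row_no, "followup_mean"),
                    followup_sd=_parse_float(row["followup_sd"], row_no, "followup_sd"),
                    change_mean=_parse_float(row["change_mean"], row_no, "change_mean"),
                    change_sd=_parse_float(row["change_sd"], row_no, "change_sd"),
                )
    return list(trials.values())


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    return repr(float(v))


def write_trials(trials: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    """Write trial records back to the CSV schema (numeric round-trip safe)."""
    path = Path(path)
    cols = _CSV_COLUMNS + _OPTIONAL_COLUMNS
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in trials:
            for arm in rec.arms:
                for outcome in OUTCOMES:
                    if outcome not in arm.outcomes:
                        continue
                    s = arm.outcomes[outcome]
                    if isinstance(s, BinaryArmSummary):
                        vals = [None] * 6 + [s.events]
                    else:
                        vals = [s.baseline_mean, s.baseline_sd,
                                s.followup_mean, s.followup_sd,
                                s.change_mean, s.change_sd, None]
                    writer.writerow(
                        [rec.trial_id, rec.week, arm.treatment, outcome, s.n]
                        + [_fmt(v) for v in vals]
                        + [_fmt(arm.approved), arm.provenance.get(outcome, "")]
                    )


def validate_record(rec: TrialRecord) -> list[Violation]:
    """Check a trial record against the type invariants; report, never throw.

    Returns an empty list iff the record is analysable: it has at least two
    arms with distinct treatments, is reported at the 52-week analysis time
    point, and every arm summary satisfies its own invariants.
    """
    out: list[Violation] = []
    if rec.week != ANALYSIS_WEEK:
        out.append(Violation(
            rec.trial_id, None, "week",
            f"analyses only accept data reported at {ANALYSIS_WEEK} weeks "
            f"of treatment (got {rec.week})",
        ))
    if len(rec.arms) < 2:
        out.append(Violation(rec.trial_id, None, "arms",
                             f"trial has {len(rec.arms)} arm(s); need >= 2"))
    seen: set[str] = set()
    for arm in rec.arms:
        if arm.treatment in seen:
            out.append(Violation(rec.trial_id, arm.treatment, "treatment",
                                 "duplicate treatment within trial"))
        seen.add(arm.treatment)
        for outcome, s in arm.outcomes.items():
            loc = f"{outcome}"
            if s.n < 1:
                out.append(Violation(rec.trial_id, arm.treatment, loc,
                                     f"n must be >= 1 (got {s.n})"))
            if isinstance(s, BinaryArmSummary):
                if not 0 <= s.events <= s.n:
                    out.append(Violation(rec.trial_id, arm.treatment, loc,
                                         f"events={s.events} outside [0, n={s.n}]"))
                continue
            for name in ("baseline_sd", "followup_sd", "change_sd"):
                v = getattr(s, name)
                if v is not None and not (v > 0 and math.isfinite(v)):
                    out.append(Violation(rec.trial_id, arm.treatment, loc,
                                         f"{name} must be > 0 (got {v})"))
            if not (s.has_change_pair() or s.has_raw_pairs()
                    or (s.change_mean is not None and s.baseline_sd is not None
                        and s.followup_sd is not None)):
                out.append(Violation(
                    rec.trial_id, arm.treatment, loc,
                    "need a change mean/SD pair, or baseline+follow-up pairs, "
                    "or a change mean with imputable SD",
                ))
    return out


def validate_trials(trials: Iterable[TrialRecord]) -> list[Violation]:
    out: list[Violation] = []
    for rec in trials:
        out.extend(validate_record(rec))
    return out
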