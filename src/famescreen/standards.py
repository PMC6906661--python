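"""Biodiesel standard compliance: inclusive limit checks on fuel properties.

The default criteria set mirrors the limit row of the study's results
table: kinematic viscosity, specific gravity and cetane number from the
US standard ASTM D6751, iodine value from the European EN 14214, and
ADU / higher-heating-value ranges quoted without explicit attribution
(source ``paper_stated``).  Bounds are inclusive on both sides, and
when the properties were produced under rounding policy "paper" the
comparison happens at printed precision — 41.4 versus an upper limit
of 41 fails deterministically rather than hinging on float noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from famescreen.fuel_properties import FuelProperties

__all__ = [
    "StandardCriterion",
    "Verdict",
    "ComplianceReport",
    "evaluate",
    "summarize",
    "read_criteria",
    "default_criteria",
]


@dataclass(frozen=True)
class StandardCriterion:
    """One inclusive-bound quality criterion on a named property."""

    property_name: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    source: str = "paper_stated"

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError(f"{self.property_name}: criterion needs at least one bound")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"{self.property_name}: lower bound exceeds upper bound")

    def describe(self) -> str:
        if self.lower is not None and self.upper is not None:
            return f"{self.lower}–{self.upper}"
        if self.lower is not None:
            return f"≥{self.lower}"
        return f"≤{self.upper}"


@dataclass(frozen=True)
class Verdict:
    """One criterion's outcome on one sample.

    ``margin`` is the signed distance to the nearest violated bound:
    non-negative slack for passes (distance to the closest bound),
    negative by the size of the violation for fails.
    """

    criterion: StandardCriterion
    value: float
    passed: bool
    margin: float


@dataclass(frozen=True)
class ComplianceReport:
    """All verdicts for one sample; ``overall_pass`` iff every one passed."""

    sample_id: str
    verdicts: tuple[Verdict, ...]
    overall_pass: bool

    @property
    def violations(self) -> list[Verdict]:
        return [v for v in self.verdicts if not v.passed]


def evaluate(
    properties: FuelProperties, criteria: Optional[list[StandardCriterion]] = None
) -> ComplianceReport:
    """Check a sample's properties against a criteria list.

    Verdict order follows criteria order.  A criterion naming a property
    the input does not carry is a configuration error, never a silent
    skip.
    """
    if criteria is None:
        criteria = default_criteria()
    values = properties.as_dict()
    verdicts = []
    for criterion in criteria:
        if criterion.property_name not in values:
            raise KeyError(
                f"criterion references unknown property {criterion.property_name!r}; "
                f"available: {sorted(values)}"
            )
        value = values[criterion.property_name]
        below = criterion.lower is not None and value < criterion.lower
        above = criterion.upper is not None and value > criterion.upper
        if below:
            margin = value - criterion.lower
        elif above:
            margin = criterion.upper - value
        else:
            slacks = []
            if criterion.lower is not None:
                slacks.append(value - criterion.lower)
            if criterion.upper is not None:
                slacks.append(criterion.upper - value)
            margin = min(slacks)
        verdicts.append(Verdict(criterion, value, not (below or above), margin))
    return ComplianceReport(
        sample_id=properties.sample_id,
        verdicts=tuple(verdicts),
        overall_pass=all(v.passed for v in verdicts),
    )


def summarize(reports: list[ComplianceReport]):
    """Tabulate reports: one row per sample (sorted by id) of pass/fail
    flags per property plus a violation count."""
    import pandas as pd

    rows = []
    for report in sorted(reports, key=lambda r: r.sample_id):
        row: dict[str, object] = {"sample_id": report.sample_id}
        for v in report.verdicts:
            row[v.criterion.property_name] = "pass" if v.passed else "fail"
        row["n_violations"] = len(report.violations)
        row["overall_pass"] = report.overall_pass
        rows.append(row)
    return pd.DataFrame(rows)


def read_criteria(path: str | Path) -> list[StandardCriterion]:
    """Read criteria from a TSV of (property_name, lower, upper, source);
    an empty cell leaves that side unbounded."""
    criteria = []
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        name, lower, upper, source = (line.split("\t") + [""] * 4)[:4]
        if name == "property_name":
            continue
        criteria.append(
            StandardCriterion(
                property_name=name,
                lower=float(lower) if lower.strip() else None,
                upper=float(upper) if upper.strip() else None,
                source=source.strip() or "paper_stated",
            )
        )
    return criteria


_DEFAULTS: Optional[list[StandardCriterion]] = None


def default_criteria() -> list[StandardCriterion]:
    """The packaged six-criterion set (ADU, Vis, SG, CN, IV, HHV)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        with resources.as_file(
            resources.files("famescreen.data").joinpath("criteria.tsv")
        ) as p:
            _DEFAULTS = read_criteria(p)
    return list(_DEFAULTS)
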