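"""Reading, validating and writing FAME composition profiles and culture metrics.

The on-disk layout is the long format common to published composition
tables: first column fatty-acid shorthand, an optional second column
with the systematic methyl-ester name, and one column per sample whose
cells are mass percent of total lipid.  An empty cell means "not
detected"; an explicit zero is dropped at load with a logged notice.

The package ships the composition profiles and culture metrics of four
microalgal isolates (G4-3, G4-9, P2-15, P5-4) from a published
GC-MS screening as reference fixtures; see :func:`load_reference_profiles`
and :func:`load_reference_isolates`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from famescreen._round import round_half_up
from famescreen.nomenclature import FattyAcid, parse_shorthand

__all__ = [
    "FameComponent",
    "FameProfile",
    "IsolateRecord",
    "ProfileError",
    "read_profiles",
    "write_profiles",
    "total_fame",
    "validate_profile",
    "read_isolates",
    "load_reference_profiles",
    "load_reference_isolates",
    "DEFAULT_SUM_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: Allowed overshoot of a profile's percentage sum past 100, in
#: percentage points; printed tables carry rounding error.
DEFAULT_SUM_TOLERANCE = 0.5


class ProfileError(ValueError):
    """A composition table violates the profile contract."""


@dataclass(frozen=True)
class FameComponent:
    """One (fatty acid, mass percent of total lipid) entry of a profile.

    Contract: ``0 < mass_percent <= 100``.  The bounds are enforced at
    load time and reported by :func:`validate_profile`, not by the
    constructor, so that malformed profiles can be represented and
    diagnosed.
    """

    acid: FattyAcid
    mass_percent: float


@dataclass
class FameProfile:
    """A sample's FAME composition: ordered components plus annotations."""

    sample_id: str
    components: list[FameComponent] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def percent_of(self, acid: FattyAcid) -> float:
        """Mass percent of one acid, 0.0 when absent."""
        for c in self.components:
            if c.acid == acid:
                return c.mass_percent
        return 0.0


@dataclass
class IsolateRecord:
    """Culture screening metrics for one isolate.

    ``dry_biomass`` is g per L of culture (None when unreported),
    ``lipid_content`` percent of dry biomass.  Standard deviations, when
    known, ride along in ``metadata`` and are not used in computations.
    """

    sample_id: str
    dry_biomass: Optional[float]
    lipid_content: float
    profile: Optional[FameProfile] = None
    metadata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dry_biomass is not None and self.dry_biomass < 0:
            raise ProfileError(f"{self.sample_id}: negative dry biomass")
        if not 0 <= self.lipid_content <= 100:
            raise ProfileError(
                f"{self.sample_id}: lipid content {self.lipid_content}% outside [0, 100]"
            )


def _read_table(path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)


def read_profiles(
    path: str | Path,
    format: Optional[str] = None,
    sum_tolerance: float = DEFAULT_SUM_TOLERANCE,
) -> list[FameProfile]:
    """Read FAME profiles from a long-format CSV/TSV composition table.

    Parameters
    ----------
    path : path-like
        Table with a shorthand column first, an optional ``fame_name``
        column, and one column per sample.  Lines starting with ``#``
        are comments.
    format : {"csv", "tsv"}, optional
        Defaults from the file suffix (``.tsv`` → tab, else comma).
    sum_tolerance : float
        Maximum allowed overshoot of a sample's percentage sum past 100.

    Returns
    -------
    list of FameProfile
        One profile per sample column, in column order; empty cells are
        skipped, explicit zeros dropped with a logged notice.

    Raises
    ------
    ProfileError
        On unparseable shorthand (with row and token), duplicate acid
        rows, non-numeric cells, or a column sum above ``100 +
        sum_tolerance``.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if format not in {"csv", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    frame = _read_table(path, "\t" if format == "tsv" else ",")
    if frame.shape[1] < 2:
        raise ProfileError(f"{path}: need a shorthand column plus at least one sample column")

    columns = list(frame.columns)
    sample_columns = columns[2:] if len(columns) > 2 and columns[1] == "fame_name" else columns[1:]

    acids: list[FattyAcid] = []
    for row_index, token in enumerate(frame[columns[0]]):
        try:
            acids.append(parse_shorthand(token))
        except ValueError as exc:
            raise ProfileError(f"{path}: row {row_index + 2}: {exc}") from exc
    seen: set[FattyAcid] = set()
    for a in acids:
        if a in seen:
            raise ProfileError(f"{path}: duplicate acid row {a.shorthand}")
        seen.add(a)

    profiles = []
    for sample in sample_columns:
        components = []
        for acid, cell in zip(acids, frame[sample]):
            cell = cell.strip()
            if cell in {"", "-", "NA", "nan"}:
                continue
            try:
                value = float(cell)
            except ValueError:
                raise ProfileError(
                    f"{path}: sample {sample}, acid {acid.shorthand}: non-numeric cell {cell!r}"
                ) from None
            if value == 0:
                logger.info("%s: %s reported as exactly 0, dropped", sample, acid.shorthand)
                continue
            components.append(FameComponent(acid, value))
        profile = FameProfile(sample_id=sample, components=components)
        total = sum(c.mass_percent for c in profile.components)
        if total > 100 + sum_tolerance:
            raise ProfileError(
                f"{path}: sample {sample}: components sum to {total:.2f}% "
                f"> 100 + {sum_tolerance}"
            )
        profiles.append(profile)
    return profiles


def write_profiles(profiles: list[FameProfile], path: str | Path, format: Optional[str] = None) -> None:
    """Write profiles in the same long-format layout ``read_profiles`` accepts.

    Percentages are written with two decimals; the acid panel is the
    union over profiles, ordered by chain length then unsaturation.
    Reading the file back reproduces the profiles up to that rounding.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    panel = sorted(
        {c.acid for p in profiles for c in p.components},
        key=lambda a: (a.carbons, a.double_bonds, a.omega or 0),
    )
    table = {"shorthand": [a.shorthand for a in panel]}
    for p in profiles:
        table[p.sample_id] = [
            f"{p.percent_of(a):.2f}" if p.percent_of(a) > 0 else "" for a in panel
        ]
    frame = pd.DataFrame(table)
    frame.to_csv(path, sep="\t" if format == "tsv" else ",", index=False)


def total_fame(profile: FameProfile) -> float:
    """Total FAME recovery: the percentage-sum of the profile, 2 decimals.

    This is the composition table's totals row — the fraction of the
    extracted lipid recovered as methyl esters.
    """
    return round_half_up(sum(c.mass_percent for c in profile.components), 2)


def validate_profile(
    profile: FameProfile, sum_tolerance: float = DEFAULT_SUM_TOLERANCE
) -> list[str]:
    """Check a profile against its contract; findings are data, not errors.

    Returns an ordered list of human-readable rule violations (sum
    bound, duplicate acids, non-positive percentages), empty when the
    profile is clean.  Pure: never mutates the profile.
    """
    findings: list[str] = []
    total = sum(c.mass_percent for c in profile.components)
    if total > 100 + sum_tolerance:
        findings.append(
            f"component sum {total:.2f}% exceeds 100 + tolerance {sum_tolerance}"
        )
    acids = [c.acid for c in profile.components]
    for dupe in sorted({a.shorthand for a in acids if acids.count(a) > 1}):
        findings.append(f"duplicate acid {dupe}")
    for c in profile.components:
        if c.mass_percent <= 0:
            findings.append(f"non-positive percentage {c.mass_percent} for {c.acid.shorthand}")
    return findings


def read_isolates(path: str | Path, profiles: Optional[list[FameProfile]] = None) -> list[IsolateRecord]:
    """Read culture metrics (sample_id, dry biomass g/L, lipid %) from CSV.

    Optional ``biomass_sd`` / ``lipid_sd`` columns are kept as metadata.
    When ``profiles`` is given, records are joined to them by sample_id.
    """
    frame = _read_table(Path(path), ",")
    by_id = {p.sample_id: p for p in profiles} if profiles else {}
    records = []
    for _, row in frame.iterrows():
        biomass = row.get("dry_biomass_g_per_L", "").strip()
        meta = {
            key: float(row[key])
            for key in ("biomass_sd", "lipid_sd")
            if key in frame.columns and row[key].strip()
        }
        records.append(
            IsolateRecord(
                sample_id=row["sample_id"],
                dry_biomass=float(biomass) if biomass else None,
                lipid_content=float(row["lipid_content_pct"]),
                profile=by_id.get(row["sample_id"]),
                metadata=meta,
            )
        )
    return records


def load_reference_profiles() -> list[FameProfile]:
    """The four packaged isolate profiles (G4-3, G4-9, P2-15, P5-4)."""
    with resources.as_file(
        resources.files("famescreen.data").joinpath("reference_profiles.csv")
    ) as p:
        return read_profiles(p, format="csv")


def load_reference_isolates() -> list[IsolateRecord]:
    """The packaged culture metrics, joined to the reference profiles."""
    with resources.as_file(
        resources.files("famescreen.data").joinpath("isolate_metrics.csv")
    ) as p:
        return read_isolates(p, profiles=load_reference_profiles())
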