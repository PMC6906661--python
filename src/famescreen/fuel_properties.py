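"""Average degree of unsaturation and empirical fuel-property correlations.

The average degree of unsaturation of a lipid is

    ADU = Σ Mᵢ · Yᵢ

over the fatty-acid constituents, with Mᵢ the number of carbon–carbon
double bonds and Yᵢ the mass fraction of constituent *i* expressed
relative to the **total lipid** (so a profile with 86% total FAME
recovery keeps Yᵢ summing to 0.86, not renormalized to 1).

Five fuel properties are then linear in ADU, with coefficients from
published regressions over algal-oil FAMEs:

    kinematic viscosity  Vis = −0.6316·ADU + 5.2065   (mm² s⁻¹ at 40 °C)
    specific gravity     SG  =  0.0055·ADU + 0.8726   (kg L⁻¹)
    cetane number        CN  = −6.6684·ADU + 62.876
    iodine value         IV  =  74.373·ADU + 12.71    (g I₂ / 100 g)
    higher heating value HHV =  1.7601·ADU + 38.534   (MJ kg⁻¹)

Two rounding policies are supported.  Policy ``"paper"`` mimics how the
values appear in a printed results table: the ADU is rounded half-up to
two decimals first, and every correlation is evaluated on that *rounded*
ADU, then rounded to the property's own printed precision.  The
two-stage scheme matters: at ADU 1.6671 the iodine value is 136.70 at
full precision but 136.91 when computed from the rounded 1.67.  Policy
``"none"`` keeps full precision throughout and is the default for
downstream numerical work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

from famescreen._round import round_half_up
from famescreen.profile_io import FameProfile

__all__ = [
    "PropertyCorrelation",
    "FuelProperties",
    "compute_adu",
    "apply_correlation",
    "compute_properties",
    "default_correlations",
    "read_correlations",
    "ADU_CALIBRATION_RANGE",
]

logger = logging.getLogger(__name__)

RoundingPolicy = Literal["paper", "none"]

#: ADU range of the quality criteria the correlations are judged
#: against; outside it the linear fits are extrapolations.
ADU_CALIBRATION_RANGE = (0.6, 1.6)


@dataclass(frozen=True)
class PropertyCorrelation:
    """One linear-in-ADU property model: value = slope·ADU + intercept."""

    property_name: str
    slope: float
    intercept: float
    units: str
    output_decimals: int


@dataclass(frozen=True)
class FuelProperties:
    """Predicted fuel properties of one sample under a rounding policy."""

    sample_id: str
    adu: float
    vis: float
    sg: float
    cn: float
    iv: float
    hhv: float
    rounding_policy: RoundingPolicy = "none"

    def as_dict(self) -> dict[str, float]:
        return {
            "ADU": self.adu,
            "Vis": self.vis,
            "SG": self.sg,
            "CN": self.cn,
            "IV": self.iv,
            "HHV": self.hhv,
        }


def read_correlations(path: str | Path) -> list[PropertyCorrelation]:
    """Read a correlation set from a TSV of
    (property_name, slope, intercept, units, output_decimals)."""
    correlations = []
    seen: set[str] = set()
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        name, slope, intercept, units, decimals = line.split("\t")
        if name == "property_name":
            continue
        if name in seen:
            raise ValueError(f"duplicate correlation for {name}")
        seen.add(name)
        correlations.append(
            PropertyCorrelation(name, float(slope), float(intercept), units, int(decimals))
        )
    return correlations


_DEFAULTS: Optional[list[PropertyCorrelation]] = None


def default_correlations() -> list[PropertyCorrelation]:
    """The packaged five-property correlation set (Vis, SG, CN, IV, HHV)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        with resources.as_file(
            resources.files("famescreen.data").joinpath("correlations.tsv")
        ) as p:
            _DEFAULTS = read_correlations(p)
    return list(_DEFAULTS)


def compute_adu(profile: FameProfile, policy: RoundingPolicy = "none") -> float:
    """Average degree of unsaturation of a profile.

    Σ double_bonds × mass_percent/100 over components; an empty profile
    gives 0.  Under policy ``"paper"`` the result is rounded half-up to
    two decimals.
    """
    adu = sum(c.acid.double_bonds * c.mass_percent / 100.0 for c in profile.components)
    return round_half_up(adu, 2) if policy == "paper" else adu


def apply_correlation(
    correlation: PropertyCorrelation, adu: float, policy: RoundingPolicy = "none"
) -> float:
    """Evaluate slope·ADU + intercept, rounding to the printed precision
    under policy ``"paper"``."""
    value = correlation.slope * adu + correlation.intercept
    if policy == "paper":
        return round_half_up(value, correlation.output_decimals)
    return value


def compute_properties(
    profile: FameProfile,
    correlations: Optional[list[PropertyCorrelation]] = None,
    policy: RoundingPolicy = "none",
) -> FuelProperties:
    """Predict the five fuel properties of a profile.

    Under policy ``"paper"`` the correlations are applied to the ADU
    *after* rounding it to two decimals — the convention of printed
    results tables, where each column is computed from the ADU column as
    shown.  Under ``"none"`` full precision is kept throughout.

    A logged warning flags ADU values outside the correlations'
    calibration range [0.6, 1.6]; values are still returned.
    """
    if correlations is None:
        correlations = default_correlations()
    adu = compute_adu(profile, policy=policy)
    lo, hi = ADU_CALIBRATION_RANGE
    if not lo <= adu <= hi:
        logger.warning(
            "%s: ADU %.4f outside calibration range [%s, %s]; "
            "property correlations are extrapolating",
            profile.sample_id, adu, lo, hi,
        )
    by_name = {c.property_name: c for c in correlations}
    missing = {"Vis", "SG", "CN", "IV", "HHV"} - set(by_name)
    if missing:
        raise ValueError(f"correlation set lacks {sorted(missing)}")
    return FuelProperties(
        sample_id=profile.sample_id,
        adu=adu,
        vis=apply_correlation(by_name["Vis"], adu, policy),
        sg=apply_correlation(by_name["SG"], adu, policy),
        cn=apply_correlation(by_name["CN"], adu, policy),
        iv=apply_correlation(by_name["IV"], adu, policy),
        hhv=apply_correlation(by_name["HHV"], adu, policy),
        rounding_policy=policy,
    )
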