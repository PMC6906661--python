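"""Synthetic FAME profiles with known ground-truth unsaturation.

The generator emulates the statistical shape of published microalgal
composition tables: sparse panels of C12–C24 acids with 0–6 double
bonds, component percentages drawn as a symmetric composition
(normalized gamma variates, the standard Dirichlet construction), and
totals in the 60–90% FAME-recovery range.  Each profile records its
ground-truth ADU at generation time from the unrounded weights, so
every downstream stage can be tested for exact parameter recovery
without any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from famescreen.nomenclature import FattyAcid, parse_shorthand
from famescreen.profile_io import FameComponent, FameProfile

__all__ = [
    "SyntheticSpec",
    "SyntheticProfile",
    "generate",
    "make_profile_with_target_adu",
    "default_panel",
]

#: Acid panel of the packaged reference profiles: the 21 distinct
#: C14–C24 fatty acids observed across the four isolates.
_DEFAULT_PANEL = (
    "C14", "C15", "C16", "C16:1n-7", "C16:2n-6", "C16:3n-3", "C16:3n-6",
    "C17", "C18", "C18:1n-4", "C18:1n-7", "C18:2n-6", "C18:3n-3",
    "C18:3n-6", "C20", "C20:1n-9", "C20:4n-3", "C20:5n-3", "C22",
    "C24", "C24:1n-9",
)


def default_panel() -> list[FattyAcid]:
    """The 21-acid candidate panel used when a spec gives none."""
    return [parse_shorthand(s) for s in _DEFAULT_PANEL]


@dataclass
class SyntheticSpec:
    """Parameters of one batch of synthetic profiles.

    ``concentration`` is the gamma shape of the composition draw: large
    values give near-equal component weights, values below 1 give
    spiky, dominated compositions like real profiles.
    ``recovery_range`` bounds the profile total (percent of total
    lipid), matching the 60–90% recoveries typical of direct
    transesterification.
    """

    panel: list[FattyAcid] = field(default_factory=default_panel)
    n_components: int = 12
    concentration: float = 0.7
    recovery_range: tuple[float, float] = (60.0, 90.0)
    n_profiles: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.recovery_range
        if not 1 <= self.n_components <= len(self.panel):
            raise ValueError(
                f"n_components {self.n_components} outside [1, {len(self.panel)}]"
            )
        if not 0 < low <= high <= 100:
            raise ValueError(f"recovery range ({low}, {high}) invalid")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class SyntheticProfile:
    """A generated profile plus its exact generation-time ADU."""

    profile: FameProfile
    truth_adu: float


def generate(spec: SyntheticSpec) -> list[SyntheticProfile]:
    """Draw ``spec.n_profiles`` synthetic profiles.

    Per profile: ``n_components`` acids are sampled uniformly without
    replacement from the panel; positive weights come from normalizing
    independent Gamma(concentration) variates; the weights are scaled to
    a total drawn uniformly from ``recovery_range``.  The truth ADU is
    Σ double_bonds × weight/100 over the stored full-precision weights.
    The same seed and spec reproduce the output exactly.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for index in range(spec.n_profiles):
        picks = rng.choice(len(spec.panel), size=spec.n_components, replace=False)
        acids = [spec.panel[i] for i in picks]
        raw = rng.gamma(shape=spec.concentration, scale=1.0, size=spec.n_components)
        # a zero draw is measure-zero but would break normalization
        raw = np.maximum(raw, np.finfo(float).tiny)
        total = rng.uniform(*spec.recovery_range)
        weights = raw / raw.sum() * total
        components = [
            FameComponent(acid, float(w)) for acid, w in zip(acids, weights)
        ]
        truth = float(sum(a.double_bonds * w / 100.0 for a, w in zip(acids, weights)))
        profile = FameProfile(
            sample_id=f"SYN-{spec.seed}-{index:04d}",
            components=components,
            metadata={"synthetic": "true"},
        )
        out.append(SyntheticProfile(profile=profile, truth_adu=truth))
    return out


def make_profile_with_target_adu(
    target: float,
    unsat_acid: FattyAcid,
    recovery: float = 100.0,
    sample_id: Optional[str] = None,
) -> FameProfile:
    """Two-component profile whose ADU equals ``target`` exactly.

    The unsaturated acid (M ≥ 1 double bonds) carries
    ``x = 100 · target / M`` percent and saturated C16 fills the rest of
    ``recovery``; at ``target`` 0 the profile is C16-only.

    Raises
    ------
    ValueError
        When the target is outside [0, M · recovery / 100].
    """
    m = unsat_acid.double_bonds
    if m < 1:
        raise ValueError(f"{unsat_acid} is saturated; need at least one double bond")
    upper = m * recovery / 100.0
    if not 0 <= target <= upper:
        raise ValueError(f"target ADU {target} outside feasible [0, {upper}]")
    x = 100.0 * target / m
    filler = recovery - x
    components = []
    if x > 0:
        components.append(FameComponent(unsat_acid, x))
    if filler > 0:
        components.append(FameComponent(parse_shorthand("C16"), filler))
    return FameProfile(
        sample_id=sample_id or f"TARGET-{target:g}",
        components=components,
        metadata={"synthetic": "true", "target_adu": repr(target)},
    )
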