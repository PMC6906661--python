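"""Lipid shorthand nomenclature: parsing, validation, and the FAME name catalog.

Fatty acids are identified by the shorthand ``Cx:y n-z`` — *x* carbons,
*y* carbon–carbon double bonds, and *n-z* the omega class (position of
the last double bond counted from the methyl end).  The double-bond
count *y* is the quantity every downstream unsaturation computation
consumes, so it is always derived from the parsed name, never
hand-entered.

Accepted input dialects (all canonicalize to one form):

* optional leading ``C`` (case-insensitive): ``18:3n-3`` and ``c18:3n-3``
* an explicit ``:0`` on saturated acids: ``C16:0`` → ``C16``
* omega written ``n-3``, ``N-3``, ``(n-3)``, ``ω3`` or ``w3``
* internal whitespace, which is ignored

Canonical form omits ``:0`` for saturated acids (``C16``) and writes
unsaturated acids as ``C18:3n-3``.  Positional double-bond locants
(``5,11,14,17-``) live only in systematic methyl-ester names, not in the
shorthand.  Branched, hydroxy and trans-designated acids are rejected:
a silently wrong double-bond count would corrupt every property
computed from it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

__all__ = [
    "FattyAcid",
    "ShorthandError",
    "CatalogError",
    "parse_shorthand",
    "format_shorthand",
    "lookup_fame_name",
    "load_catalog",
]


class ShorthandError(ValueError):
    """A fatty-acid shorthand string could not be parsed or validated."""


class CatalogError(KeyError):
    """A fatty acid has no entry in the FAME name catalog."""


@dataclass(frozen=True)
class FattyAcid:
    """A fatty-acid identity parsed from shorthand.

    Attributes
    ----------
    carbons : int
        Chain length (number of carbon atoms), at least 2.
    double_bonds : int
        Count of carbon–carbon double bonds; bounded above by
        ``(carbons - 2) // 2`` (a methylene-interrupted cis chain cannot
        hold more).
    omega : int or None
        The omega class ``z`` of ``n-z``; present exactly when the acid
        is unsaturated.
    """

    carbons: int
    double_bonds: int = 0
    omega: Optional[int] = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ShorthandError(f"chain length {self.carbons} < 2")
        if self.double_bonds < 0:
            raise ShorthandError(f"negative double-bond count {self.double_bonds}")
        bound = (self.carbons - 2) // 2
        if self.double_bonds > bound:
            raise ShorthandError(
                f"{self.double_bonds} double bonds exceed the structural bound "
                f"{bound} for a C{self.carbons} chain"
            )
        if self.double_bonds == 0:
            if self.omega is not None:
                raise ShorthandError(
                    f"omega class n-{self.omega} given for a saturated C{self.carbons} acid"
                )
        else:
            if self.omega is None:
                raise ShorthandError(
                    f"unsaturated acid C{self.carbons}:{self.double_bonds} lacks an omega class"
                )
            if not 1 <= self.omega <= self.carbons - 2:
                raise ShorthandError(
                    f"omega class n-{self.omega} out of range [1, {self.carbons - 2}]"
                )

    @property
    def shorthand(self) -> str:
        """Canonical shorthand rendering (``C16``, ``C18:3n-3``)."""
        return format_shorthand(self)

    def __str__(self) -> str:
        return self.shorthand


# One regex per dialect family.  Groups: carbons, bonds, omega.
_PATTERN = re.compile(
    r"""^
    [Cc]?                    # optional leading C
    (?P<carbons>\d{1,2})
    (?:
        :(?P<bonds>\d{1,2})
        (?:
            \(?\s*           # "(n-3)" variant
            (?:[nN]\s*-\s*|[ωw])
            (?P<omega>\d{1,2})
            \)?
        )?
    )?
    $""",
    re.VERBOSE,
)


def parse_shorthand(text: str) -> FattyAcid:
    """Parse a fatty-acid shorthand string in any accepted dialect.

    Parameters
    ----------
    text : str
        e.g. ``"C18:3n-3"``, ``"c20:4N-3"``, ``"C16:0"``, ``"18:2(n-6)"``,
        ``"C16:1w7"``.

    Returns
    -------
    FattyAcid
        The parsed identity; its ``shorthand`` is canonical regardless of
        the input dialect.

    Raises
    ------
    ShorthandError
        For malformed strings, a double-bond count exceeding the
        structural bound, an omega class out of range, or an omega class
        attached to a saturated acid.
    """
    stripped = "".join(text.split())
    if not stripped:
        raise ShorthandError("empty fatty-acid shorthand")
    m = _PATTERN.match(stripped)
    if m is None:
        raise ShorthandError(f"unrecognized fatty-acid shorthand {text!r}")
    carbons = int(m.group("carbons"))
    bonds = int(m.group("bonds") or 0)
    omega = m.group("omega")
    if bonds > 0 and omega is None:
        raise ShorthandError(
            f"unsaturated shorthand {text!r} must state an omega class (e.g. n-3)"
        )
    if bonds == 0 and omega is not None:
        raise ShorthandError(f"omega class given for saturated acid in {text!r}")
    return FattyAcid(carbons=carbons, double_bonds=bonds, omega=int(omega) if omega else None)


def format_shorthand(acid: FattyAcid) -> str:
    """Render the canonical shorthand; inverse of :func:`parse_shorthand`."""
    if acid.double_bonds == 0:
        return f"C{acid.carbons}"
    return f"C{acid.carbons}:{acid.double_bonds}n-{acid.omega}"


_CATALOG: Optional[dict[FattyAcid, str]] = None


def load_catalog() -> dict[FattyAcid, str]:
    """Load the packaged shorthand → systematic methyl-ester name catalog."""
    global _CATALOG
    if _CATALOG is None:
        catalog: dict[FattyAcid, str] = {}
        text = resources.files("famescreen.data").joinpath("fame_catalog.tsv").read_text("utf-8")
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            shorthand, name = line.split("\t")
            if shorthand == "shorthand":
                continue
            catalog[parse_shorthand(shorthand)] = name
        _CATALOG = catalog
    return _CATALOG


def lookup_fame_name(acid: FattyAcid) -> str:
    """Return the systematic methyl-ester name for a cataloged acid.

    Raises
    ------
    CatalogError
        When the acid is unknown; the message lists the nearest catalog
        entries by chain length to aid diagnosis.
    """
    catalog = load_catalog()
    try:
        return catalog[acid]
    except KeyError:
        nearest = sorted(
            catalog,
            key=lambda a: (abs(a.carbons - acid.carbons), a.carbons, a.double_bonds, a.omega or 0),
        )[:3]
        hint = ", ".join(a.shorthand for a in nearest)
        raise CatalogError(
            f"{acid.shorthand} is not in the FAME catalog (nearest by chain length: {hint})"
        ) from None
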