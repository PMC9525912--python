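"""Elemental-formula arithmetic and derivatization mass chemistry.

Everything downstream — library matching at 5 ppm, internal-standard
assignment, isotopologue correction — rests on exact monoisotopic masses.
Formulas are written in Hill-like notation; isotope-labeled atoms (as used
in spiked internal standards, e.g. ``[13C]2H3[2H]2[15N]O2`` for
13C2,2,2-2H2,15N-glycine) appear as bracketed symbols with their own
monoisotopic mass.

Two derivatization chemistries are supported:

* dansylation (dansyl chloride + primary/secondary amine, losing HCl):
  net addition C12H11NO2S per site;
* O-benzylhydroxylamine (O-BHA; oxime with carbonyls or, via carbodiimide
  coupling, amide with carboxyls, losing H2O): net addition C7H7N per site.

Both shifts are per-site and additive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Union

logger = logging.getLogger(__name__)

#: Monoisotopic atomic masses (Da). Bracketed symbols are isotope labels
#: with the heavy isotope's mass (used for stable-isotope-labeled internal
#: standards and tracer-fixed atoms).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "[13C]": 13.0033548378,
    "[2H]": 2.0141017778,
    "[15N]": 15.0001088984,
}

#: Mass of a proton (Da); positive-mode MH+ ions only.
PROTON_MASS = 1.00727646688

_TOKEN_RE = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unknown element symbols or malformed formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map with monoisotopic mass arithmetic.

    Counts must be non-negative; the empty formula is valid (mass 0).
    Instances are immutable and support ``+``, ``-`` and ``*`` (integer
    scaling), so derivatization shifts compose by plain arithmetic.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, formula: str) -> "ElementalFormula":
        """Parse Hill-like notation with bracketed isotope labels.

        >>> ElementalFormula.parse("C2H5NO2").counts
        {'C': 2, 'H': 5, 'N': 1, 'O': 2}
        """
        s = formula.strip()
        if not s:
            return cls({})
        counts: Dict[str, int] = {}
        pos = 0
        while pos < len(s):
            m = _TOKEN_RE.match(s, pos)
            if m is None:
                raise FormulaError(
                    f"malformed formula {formula!r} at position {pos}"
                )
            sym, num = m.group(1), m.group(2)
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        return cls(counts)

    @property
    def mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in self.counts.items())

    def n_atoms(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) - n
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({s: n * k for s, n in self.counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return "".join(
            f"{sym}{n if n != 1 else ''}" for sym, n in sorted(self.counts.items())
        )


FormulaLike = Union[ElementalFormula, Mapping[str, int], str]


def as_formula(formula: FormulaLike) -> ElementalFormula:
    if isinstance(formula, ElementalFormula):
        return formula
    if isinstance(formula, str):
        return ElementalFormula.parse(formula)
    return ElementalFormula(dict(formula))


def monoisotopic_mass(formula: FormulaLike) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass.

    Isotope-labeled atoms (``[13C]`` etc.) contribute the heavy isotope's
    mass, as required for labeled internal standards.
    """
    return as_formula(formula).mass


@dataclass(frozen=True)
class DerivatizationScheme:
    """A per-site derivatization: net formula shift and the site chemistry."""

    name: str
    net_shift: ElementalFormula
    site_kind: str


# dansyl chloride C12H12ClNO2S reacting with an amine loses HCl.
DANSYL = DerivatizationScheme(
    name="dansyl",
    net_shift=ElementalFormula.parse("C12H12ClNO2S") - ElementalFormula.parse("HCl"),
    site_kind="primary_amine",
)
# O-benzylhydroxylamine C7H9NO condensing with a carbonyl/carboxyl loses H2O.
OBHA = DerivatizationScheme(
    name="obha",
    net_shift=ElementalFormula.parse("C7H9NO") - ElementalFormula.parse("H2O"),
    site_kind="carbonyl_or_carboxyl",
)
NONE = DerivatizationScheme(
    name="none", net_shift=ElementalFormula({}), site_kind="none"
)

SCHEMES: Dict[str, DerivatizationScheme] = {s.name: s for s in (DANSYL, OBHA, NONE)}


def get_scheme(name: str) -> DerivatizationScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown derivatization scheme {name!r}; expected one of {sorted(SCHEMES)}"
        ) from None


def derivatization_shift(scheme: Union[str, DerivatizationScheme]) -> float:
    """Per-site neutral mass delta (Da) for a derivatization scheme."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if scheme.name == "none":
        logger.warning("derivatization scheme 'none' has zero mass shift")
        return 0.0
    return scheme.net_shift.mass


@dataclass(frozen=True)
class IonSpec:
    """Positive-mode ion: ``m/z = (M + adduct x proton) / charge``.

    ``adduct`` is the number of protons added and defaults to the charge
    ([M+zH]z+; small-molecule ions here are MH+).
    """

    charge: int = 1
    adduct: int = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.adduct is None:
            object.__setattr__(self, "adduct", self.charge)

    def mz(self, neutral_mass: float) -> float:
        return (neutral_mass + self.adduct * PROTON_MASS) / self.charge


def derivatized_mz(
    compound_formula: FormulaLike,
    n_sites: int,
    scheme: Union[str, DerivatizationScheme],
    ion: IonSpec = IonSpec(1),
) -> float:
    """Theoretical m/z of a compound carrying ``n_sites`` derivatization tags."""
    if n_sites < 0:
        raise ValueError(f"n_sites must be >= 0, got {n_sites}")
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    shift = scheme.net_shift.mass if scheme.name != "none" else 0.0
    neutral = monoisotopic_mass(compound_formula) + n_sites * shift
    return ion.mz(neutral)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical_mz}")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6
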