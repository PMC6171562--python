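"""Molecular formulas, mass arithmetic and ion m/z for unit-resolution MRM work.

Two mass modes are supported throughout:

``nominal``
    Integer masses (C=12, H=1, N=14, O=16, P=31, S=32) and a proton of
    exactly 1.  This is the arithmetic behind every printed Q1/Q3 value on a
    unit-resolution triple quadrupole, and it is the default everywhere.

``monoisotopic``
    Exact masses of the most abundant isotopes, for high-resolution use.

The O-benzylhydroxylamine (OBHA) derivatization used for carbonyl/carboxyl
metabolites condenses one OBHA (C7H9NO) per site with loss of water, a net
gain of C7H7N (+105 nominal) per site.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "ElementMassTable",
    "MolecularFormula",
    "IonSpec",
    "Polarity",
    "parse_formula",
    "nominal_mass",
    "monoisotopic_mass",
    "ion_mz",
    "derivatize_obha",
    "OBHA_NET_ADDITION",
    "PROTON_MONOISOTOPIC",
]

#: Mass of a proton in Da (monoisotopic mode); nominal mode uses exactly 1.
PROTON_MONOISOTOPIC = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


@dataclass(frozen=True)
class ElementMassTable:
    """Per-element nominal mass, monoisotopic mass and +1 heavy-isotope abundance.

    Loaded from the packaged ``data/elements.csv`` (CHNOPS).  Nominal masses
    are integers; abundances are fractions in [0, 1].
    """

    nominal: Mapping[str, int]
    monoisotopic: Mapping[str, float]
    heavy_abundance: Mapping[str, float]

    def __post_init__(self) -> None:
        for el, m in self.nominal.items():
            if m != int(m):
                raise ValueError(f"nominal mass of {el} must be an integer")
        for el, a in self.heavy_abundance.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"heavy abundance of {el} outside [0, 1]")

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self.nominal)

    @classmethod
    def from_packaged(cls) -> "ElementMassTable":
        nominal: dict[str, int] = {}
        mono: dict[str, float] = {}
        heavy: dict[str, float] = {}
        text = resources.files("mrmtrace.data").joinpath("elements.csv").read_text()
        rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        for row in csv.DictReader(rows):
            el = row["element"]
            nominal[el] = int(row["nominal"])
            mono[el] = float(row["monoisotopic"])
            heavy[el] = float(row["heavy_abundance"])
        return cls(
            MappingProxyType(nominal), MappingProxyType(mono), MappingProxyType(heavy)
        )


_DEFAULT_TABLE: ElementMassTable | None = None


def default_mass_table() -> ElementMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ElementMassTable.from_packaged()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class MolecularFormula:
    """An element → atom-count map with additive mass semantics.

    Counts are non-negative; elements are restricted to the CHNOPS table.
    Formulas support ``+``, ``-`` (which raises if any count would go
    negative) and ``*`` by a non-negative integer.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = default_mass_table().elements
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in table:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count "
                    f"({self} - {other})"
                )
        return MolecularFormula(merged)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError("formula multiplier must be a non-negative integer")
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] != 1 else el for el in order
        )

    def __repr__(self) -> str:
        return f"MolecularFormula({str(self)!r})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string like ``"C10H14N5O7P"``.

    Repeated element symbols accumulate.  Raises :class:`FormulaError` on
    unknown symbols or malformed input; round-trips through ``str()``.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        el, num = match.group(1), match.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula near {text[pos:]!r}")
    return MolecularFormula(counts)


def nominal_mass(f: MolecularFormula, table: ElementMassTable | None = None) -> int:
    """Integer (unit-resolution) mass: sum of nominal element masses × counts."""
    table = table or default_mass_table()
    return sum(table.nominal[el] * n for el, n in f.counts.items())


def monoisotopic_mass(
    f: MolecularFormula, table: ElementMassTable | None = None
) -> float:
    """Exact mass in Da using most-abundant-isotope masses."""
    table = table or default_mass_table()
    return sum(table.monoisotopic[el] * n for el, n in f.counts.items())


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Adduct(str, Enum):
    PROTON_GAIN = "proton-gain"
    PROTON_LOSS = "proton-loss"


@dataclass(frozen=True)
class IonSpec:
    """Ionization mode for m/z computation.

    Only protonation ([M+H]+, positive) and deprotonation ([M-H]-, negative)
    occur in this workflow, so polarity fixes the adduct and the pairing is
    enforced.
    """

    polarity: Polarity
    charge: int = 1
    adduct: Adduct | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        expected = (
            Adduct.PROTON_GAIN
            if self.polarity == Polarity.POSITIVE
            else Adduct.PROTON_LOSS
        )
        if self.adduct is None:
            object.__setattr__(self, "adduct", expected)
        elif self.adduct != expected:
            raise ValueError(
                f"{self.polarity.value} polarity pairs with {expected.value}"
            )

    @property
    def sign(self) -> int:
        return 1 if self.adduct == Adduct.PROTON_GAIN else -1


POSITIVE_ION = IonSpec(Polarity.POSITIVE)
NEGATIVE_ION = IonSpec(Polarity.NEGATIVE)


def ion_mz(
    f: MolecularFormula,
    ion: IonSpec,
    mode: str = "nominal",
    table: ElementMassTable | None = None,
) -> float:
    """m/z of ``f`` under ``ion``: (mass ± z·proton) / z.

    Proton-gain adds, proton-loss subtracts.  In nominal mode the proton is
    exactly 1 and integer arithmetic is preserved for singly charged ions.
    """
    if mode == "nominal":
        mass: float = nominal_mass(f, table)
        proton: float = 1
    elif mode == "monoisotopic":
        mass = monoisotopic_mass(f, table)
        proton = PROTON_MONOISOTOPIC
    else:
        raise ValueError(f"unknown mass mode: {mode!r}")
    mz = (mass + ion.sign * ion.charge * proton) / ion.charge
    if mz <= 0:
        raise ValueError(f"non-positive m/z for {f} under {ion}")
    return mz


#: Net composition gained per OBHA-derivatized site: C7H9NO condensed minus H2O.
OBHA_NET_ADDITION = MolecularFormula({"C": 7, "H": 7, "N": 1})


def derivatize_obha(f: MolecularFormula, n_sites: int) -> MolecularFormula:
    """Apply OBHA oxime/amide condensation at ``n_sites`` carbonyl/carboxyl sites.

    Each site adds a net C7H7N (+105 nominal Da).  ``n_sites=0`` is the
    identity; the operation is additive in the site count.
    """
    if not isinstance(n_sites, int) or n_sites < 0:
        raise ValueError("n_sites must be a non-negative integer")
    return f + OBHA_NET_ADDITION * n_sites
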