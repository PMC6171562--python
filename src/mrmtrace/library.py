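"""The packaged MRM transition library and the formula-based transition predictor.

The library is a curated, machine-readable transition list for central-carbon,
amino-acid and nucleotide metabolism on a single fusion-core reversed-phase
column: four acquisition methods (underivatized positive, underivatized
negative, and two gradients for O-benzylhydroxylamine-derivatized analytes),
each row carrying the empirically optimized Q1/Q3, collision energy and
retention time.

Printed Q1/Q3 values are authoritative for acquisition.  The predictor
recomputes them from molecular formulas (plus curated derivatization site
counts and fragment specifications) so the library can be validated and
extended to new analytes; collision energies and retention times are
empirical and are stored, never computed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Sequence

import yaml

from .chem import (
    IonSpec,
    MolecularFormula,
    Polarity,
    derivatize_obha,
    ion_mz,
    nominal_mass,
    parse_formula,
)

__all__ = [
    "Analyte",
    "MRMTransition",
    "GradientProgram",
    "TransitionLibrary",
    "PredictedTransition",
    "ValidationRecord",
    "load_library",
    "load_gradients",
    "predict_transition",
    "validate_library",
    "resolve_isobars",
    "IsobarResolutionError",
]


class FragmentKind(str, Enum):
    NONE = "none"
    ION = "ion"  # fragment_formula is the neutral whose (de)protonated ion is Q3
    LOSS = "loss"  # fragment_formula is a neutral loss; Q3 = Q1 - nominal(loss)


@dataclass(frozen=True)
class Analyte:
    """One library analyte: identity, composition and fragmentation curation.

    ``n_obha_sites`` is a stored curation, never inferred from the formula:
    derivatization efficiency is empirical (glutamate, with two carboxyls,
    runs mono-derivatized).
    """

    abbreviation: str
    name: str
    formula: MolecularFormula
    polarity: Polarity
    derivatization: str  # "none" | "OBHA"
    n_obha_sites: int
    fragment_kind: FragmentKind
    fragment_formula: MolecularFormula | None
    method_tag: str
    note: str = ""

    @property
    def precursor_formula(self) -> MolecularFormula:
        """Composition of the species actually ionized (after derivatization)."""
        if self.derivatization == "OBHA":
            return derivatize_obha(self.formula, self.n_obha_sites)
        return self.formula

    @property
    def ion(self) -> IonSpec:
        return IonSpec(self.polarity)


@dataclass(frozen=True)
class MRMTransition:
    """Printed acquisition parameters for one analyte (verbatim floats)."""

    analyte: Analyte
    q1: float
    q3: tuple[float, ...]
    ce: tuple[float, ...]
    rt: float

    def __post_init__(self) -> None:
        if self.q1 <= 0:
            raise ValueError("Q1 must be positive")
        if self.rt < 0:
            raise ValueError("RT must be non-negative")
        for q3 in self.q3:
            # Reporter ions of derivatized analytes (benzyl 91.2) are the only
            # products allowed below a generic sanity floor; all must be < Q1.
            if q3 >= self.q1:
                raise ValueError(f"Q3 {q3} not below Q1 {self.q1}")


@dataclass(frozen=True)
class GradientProgram:
    """An HPLC gradient timetable: (time min, %B) pairs, strictly increasing."""

    name: str
    timetable: tuple[tuple[float, float], ...]
    buffers: str = ""
    column_temperature_c: float | None = None
    flow_ml_min: float | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.timetable]
        if any(b <= a for a, b in zip(times, times[1:], strict=False)):
            raise ValueError("gradient times must be strictly increasing")
        if any(not 0 <= b <= 100 for _, b in self.timetable):
            raise ValueError("%B must lie in [0, 100]")


class TransitionLibrary:
    """Immutable collection of analytes and their transitions."""

    def __init__(self, transitions: Sequence[MRMTransition]):
        self._transitions = tuple(transitions)
        self._by_abbrev: dict[str, MRMTransition] = {}
        for t in self._transitions:
            key = t.analyte.abbreviation
            if key in self._by_abbrev:
                raise ValueError(f"duplicate abbreviation: {key}")
            self._by_abbrev[key] = t

    def __iter__(self):
        return iter(self._transitions)

    def __len__(self) -> int:
        return len(self._transitions)

    def __getitem__(self, abbreviation: str) -> MRMTransition:
        return self._by_abbrev[abbreviation]

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._by_abbrev

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(self._by_abbrev)

    def n_transition_pairs(self) -> int:
        """Number of distinct (Q1, Q3) acquisition pairs across the library."""
        return sum(len(t.q3) for t in self._transitions)


def _parse_float_list(text: str) -> tuple[float, ...]:
    return tuple(float(x) for x in text.split(";") if x.strip())


def load_library() -> TransitionLibrary:
    """Load the packaged transition library (pure: repeated loads are equal)."""
    text = resources.files("mrmtrace.data").joinpath("transition_library.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    if not rows:
        raise RuntimeError("packaged transition library is empty or corrupt")
    transitions = []
    for row in rows:
        kind = FragmentKind(row["fragment_kind"])
        frag = (
            parse_formula(row["fragment_formula"])
            if kind != FragmentKind.NONE
            else None
        )
        analyte = Analyte(
            abbreviation=row["abbreviation"],
            name=row["name"],
            formula=parse_formula(row["formula"]),
            polarity=Polarity(row["polarity"]),
            derivatization=row["derivatization"],
            n_obha_sites=int(row["n_obha_sites"]),
            fragment_kind=kind,
            fragment_formula=frag,
            method_tag=row["method_tag"],
            note=row["note"],
        )
        transitions.append(
            MRMTransition(
                analyte=analyte,
                q1=float(row["q1"]),
                q3=_parse_float_list(row["q3_list"]),
                ce=_parse_float_list(row["ce_list"]),
                rt=float(row["rt"]),
            )
        )
    return TransitionLibrary(transitions)


def load_gradients() -> dict[str, GradientProgram]:
    """Load the packaged HPLC gradient programs, keyed by method tag."""
    text = resources.files("mrmtrace.data").joinpath("gradients.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for key, g in raw.items():
        out[key] = GradientProgram(
            name=g["name"],
            timetable=tuple((float(t), float(b)) for t, b in g["timetable"]),
            buffers=g.get("buffers", ""),
            column_temperature_c=g.get("column_temperature_c"),
            flow_ml_min=g.get("flow_ml_min"),
        )
    return out


@dataclass(frozen=True)
class PredictedTransition:
    """Predictor output: Q1 always; Q3 only when a fragment spec is curated."""

    q1: float
    q3: float | None


def predict_transition(a: Analyte, mode: str = "nominal") -> PredictedTransition:
    """Predict Q1 (and Q3 where a fragment spec exists) from first principles.

    Q1 is the (de)protonated, optionally derivatized precursor.  Q3 is either
    the (de)protonated product-ion formula or Q1 minus a neutral loss; without
    a fragment spec the prediction is limited to Q1.
    """
    q1 = ion_mz(a.precursor_formula, a.ion, mode)
    q3: float | None = None
    if a.fragment_kind == FragmentKind.ION:
        q3 = ion_mz(a.fragment_formula, a.ion, mode)
    elif a.fragment_kind == FragmentKind.LOSS:
        if mode == "nominal":
            q3 = q1 - nominal_mass(a.fragment_formula)
        else:
            from .chem import monoisotopic_mass

            q3 = q1 - monoisotopic_mass(a.fragment_formula)
    return PredictedTransition(q1=q1, q3=q3)


@dataclass(frozen=True)
class ValidationRecord:
    """Per-analyte agreement between predicted and printed values."""

    abbreviation: str
    status: str  # "exact-match" | "off-by-k" | "not-predictable"
    predicted_q1: float
    printed_q1: float
    q1_offset: int
    q3_status: str  # "exact-match" | "off-by-k" | "not-predictable"
    note: str = ""


def validate_library(
    library: TransitionLibrary | None = None,
) -> list[ValidationRecord]:
    """Recompute every predictable Q1/Q3 and classify agreement with print.

    Printed values are compared after rounding to the nearest integer (the
    library stores unit-resolution floats like 147.0 or 91.2 verbatim).  A
    report is always returned; anomalies are flagged, never raised.
    """
    library = library or load_library()
    records = []
    for t in library:
        a = t.analyte
        pred = predict_transition(a, mode="nominal")
        offset = int(round(t.q1) - round(pred.q1))
        status = "exact-match" if offset == 0 else "off-by-k"
        if pred.q3 is None:
            q3_status = "not-predictable"
        elif any(round(q3) == round(pred.q3) for q3 in t.q3):
            q3_status = "exact-match"
        else:
            q3_status = "off-by-k"
        records.append(
            ValidationRecord(
                abbreviation=a.abbreviation,
                status=status,
                predicted_q1=pred.q1,
                printed_q1=t.q1,
                q1_offset=offset,
                q3_status=q3_status,
                note=a.note,
            )
        )
    return records


class IsobarResolutionError(LookupError):
    """No unique analyte matches a (Q1, Q3, RT) observation."""


def resolve_isobars(
    q1: float,
    q3: float,
    rt: float,
    tolerance: float = 0.5,
    library: TransitionLibrary | None = None,
) -> Analyte:
    """Resolve analytes sharing a (Q1, Q3) pair by retention time.

    Isobaric pairs (lysine/glutamine at 147.0/84.1, isoleucine/leucine at
    132.0/86.0) share transitions and are distinguished chromatographically.
    Returns the candidate whose library RT is nearest to ``rt`` within
    ``tolerance`` minutes; raises on no candidate or an exact tie.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    library = library or load_library()
    candidates = [
        t
        for t in library
        if round(t.q1) == round(q1) and any(round(x) == round(q3) for x in t.q3)
    ]
    in_window = [t for t in candidates if abs(t.rt - rt) <= tolerance]
    if not in_window:
        raise IsobarResolutionError(
            f"no library analyte with Q1/Q3 {q1}/{q3} within {tolerance} min of RT {rt}"
        )
    in_window.sort(key=lambda t: abs(t.rt - rt))
    if len(in_window) > 1 and abs(in_window[0].rt - rt) == abs(in_window[1].rt - rt):
        raise IsobarResolutionError(
            f"RT tie between {in_window[0].analyte.abbreviation} and "
            f"{in_window[1].analyte.abbreviation} at {rt} min"
        )
    return in_window[0].analyte
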