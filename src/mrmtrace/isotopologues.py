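"""Stable-isotope isotopologue transition ladders with moiety resolution.

For a tracer element (¹³C or ¹⁵N) an analyte carries ``n_total`` labelable
atoms in the precursor ion, of which ``n_frag`` survive into the monitored
product ion.  A precursor carrying ``k`` labels shifts Q1 by ``k``; the
product shifts by ``j``, the number of those labels that sit in the fragment
moiety.  Feasibility is the hypergeometric-support constraint

    max(0, k - (n_total - n_frag)) <= j <= min(k, n_frag).

Because Q1 and Q3 shift independently, an MRM instrument can attribute label
to sub-structures: for AMP monitored by loss of the nitrogen base, all five
nitrogens and five of the ten carbons are in the base (fragment), the other
five carbons in the ribose (remainder), so e.g. the (k=5, j=0) channel reads
out a fully ¹³C-labeled ribose on an unlabeled base.
"""

from __future__ import annotations

from dataclasses import dataclass

from .library import Analyte, FragmentKind, MRMTransition

__all__ = [
    "LabelScheme",
    "IsotopologueChannel",
    "generate_ladder",
    "select_channels",
    "moiety_atoms",
    "ISOTOPE_MASS_SHIFT",
]

#: Monoisotopic mass shift per heavy label, for high-resolution use.
#: Nominal (unit-resolution) mode always shifts by exactly 1.
ISOTOPE_MASS_SHIFT = {"C": 1.0033548378, "N": 0.9970348893}


@dataclass(frozen=True)
class LabelScheme:
    """Tracer element plus labelable-atom counts for precursor and fragment."""

    element: str  # "C" or "N"
    n_total: int
    n_frag: int

    def __post_init__(self) -> None:
        if self.element not in ("C", "N"):
            raise ValueError("tracer element must be C or N")
        if not 0 <= self.n_frag <= self.n_total:
            raise ValueError("need 0 <= n_frag <= n_total")

    @property
    def n_remainder(self) -> int:
        return self.n_total - self.n_frag

    def feasible(self, k: int, j: int) -> bool:
        """Can ``k`` precursor labels place exactly ``j`` in the fragment?"""
        return (
            0 <= k <= self.n_total
            and max(0, k - self.n_remainder) <= j <= min(k, self.n_frag)
        )


@dataclass(frozen=True)
class IsotopologueChannel:
    """One labeled MRM channel: k labels in the precursor, j in the fragment."""

    name: str
    k: int
    j: int
    q1: float
    q3: float
    ce: float
    moiety_tag: str  # unlabeled | fragment-labeled | remainder-labeled | mixed

    @property
    def remainder_labels(self) -> int:
        return self.k - self.j


def _moiety_tag(k: int, j: int) -> str:
    if k == 0:
        return "unlabeled"
    if j == k:
        return "fragment-labeled"
    if j == 0:
        return "remainder-labeled"
    return "mixed"


def scheme_for_analyte(a: Analyte, element: str) -> LabelScheme:
    """Derive the label scheme from an analyte's formulas (biological atoms).

    Labelable atoms are those of the tracer element in the underivatized
    molecule; derivatization-tag atoms are never biosynthetically labeled.
    Requires a product-ion fragment formula to place ``n_frag``.
    """
    n_total = a.formula[element]
    if a.fragment_kind == FragmentKind.ION and a.fragment_formula is not None:
        n_frag = min(a.fragment_formula[element], n_total)
    elif a.fragment_kind == FragmentKind.LOSS and a.fragment_formula is not None:
        n_frag = n_total - min(a.fragment_formula[element], n_total)
    else:
        raise ValueError(
            f"{a.abbreviation}: no fragment spec; cannot partition labelable atoms"
        )
    return LabelScheme(element=element, n_total=n_total, n_frag=n_frag)


def generate_ladder(
    transition: MRMTransition,
    scheme: LabelScheme,
    mode: str = "nominal",
) -> list[IsotopologueChannel]:
    """Enumerate every feasible (k, j) labeled channel for one base transition.

    Channels are ordered by (k, j).  Q1 shifts by k and Q3 by j heavy-isotope
    mass units; collision energy is inherited from the base transition.  Names
    follow the ``<iso>_<abbrev>_<k>`` pattern, with a ``_frag<j>`` suffix when
    several j share one k.
    """
    a = transition.analyte
    if scheme.n_total > a.formula[scheme.element]:
        raise ValueError(
            f"scheme n_total={scheme.n_total} exceeds {scheme.element} atoms "
            f"in {a.abbreviation}"
        )
    iso = {"C": "13C", "N": "15N"}[scheme.element]
    shift = 1.0 if mode == "nominal" else ISOTOPE_MASS_SHIFT[scheme.element]
    base_q3 = transition.q3[0]
    base_ce = transition.ce[0]
    channels = []
    for k in range(scheme.n_total + 1):
        js = [j for j in range(scheme.n_frag + 1) if scheme.feasible(k, j)]
        for j in js:
            name = f"{iso}_{a.abbreviation}_{k}"
            if len(js) > 1:
                name += f"_frag{j}"
            channels.append(
                IsotopologueChannel(
                    name=name,
                    k=k,
                    j=j,
                    q1=transition.q1 + k * shift,
                    q3=base_q3 + j * shift,
                    ce=base_ce,
                    moiety_tag=_moiety_tag(k, j),
                )
            )
    return channels


def select_channels(
    ladder: list[IsotopologueChannel], policy: str
) -> list[IsotopologueChannel]:
    """Select an acquisition subset from a full (k, j) ladder.

    ``q3-tracks-fragment``
        the maximal-j channel per k (labels fill the fragment first);
    ``fragment-unlabeled``
        the j = 0 channels (labels confined to the remainder moiety);
    ``moiety-pure``
        channels whose remainder moiety is either fully unlabeled or fully
        labeled — the union of the fragment-filled series (j = k, while
        feasible) and the remainder-filled series (j = k - n_remainder).
        For a nucleotide monitored by base release this is the published
        acquisition set: base-only labeling for k <= n_frag, then a fully
        labeled ribose carrying the overflow;
    ``full-grid``
        everything.
    """
    if policy == "full-grid":
        return list(ladder)
    if policy == "moiety-pure":
        n_rem = max(ch.k - ch.j for ch in ladder)
        return [ch for ch in ladder if ch.k - ch.j in (0, n_rem)]
    if policy == "q3-tracks-fragment":
        best: dict[int, IsotopologueChannel] = {}
        for ch in ladder:
            if ch.k not in best or ch.j > best[ch.k].j:
                best[ch.k] = ch
        return [best[k] for k in sorted(best)]
    if policy == "fragment-unlabeled":
        return [ch for ch in ladder if ch.j == 0]
    raise ValueError(f"unknown channel-selection policy: {policy!r}")


def moiety_atoms(a: Analyte) -> dict[str, tuple[int, int]]:
    """Partition each element's atoms into (fragment, remainder) counts.

    Uses the underivatized molecular formula and the product-ion fragment
    formula; the remainder is the neutral-loss moiety (e.g. the ribose
    phosphate of a nucleotide monitored by base release).
    """
    if a.fragment_kind != FragmentKind.ION or a.fragment_formula is None:
        raise ValueError(f"{a.abbreviation}: fragment is not a product-ion formula")
    out: dict[str, tuple[int, int]] = {}
    for el in sorted(set(a.formula) | set(a.fragment_formula)):
        total = a.formula[el]
        frag = a.fragment_formula[el]
        if frag > total:
            # H can legitimately exceed (protonation/rearrangement); cap it.
            if el == "H":
                frag = total
            else:
                raise ValueError(
                    f"{a.abbreviation}: fragment has more {el} than precursor"
                )
        out[el] = (frag, total - frag)
    return out


def ladder_to_rows(channels: list[IsotopologueChannel]) -> list[dict]:
    """Flatten a ladder for CSV export as an acquisition list."""
    return [
        {
            "name": ch.name,
            "k": ch.k,
            "j": ch.j,
            "q1": ch.q1,
            "q3": ch.q3,
            "ce": ch.ce,
            "moiety_tag": ch.moiety_tag,
        }
        for ch in channels
    ]
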