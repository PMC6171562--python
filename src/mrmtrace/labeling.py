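"""Isotopologue-distribution analysis: MIDs, label incorporation, natural-
abundance correction and moiety-resolved labeling.

Per-channel areas from a labeling experiment become a mass isotopomer
distribution (MID, the normalized M+0..M+n vector).  Three presentation
formats are provided: percent label incorporation (100·(1−f₀), the labeled-
molecule fraction), the individual M+i intensities, and the fractional
distribution profile.  Mean atom enrichment (Σ i·fᵢ / n) is exposed as a
companion statistic.

Natural-abundance correction removes the contribution of naturally occurring
heavy isotopes (≈1.07% ¹³C, ≈0.36% ¹⁵N) by solving I = M·x with a
lower-triangular binomial convolution matrix and non-negative least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .chem import default_mass_table
from .isotopologues import LabelScheme

__all__ = [
    "IsotopologueDistribution",
    "MoietyLabeling",
    "fractional_distribution",
    "percent_label_incorporation",
    "mean_enrichment",
    "abundance_correction_matrix",
    "correct_natural_abundance",
    "moiety_labeling",
]


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Raw M+i intensities and normalized fractions for one analyte/sample."""

    analyte: str
    sample: str
    intensities: np.ndarray
    fractions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        I = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", I)
        object.__setattr__(self, "fractions", fractional_distribution(I))

    @property
    def n(self) -> int:
        return self.intensities.size - 1


def fractional_distribution(intensities: np.ndarray) -> np.ndarray:
    """Normalize M+i intensities to fractions summing to one."""
    I = np.asarray(intensities, dtype=float)
    if np.any(I < 0):
        raise ValueError("intensities must be non-negative")
    total = I.sum()
    if total <= 0:
        raise ValueError("all-zero intensity vector has no distribution")
    return I / total


def _check_normalized(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("fractions are not normalized (sum != 1)")
    return f


def percent_label_incorporation(fractions: np.ndarray) -> float:
    """Percent of molecules carrying at least one label: 100·(1−f₀)."""
    f = _check_normalized(fractions)
    return float(100.0 * f[1:].sum())


def mean_enrichment(fractions: np.ndarray, n_atoms: int) -> float:
    """Atom-weighted fractional enrichment Σ i·fᵢ / n ∈ [0, 1]."""
    f = _check_normalized(fractions)
    if n_atoms < 1 or f.size != n_atoms + 1:
        raise ValueError("fraction vector must have n_atoms + 1 entries")
    return float(np.dot(np.arange(f.size), f) / n_atoms)


def abundance_correction_matrix(
    n_channels: int, n_element_atoms: int, abundance: float
) -> np.ndarray:
    """Binomial natural-abundance convolution matrix M, lower triangular.

    ``M[i, j]`` is the probability that a molecule with ``j`` tracer labels is
    observed in channel M+i because ``i − j`` of its remaining
    ``n_element_atoms − j`` tracer-element atoms carry a natural heavy
    isotope.  Columns sum to one whenever the channel range covers the full
    binomial support.
    """
    if not 0.0 <= abundance < 1.0:
        raise ValueError("abundance must be in [0, 1)")
    M = np.zeros((n_channels, n_channels))
    for j in range(n_channels):
        n_unlabeled = max(n_element_atoms - j, 0)
        shifts = np.arange(n_channels - j)
        M[j:, j] = binom.pmf(shifts, n_unlabeled, abundance)
    return M


@dataclass(frozen=True)
class CorrectedDistribution:
    fractions: np.ndarray
    residual: float
    clipped_negative: bool


def correct_natural_abundance(
    intensities: np.ndarray,
    scheme: LabelScheme,
    n_extra_atoms: int = 0,
    abundance: float | None = None,
) -> CorrectedDistribution:
    """Remove natural heavy-isotope contributions from an observed MID.

    ``n_extra_atoms`` counts tracer-element atoms outside the labelable set
    (e.g. the seven carbons of each O-benzylhydroxylamine tag on a
    derivatized analyte) which still contribute natural abundance.  Solves
    ``I = M·x`` by non-negative least squares, then normalizes; a warning is
    attached when the unconstrained solution would have gone negative beyond
    numerical tolerance.
    """
    I = np.asarray(intensities, dtype=float)
    if I.size != scheme.n_total + 1:
        raise ValueError("intensity vector must have n_total + 1 channels")
    if abundance is None:
        abundance = default_mass_table().heavy_abundance[scheme.element]
    n_el = scheme.n_total + n_extra_atoms
    M = abundance_correction_matrix(I.size, n_el, abundance)
    x, rnorm = nnls(M, I)
    raw = np.linalg.solve(M, I) if abs(np.linalg.det(M)) > 1e-300 else x
    clipped = bool(np.any(raw < -1e-6 * max(I.sum(), 1.0)))
    if clipped:
        warnings.warn(
            "natural-abundance correction clipped negative channels; "
            "data may be noisy or the scheme mis-specified",
            stacklevel=2,
        )
    if x.sum() <= 0:
        raise ValueError("correction produced an all-zero distribution")
    return CorrectedDistribution(
        fractions=x / x.sum(), residual=float(rnorm), clipped_negative=clipped
    )


@dataclass(frozen=True)
class MoietyLabeling:
    """Labeled fractions attributed to the fragment and remainder moieties."""

    fragment_fraction: float
    remainder_fraction: float
    coverage_complete: bool

    def __post_init__(self) -> None:
        for x in (self.fragment_fraction, self.remainder_fraction):
            if not 0.0 <= x <= 1.0 + 1e-12:
                raise ValueError("moiety fractions must lie in [0, 1]")


def moiety_labeling(
    areas: dict[tuple[int, int], float], scheme: LabelScheme | None = None
) -> MoietyLabeling:
    """Attribute label to moieties from a full-grid (k, j) channel table.

    The fragment-moiety labeled fraction is the area share of channels with
    j ≥ 1 (at least one label in the fragment); the remainder-moiety fraction
    the share with k − j ≥ 1.  When a scheme is given, missing feasible
    channels are flagged via ``coverage_complete``.
    """
    if not areas:
        raise ValueError("no channel areas provided")
    if any(a < 0 for a in areas.values()):
        raise ValueError("areas must be non-negative")
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("total area is zero")
    frag = sum(a for (k, j), a in areas.items() if j >= 1)
    rem = sum(a for (k, j), a in areas.items() if k - j >= 1)
    complete = True
    if scheme is not None:
        expected = {
            (k, j)
            for k in range(scheme.n_total + 1)
            for j in range(scheme.n_frag + 1)
            if scheme.feasible(k, j)
        }
        complete = expected <= set(areas)
    return MoietyLabeling(
        fragment_fraction=frag / total,
        remainder_fraction=rem / total,
        coverage_complete=complete,
    )
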