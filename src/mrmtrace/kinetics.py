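"""Label-incorporation kinetics: tracer-strategy design, pool-chain
simulation, multi-input convolution and curve fitting.

The canonical model is first-order well-mixed pool turnover: a pool of size
``P`` fed at flux ``F`` relaxes its labeled fraction toward its donor's at
rate ``F/P``.  Chains of pools capture linear pathways; a recycle edge with a
mixing fraction captures cyclic ones; an exponent ``h`` on the donor fraction
stands in for cooperative (h > 1) or anti-cooperative (h < 1) regulation.
These are deliberately minimal interpretations of qualitative pathway
archetypes (flux high/low, regulation, number of inputs, linear/cyclic), not
a full isotopomer flux model.

Three labeling-experiment designs are supported by the enrichment
calculator: spiking tracer into running medium (diluted by the unlabeled
precursor already present), swapping to fully labeled medium (maximal but
perturbing), and conditioning on half-strength unlabeled precursor before
adding the other half as tracer, which caps initial downstream incorporation
near 50% while barely perturbing growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from lmfit import Model
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import binom

__all__ = [
    "Strategy",
    "StrategySpec",
    "PoolChainModel",
    "LabelingFit",
    "MoietyComparison",
    "precursor_enrichment",
    "simulate_chain",
    "simulate_multi_input",
    "fit_labeling_curve",
    "compare_moieties",
]


class Strategy(str, Enum):
    SPIKE_IN = "spike_in"
    MEDIUM_SWAP = "medium_swap"
    CONDITIONING = "conditioning"


@dataclass(frozen=True)
class StrategySpec:
    """Amounts (same arbitrary unit) defining a labeling-experiment design."""

    strategy: Strategy
    labeled: float
    unlabeled_medium: float = 0.0
    unlabeled_internal: float = 0.0

    def __post_init__(self) -> None:
        for x in (self.labeled, self.unlabeled_medium, self.unlabeled_internal):
            if x < 0:
                raise ValueError("amounts must be non-negative")


def precursor_enrichment(s: StrategySpec) -> float:
    """Initial labeled fraction of the precursor pool the cell draws from.

    labeled / (labeled + unlabeled in medium + unlabeled internal pool).
    A medium swap with no internal pool gives 1; the conditioning design
    with equal labeled and unlabeled halves gives 0.5.
    """
    total = s.labeled + s.unlabeled_medium + s.unlabeled_internal
    if total <= 0:
        raise ValueError("all amounts are zero")
    return s.labeled / total


@dataclass(frozen=True)
class PoolChainModel:
    """Chain of well-mixed pools turned over by a common flux.

    ``pool_sizes[i] > 0`` (amount units), ``flux > 0`` (amount/time, the
    user's time unit throughout), ``hill`` the cooperativity exponent on the
    donor labeled fraction, and for cyclic topology ``recycle_fraction`` of
    the first pool's influx is drawn from the last pool instead of the
    external precursor.  ``input_enrichment`` is the precursor labeled
    fraction, a constant or a function of time.
    """

    pool_sizes: tuple[float, ...]
    flux: float
    topology: str = "linear"  # "linear" | "cyclic"
    hill: float = 1.0
    recycle_fraction: float = 0.0
    input_enrichment: float | Callable[[float], float] = 1.0

    def __post_init__(self) -> None:
        if not self.pool_sizes or any(p <= 0 for p in self.pool_sizes):
            raise ValueError("pool sizes must be positive")
        if self.flux <= 0:
            raise ValueError("flux must be positive")
        if self.hill <= 0:
            raise ValueError("cooperativity exponent must be positive")
        if self.topology not in ("linear", "cyclic"):
            raise ValueError("topology must be linear or cyclic")
        if not 0.0 <= self.recycle_fraction < 1.0:
            raise ValueError("recycle fraction must be in [0, 1)")

    def input_at(self, t: float) -> float:
        u = (
            self.input_enrichment(t)
            if callable(self.input_enrichment)
            else self.input_enrichment
        )
        return float(np.clip(u, 0.0, 1.0))


def simulate_chain(model: PoolChainModel, times: Sequence[float]) -> np.ndarray:
    """Labeled-fraction trajectories, shape (n_pools, n_times).

    Solves dL_i/dt = (F/P_i)(donor_i^h − L_i) with donor_1 the external
    precursor enrichment (mixed with the recycled last pool for cyclic
    topology) and donor_i = L_{i−1} along the chain.  Pools start unlabeled.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 1 or t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be increasing and start at >= 0")
    rates = model.flux / np.asarray(model.pool_sizes)
    h = model.hill
    rho = model.recycle_fraction if model.topology == "cyclic" else 0.0

    def rhs(tt: float, L: np.ndarray) -> np.ndarray:
        L = np.clip(L, 0.0, 1.0)
        donor_first = (1.0 - rho) * model.input_at(tt) + rho * L[-1]
        donors = np.concatenate(([donor_first], L[:-1]))
        return rates * (np.power(donors, h) - L)

    t_span = (0.0, float(t[-1]) if t[-1] > 0 else 1e-9)
    sol = solve_ivp(
        rhs,
        t_span,
        np.zeros(len(model.pool_sizes)),
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"pool-chain integration failed: {sol.message}")
    return np.clip(sol.y, 0.0, 1.0)


def simulate_multi_input(
    moiety_fractions: Sequence[np.ndarray],
    atom_counts: Sequence[int],
    total_atoms: int | None = None,
) -> dict[str, np.ndarray]:
    """Combine independent moiety enrichments into isotopologue trajectories.

    Each moiety m contributes ``atom_counts[m]`` labelable atoms whose
    labeling is binomial at that moiety's enrichment; moieties label
    independently (they come from distinct pathways), so the M+k
    distribution is the convolution of the per-moiety binomials and the
    fully labeled species fraction the product of the per-moiety fully
    labeled fractions p_m^{n_m}.

    Returns ``{"distribution": (n_times, n_total+1), "fully_labeled": (n_times,)}``.
    """
    fracs = [np.atleast_1d(np.asarray(f, dtype=float)) for f in moiety_fractions]
    if len(fracs) != len(atom_counts) or not fracs:
        raise ValueError("need one atom count per moiety trajectory")
    if any(n < 1 for n in atom_counts):
        raise ValueError("atom counts must be positive")
    n_total = int(sum(atom_counts))
    if total_atoms is not None and n_total > total_atoms:
        raise ValueError("moiety composition exceeds the analyte's atom count")
    n_times = fracs[0].size
    if any(f.size != n_times for f in fracs):
        raise ValueError("moiety trajectories must share a time grid")
    if any(np.any((f < 0) | (f > 1)) for f in fracs):
        raise ValueError("moiety fractions must lie in [0, 1]")
    dist = np.zeros((n_times, n_total + 1))
    fully = np.ones(n_times)
    for ti in range(n_times):
        acc = np.array([1.0])
        for f, n in zip(fracs, atom_counts, strict=True):
            pmf = binom.pmf(np.arange(n + 1), n, f[ti])
            acc = np.convolve(acc, pmf)
            fully[ti] *= f[ti] ** n
        dist[ti] = acc
    return {"distribution": dist, "fully_labeled": fully}


@dataclass(frozen=True)
class LabelingFit:
    """Fitted description of a label-incorporation time course."""

    model: str  # "exponential" | "lagged" | "sigmoidal"
    plateau: float
    rate: float
    shape: float  # second rate (lagged) or Hill exponent (sigmoidal); 0 for exp
    residual_norm: float
    half_time: float
    converged: bool
    degenerate: bool = False
    params: dict = field(default_factory=dict)

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "exponential":
            return _exp_model(t, self.plateau, self.rate)
        if self.model == "lagged":
            return _lagged_model(t, self.plateau, self.rate, self.shape)
        return _hill_model(t, self.plateau, self.half_time, self.shape)


def _exp_model(t, plateau, rate):
    return plateau * (1.0 - np.exp(-rate * t))


def _lagged_model(t, plateau, k1, k2):
    # two-pool series closed form; stable as k2 -> k1
    if abs(k1 - k2) < 1e-9 * max(k1, k2, 1e-12):
        return plateau * (1.0 - (1.0 + k1 * t) * np.exp(-k1 * t))
    return plateau * (
        1.0 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1)
    )


def _hill_model(t, plateau, t50, hill):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = plateau * t[pos] ** hill / (t50**hill + t[pos] ** hill)
    return out


def fit_labeling_curve(
    times: Sequence[float],
    fractions: Sequence[float],
    model: str = "exponential",
) -> LabelingFit:
    """Least-squares fit of a labeling time course.

    Models: ``exponential`` A(1−e^{−kt}); ``lagged`` the two-pool series
    closed form (an initial lag before near-exponential rise); ``sigmoidal``
    the Hill-time form A·tʰ/(t50ʰ+tʰ).  All-zero (or near-zero) data is
    returned as a degenerate fit rather than an error.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size < 4 or t.size != y.size:
        raise ValueError("need >= 4 matched (time, fraction) points")
    if np.any((y < -1e-9) | (y > 1 + 1e-9)):
        raise ValueError("labeled fractions must lie in [0, 1]")
    ymax = float(y.max())
    if ymax < 1e-9:
        return LabelingFit(
            model=model,
            plateau=0.0,
            rate=np.nan,
            shape=0.0,
            residual_norm=float(np.linalg.norm(y)),
            half_time=np.inf,
            converged=True,
            degenerate=True,
        )
    t_scale = max(float(t[t > 0].min()) if np.any(t > 0) else 1.0, 1e-6)
    t50_guess = float(np.interp(ymax / 2, y, t)) or t_scale

    if model == "exponential":
        m = Model(_exp_model)
        params = m.make_params(plateau=ymax, rate=np.log(2) / max(t50_guess, t_scale))
    elif model == "lagged":
        m = Model(_lagged_model)
        k = np.log(2) / max(t50_guess, t_scale)
        params = m.make_params(plateau=ymax, k1=2 * k, k2=0.9 * k)
        params["k1"].set(min=1e-9)
        params["k2"].set(min=1e-9)
    elif model == "sigmoidal":
        m = Model(_hill_model)
        params = m.make_params(plateau=ymax, t50=max(t50_guess, t_scale), hill=2.0)
        params["t50"].set(min=1e-9)
        params["hill"].set(min=0.1, max=20)
    else:
        raise ValueError(f"unknown model: {model!r}")
    params["plateau"].set(min=0.0, max=1.0)
    if "rate" in params:
        params["rate"].set(min=1e-9)

    result = m.fit(y, params, t=t)
    p = result.params
    plateau = float(p["plateau"].value)
    if model == "exponential":
        rate, shape = float(p["rate"].value), 0.0
        half_time = np.log(2) / rate if rate > 0 else np.inf
    elif model == "lagged":
        rate, shape = float(p["k1"].value), float(p["k2"].value)
        half_time = _numeric_half_time(
            lambda tt: _lagged_model(tt, 1.0, rate, shape), t[-1]
        )
    else:
        shape = float(p["hill"].value)
        half_time = float(p["t50"].value)
        rate = np.log(2) / half_time if half_time > 0 else np.inf
    return LabelingFit(
        model=model,
        plateau=plateau,
        rate=rate,
        shape=shape,
        residual_norm=float(np.linalg.norm(result.residual)),
        half_time=float(half_time),
        converged=bool(result.success),
        degenerate=plateau < 1e-6,
        params={k: float(v.value) for k, v in p.items()},
    )


def _numeric_half_time(unit_curve: Callable, t_max: float) -> float:
    """Time at which a unit-plateau curve crosses 0.5 (searched past t_max)."""
    hi = max(t_max, 1.0)
    for _ in range(60):
        if unit_curve(hi) >= 0.5:
            return brentq(lambda tt: unit_curve(tt) - 0.5, 1e-12, hi)
        hi *= 2
    return np.inf


@dataclass(frozen=True)
class MoietyComparison:
    """Relative labeling speed of two moieties (e.g. ribose vs base)."""

    rate_ratio: float
    half_time_ratio: float
    rate_ratio_ci: tuple[float, float] | None = None
    faster: str = "first"


def compare_moieties(
    fit_fast: LabelingFit,
    fit_slow: LabelingFit,
    data_fast: tuple[Sequence[float], Sequence[float]] | None = None,
    data_slow: tuple[Sequence[float], Sequence[float]] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> MoietyComparison:
    """Rate and half-time ratios between two fitted moiety time courses.

    With the underlying data supplied, a residual-resampling bootstrap
    (refitting both curves ``n_boot`` times) yields a 95% percentile
    interval on the rate ratio.
    """
    for f in (fit_fast, fit_slow):
        if f.degenerate or not f.converged:
            raise ValueError("cannot compare degenerate or unconverged fits")
    ratio = fit_fast.rate / fit_slow.rate
    ht_ratio = fit_slow.half_time / fit_fast.half_time
    ci = None
    if data_fast is not None and data_slow is not None:
        rng = np.random.default_rng(seed)
        ratios = []
        sets = []
        for fit, (tt, yy) in ((fit_fast, data_fast), (fit_slow, data_slow)):
            tt = np.asarray(tt, dtype=float)
            yy = np.asarray(yy, dtype=float)
            resid = yy - fit.curve(tt)
            sets.append((fit, tt, yy, resid))
        for _ in range(n_boot):
            rates = []
            for fit, tt, yy, resid in sets:
                yboot = np.clip(
                    fit.curve(tt) + rng.choice(resid, size=resid.size), 0.0, 1.0
                )
                try:
                    refit = fit_labeling_curve(tt, yboot, model=fit.model)
                except (ValueError, RuntimeError):
                    rates.append(np.nan)
                    continue
                rates.append(refit.rate if not refit.degenerate else np.nan)
            if np.all(np.isfinite(rates)) and rates[1] > 0:
                ratios.append(rates[0] / rates[1])
        if len(ratios) >= max(20, n_boot // 4):
            ci = (
                float(np.percentile(ratios, 2.5)),
                float(np.percentile(ratios, 97.5)),
            )
    return MoietyComparison(
        rate_ratio=float(ratio),
        half_time_ratio=float(ht_ratio),
        rate_ratio_ci=ci,
        faster="first" if ratio >= 1 else "second",
    )
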