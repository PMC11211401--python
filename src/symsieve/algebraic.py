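"""Discrete-generation recursion for the frequency of hosts carrying an
augmented symbiont community, and the analytic invasion condition.

The model tracks the frequency ``p`` of hosts whose symbiont community has
been augmented by a new taxon (community ``S``) against hosts with the
resident community ``s``, under random mating and vertical transmission with
per-parent transmission probabilities ``alpha`` (mother) and ``beta``
(father).  Generations are discrete and non-overlapping, the population is
effectively infinite (no drift), and selection acts through the relative
fitness ``w`` of carrier hosts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoVerticalTransmissionError",
    "TransmissionParams",
    "SymbiontFitness",
    "FrequencyState",
    "offspring_carriage_probs",
    "mean_fitness",
    "next_frequency",
    "delta_p",
    "invasion_threshold",
    "iterate_generations",
    "recursion_outcome",
]

#: tolerance used to absorb floating-point excursions of p outside [0, 1]
_CLIP_TOL = 1e-12


class NoVerticalTransmissionError(ValueError):
    """Raised when alpha = beta = 0 leaves the symbiont no vertical route."""


@dataclass(frozen=True)
class TransmissionParams:
    """Per-parent vertical-transmission probabilities.

    Parameters
    ----------
    alpha
        Probability that the mother passes the augmented community on.
    beta
        Probability that the father passes it on.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")

    @classmethod
    def biparental(cls) -> "TransmissionParams":
        return cls(1.0, 1.0)

    @classmethod
    def maternal(cls) -> "TransmissionParams":
        return cls(1.0, 0.0)

    @classmethod
    def paternal(cls) -> "TransmissionParams":
        return cls(0.0, 1.0)

    @classmethod
    def from_mode(cls, mode: str) -> "TransmissionParams":
        try:
            return {"biparental": cls.biparental,
                    "maternal": cls.maternal,
                    "paternal": cls.paternal}[mode]()
        except KeyError:
            raise ValueError(f"unknown transmission mode {mode!r}") from None

    def phi(self, p: float) -> float:
        """phi = alpha + beta - alpha*beta*p, the transmission factor."""
        return self.alpha + self.beta - self.alpha * self.beta * p


@dataclass(frozen=True)
class SymbiontFitness:
    """Relative fitness w > 0 of carrier hosts versus non-carriers."""

    w: float

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"w must be positive, got {self.w}")


@dataclass(frozen=True)
class FrequencyState:
    """Frequency p of carrier hosts, with derived quantities."""

    p: float

    def __post_init__(self) -> None:
        _check_p(self.p)

    @property
    def q(self) -> float:
        return 1.0 - self.p

    def phi(self, tp: TransmissionParams) -> float:
        return tp.phi(self.p)

    def mean_fitness(self, w, tp: TransmissionParams) -> float:
        return mean_fitness(self.p, w, tp)


def _check_p(p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"frequency p must lie in [0, 1], got {p}")


def _w_value(w) -> float:
    wv = w.w if isinstance(w, SymbiontFitness) else float(w)
    if not wv > 0:
        raise ValueError(f"w must be positive, got {wv}")
    return wv


def offspring_carriage_probs(tp: TransmissionParams) -> dict[str, tuple[float, float]]:
    """Offspring carriage probabilities for the four mating classes.

    Returns a mapping from mating class (mother listed first) to the pair
    ``(P(S), P(s))``: probabilities that the offspring carries the augmented
    community or not.  Each pair sums to one.
    """
    a, b = tp.alpha, tp.beta
    return {
        "sxs": (0.0, 1.0),
        "Sxs": (a, 1.0 - a),
        "sxS": (b, 1.0 - b),
        "SxS": (a + b - a * b, (1.0 - a) * (1.0 - b)),
    }


def mean_fitness(p: float, w, tp: TransmissionParams) -> float:
    """Mean fitness of the next generation, w_bar = 1 - p(1-w)(a+b-abp)."""
    _check_p(p)
    wv = _w_value(w)
    return 1.0 - p * (1.0 - wv) * tp.phi(p)


def next_frequency(p: float, w, tp: TransmissionParams) -> float:
    """One generation of the carrier-frequency recursion.

    p' = (p w / w_bar) (alpha + beta - alpha beta p).  The result is clipped
    to [0, 1] only within a rounding tolerance; larger excursions indicate a
    bug and raise.
    """
    _check_p(p)
    wv = _w_value(w)
    wbar = mean_fitness(p, wv, tp)
    p_next = (p * wv / wbar) * tp.phi(p)
    if p_next < -_CLIP_TOL or p_next > 1.0 + _CLIP_TOL:
        raise FloatingPointError(
            f"recursion produced p' = {p_next} outside [0, 1] beyond tolerance")
    return min(max(p_next, 0.0), 1.0)


def delta_p(p: float, w, tp: TransmissionParams) -> float:
    """Per-generation change Delta p = (p / w_bar)(phi (p + w q) - 1)."""
    _check_p(p)
    wv = _w_value(w)
    q = 1.0 - p
    phi = tp.phi(p)
    wbar = mean_fitness(p, wv, tp)
    return (p / wbar) * (phi * (p + wv * q) - 1.0)


def invasion_threshold(tp: TransmissionParams) -> float:
    """Rare-symbiont invasion threshold w0 = 1 / (alpha + beta).

    This is the fitness at which delta_p changes sign as p -> 0+.  With no
    vertical route at all (alpha = beta = 0) the threshold is undefined.
    """
    s = tp.alpha + tp.beta
    if s == 0.0:
        raise NoVerticalTransmissionError(
            "alpha = beta = 0: no vertical transmission route, "
            "invasion threshold undefined")
    return 1.0 / s


def iterate_generations(p0: float, w, tp: TransmissionParams,
                        n_gen: int) -> np.ndarray:
    """Trajectory [p0, p1, ..., p_n_gen] of repeated recursion steps."""
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    _check_p(p0)
    traj = np.empty(n_gen + 1)
    traj[0] = p0
    p = p0
    for g in range(1, n_gen + 1):
        p = next_frequency(p, w, tp)
        traj[g] = p
    return traj


def recursion_outcome(p0: float, w, tp: TransmissionParams,
                      tol: float = 1e-6, max_gen: int = 10_000) -> str:
    """Classify the long-run fate of the recursion from p0.

    Returns ``"loss"`` when p falls within ``tol`` of 0, ``"fixation"``
    within ``tol`` of 1, and ``"undecided"`` if neither happens within
    ``max_gen`` generations.
    """
    _check_p(p0)
    p = p0
    for _ in range(max_gen):
        if p < tol:
            return "loss"
        if p > 1.0 - tol:
            return "fixation"
        p = next_frequency(p, w, tp)
    if p < tol:
        return "loss"
    if p > 1.0 - tol:
        return "fixation"
    return "undecided"
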