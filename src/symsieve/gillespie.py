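"""Continuous-time, sex-structured stochastic birth-death process with
vertical (and optional horizontal) symbiont transmission.

Hosts are individuals with a sex, a set of carried symbiont taxa, and (for
males, when transmission-modifier alleles are active) a Y-linked allele that
switches their matings between the biparental and maternal transmission
rules.  The process is advanced by the exact Gillespie algorithm.

Individuals within a (sex, carriage, allele) class are exchangeable, so the
population is stored as class counts; every event (birth with uniformly
chosen mother and father, per-individual density-dependent death, horizontal
uptake) is sampled exactly from the class-level rates.  A specialised
single-taxon loop in :mod:`symsieve._fastloop` handles the common protocols;
this module holds the general engine used for multi-taxon runs and direct
unit-level event access.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .algebraic import TransmissionParams
from . import _fastloop

__all__ = [
    "FEMALE", "MALE", "M_PLUS", "M_MINUS",
    "DemographyParams", "SymbiontPool", "HostIndividual", "PopulationState",
    "RealisationResult",
    "host_fitness_effect", "death_rate", "birth_event",
    "horizontal_uptake_event", "gillespie_step", "run_realisation",
    "sample_w", "disequilibrium_D",
]

FEMALE = "female"
MALE = "male"
M_PLUS = "M+"
M_MINUS = "M-"

# class key layout: (sex, carriage frozenset, y_allele or None)
_SEX, _CARRIAGE, _ALLELE = 0, 1, 2


@dataclass(frozen=True)
class DemographyParams:
    """Host demography: per-female birth rate b0, intrinsic death rate d0,
    density-dependent death coefficient dprime, horizontal uptake rate e0."""

    b0: float = 4.0
    d0: float = 1.0
    dprime: float = 0.001
    e0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("b0", "d0", "dprime", "e0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def carrying_capacity(self) -> float:
        """Symbiont-free equilibrium population size (b0/2 - d0)/dprime."""
        return (self.b0 / 2.0 - self.d0) / self.dprime


@dataclass(frozen=True)
class SymbiontPool:
    """Fitness effect w_i of each symbiont taxon on its host."""

    w_list: tuple

    def __init__(self, w_list: Sequence[float]):
        w = tuple(float(v) for v in w_list)
        if len(w) < 1:
            raise ValueError("pool must contain at least one taxon")
        if any(v <= 0 for v in w):
            raise ValueError("all fitness effects must be positive")
        object.__setattr__(self, "w_list", w)

    def __len__(self) -> int:
        return len(self.w_list)


@dataclass(frozen=True)
class HostIndividual:
    sex: str
    carriage: frozenset = frozenset()
    y_allele: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be {FEMALE!r} or {MALE!r}")
        if self.sex == FEMALE and self.y_allele is not None:
            raise ValueError("females carry no Y-linked allele")
        if self.y_allele not in (None, M_PLUS, M_MINUS):
            raise ValueError(f"invalid y_allele {self.y_allele!r}")
        object.__setattr__(self, "carriage", frozenset(self.carriage))

    @property
    def key(self) -> tuple:
        return (self.sex, self.carriage, self.y_allele)


class PopulationState:
    """Full host population at a time point, plus its random generator.

    Internally a mapping from (sex, carriage, allele) class to count;
    individuals within a class are exchangeable under every event rule, so
    this is an exact representation of the individual-based process.
    """

    def __init__(self, counts: dict, t: float = 0.0, seed: int | None = None,
                 rng: random.Random | None = None):
        self.counts = {k: int(v) for k, v in counts.items() if v > 0}
        self.t = float(t)
        self.rng = rng if rng is not None else random.Random(seed)

    @classmethod
    def from_individuals(cls, individuals: Iterable[HostIndividual],
                         t: float = 0.0, seed: int | None = None,
                         rng: random.Random | None = None) -> "PopulationState":
        counts: dict = {}
        for ind in individuals:
            counts[ind.key] = counts.get(ind.key, 0) + 1
        return cls(counts, t=t, seed=seed, rng=rng)

    @property
    def individuals(self) -> list[HostIndividual]:
        out = []
        for (sex, carriage, allele), cnt in sorted(
                self.counts.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]),
                                                     str(kv[0][2]))):
            out.extend(HostIndividual(sex, carriage, allele)
                       for _ in range(cnt))
        return out

    @property
    def rng_state(self):
        return self.rng.getstate()

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def n_females(self) -> int:
        return sum(c for k, c in self.counts.items() if k[_SEX] == FEMALE)

    def n_males(self) -> int:
        return sum(c for k, c in self.counts.items() if k[_SEX] == MALE)

    def n_plus(self, taxon: int = 0) -> int:
        return sum(c for k, c in self.counts.items() if taxon in k[_CARRIAGE])

    def n_minus(self, taxon: int = 0) -> int:
        return sum(c for k, c in self.counts.items()
                   if taxon not in k[_CARRIAGE])

    def carriage_sets(self) -> set:
        return {k[_CARRIAGE] for k in self.counts}

    def copy(self, seed: int | None = None) -> "PopulationState":
        st = PopulationState(dict(self.counts), t=self.t, seed=seed)
        if seed is None:
            st.rng.setstate(self.rng.getstate())
        return st

    def _add(self, key: tuple, delta: int) -> None:
        c = self.counts.get(key, 0) + delta
        if c < 0:
            raise RuntimeError(f"negative count for class {key}")
        if c == 0:
            self.counts.pop(key, None)
        else:
            self.counts[key] = c


@dataclass
class RealisationResult:
    """Outcome record of one stochastic realisation."""

    outcome: str  # fixation | loss | host_extinction | timeout
    t_end: float
    trajectory: pd.DataFrame
    seed: int | None
    final_counts: dict | tuple
    w: float | None = None
    extras: dict = field(default_factory=dict)


def host_fitness_effect(carriage: Iterable[int], pool: SymbiontPool) -> float:
    """Mean of w_i over carried taxa; 1 for an empty carriage set."""
    carriage = list(carriage)
    if not carriage:
        return 1.0
    return sum(pool.w_list[i] for i in carriage) / len(carriage)


def death_rate(ind: HostIndividual, n: int, dp: DemographyParams,
               pool: SymbiontPool) -> float:
    """Per-capita death rate (d0 + d' n) / w_eff.

    The fitness factor 1/w multiplies the whole rate, intrinsic and
    density-dependent parts alike.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return (dp.d0 + dp.dprime * n) / host_fitness_effect(ind.carriage, pool)


def _class_fitness(carriage: frozenset, pool: SymbiontPool,
                   cache: dict) -> float:
    try:
        return cache[carriage]
    except KeyError:
        w = host_fitness_effect(carriage, pool)
        cache[carriage] = w
        return w


def _pick_class(items: list, weights: list, r: float) -> tuple:
    acc = 0.0
    for key, wgt in zip(items, weights):
        acc += wgt
        if r < acc:
            return key
    return items[-1]  # guard against float round-off at the top end


def _resolve_mode(mode):
    """Return ('params', TransmissionParams) or ('modifier', None)."""
    if mode == "modifier":
        return "modifier", None
    if isinstance(mode, str):
        return "params", TransmissionParams.from_mode(mode)
    if isinstance(mode, TransmissionParams):
        return "params", mode
    raise ValueError(f"unsupported transmission mode {mode!r}")


def _child_carriage(mother: tuple, father: tuple, kind: str,
                    tp: TransmissionParams | None,
                    rng: random.Random) -> frozenset:
    m_car, f_car = mother[_CARRIAGE], father[_CARRIAGE]
    if kind == "modifier":
        if father[_ALLELE] == M_PLUS:
            return m_car | f_car
        return m_car
    a, b = tp.alpha, tp.beta
    if a == 1.0 and b == 1.0:
        return m_car | f_car
    if a == 1.0 and b == 0.0:
        return m_car
    if a == 0.0 and b == 1.0:
        return f_car
    taken = set()
    for taxon in m_car:
        if rng.random() < a:
            taken.add(taxon)
    for taxon in f_car:
        if taxon not in taken and rng.random() < b:
            taken.add(taxon)
    return frozenset(taken)


def birth_event(state: PopulationState, mode, dp: DemographyParams,
                pool: SymbiontPool) -> PopulationState:
    """Apply one birth: uniform mother among females, uniform father among
    males, offspring sex 1:1, carriage set by the transmission rule, sons
    inheriting the father's Y allele."""
    kind, tp = _resolve_mode(mode)
    rng = state.rng
    fem = [(k, c) for k, c in state.counts.items() if k[_SEX] == FEMALE]
    mal = [(k, c) for k, c in state.counts.items() if k[_SEX] == MALE]
    n_f = sum(c for _, c in fem)
    n_m = sum(c for _, c in mal)
    if n_f == 0 or n_m == 0:
        raise ValueError("birth requires at least one female and one male")
    mother = _pick_class([k for k, _ in fem], [c for _, c in fem],
                         rng.random() * n_f)
    father = _pick_class([k for k, _ in mal], [c for _, c in mal],
                         rng.random() * n_m)
    carriage = _child_carriage(mother, father, kind, tp, rng)
    if rng.random() < 0.5:
        child = (FEMALE, carriage, None)
    else:
        allele = father[_ALLELE] if kind == "modifier" else None
        child = (MALE, carriage, allele)
    state._add(child, +1)
    return state


def horizontal_uptake_event(state: PopulationState, focal_taxon: int,
                            dp: DemographyParams) -> PopulationState:
    """One uniformly chosen non-carrier acquires the focal taxon."""
    non = [(k, c) for k, c in state.counts.items()
           if focal_taxon not in k[_CARRIAGE]]
    n_non = sum(c for _, c in non)
    if n_non == 0:
        raise ValueError("no non-carriers available for uptake")
    key = _pick_class([k for k, _ in non], [c for _, c in non],
                      state.rng.random() * n_non)
    state._add(key, -1)
    state._add((key[_SEX], key[_CARRIAGE] | {focal_taxon}, key[_ALLELE]), +1)
    return state


def gillespie_step(state: PopulationState, dp: DemographyParams,
                   pool: SymbiontPool, mode,
                   focal_taxon: int = 0) -> tuple[PopulationState, str]:
    """Advance the population by exactly one event.

    Samples the waiting time from Exp(total rate) and picks the event with
    probability proportional to its rate.  Returns the (mutated) state and
    the event label, one of ``"birth"``, ``"death"``, ``"uptake"``.
    """
    n = state.n
    if n == 0:
        raise ValueError("population is extinct: no events possible")
    rng = state.rng
    n_f = state.n_females()
    n_m = n - n_f
    birth_rate = dp.b0 * n_f if n_m > 0 else 0.0
    dbase = dp.d0 + dp.dprime * n
    wcache: dict = {}
    keys = list(state.counts.keys())
    dweights = [state.counts[k] * dbase
                / _class_fitness(k[_CARRIAGE], pool, wcache) for k in keys]
    death_total = sum(dweights)
    n_non = state.n_minus(focal_taxon)
    uptake_rate = dp.e0 * n_non
    total = birth_rate + death_total + uptake_rate
    if total <= 0.0:
        raise RuntimeError("total event rate is zero")
    state.t += rng.expovariate(total)
    r = rng.random() * total
    if r < birth_rate:
        birth_event(state, mode, dp, pool)
        return state, "birth"
    if r < birth_rate + death_total:
        key = _pick_class(keys, dweights, r - birth_rate)
        state._add(key, -1)
        return state, "death"
    horizontal_uptake_event(state, focal_taxon, dp)
    return state, "uptake"


def _male_class_freqs(counts: dict, focal_taxon: int = 0):
    """(p1, p2, p3, p4) over male classes (M-,-), (M-,+), (M+,-), (M+,+)."""
    tallies = [0, 0, 0, 0]
    for (sex, carriage, allele), c in counts.items():
        if sex != MALE:
            continue
        carrier = focal_taxon in carriage
        if allele == M_MINUS:
            tallies[1 if carrier else 0] += c
        elif allele == M_PLUS:
            tallies[3 if carrier else 2] += c
    n_m = sum(tallies)
    if n_m == 0:
        return None
    return tuple(t / n_m for t in tallies)


def disequilibrium_D(males: Iterable[HostIndividual],
                     focal_taxon: int = 0) -> float:
    """Coefficient of disequilibrium D = p1 p4 - p2 p3 over the four male
    classes (allele x carriage); positive when the symbiont is
    under-represented in transmission-suppressing males."""
    counts: dict = {}
    for ind in males:
        if ind.sex != MALE:
            raise ValueError("disequilibrium_D expects male individuals")
        counts[ind.key] = counts.get(ind.key, 0) + 1
    freqs = _male_class_freqs(counts, focal_taxon)
    if freqs is None:
        raise ValueError("D is undefined for an empty male set")
    p1, p2, p3, p4 = freqs
    return p1 * p4 - p2 * p3


def sample_w(n: int, mean: float = 1.0, sd: float = 0.3,
             lo: float = 0.0, hi: float = 2.5,
             seed: int | None = None,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Draws from Normal(mean, sd) truncated to [lo, hi], by rejection."""
    if not lo < hi:
        raise ValueError("truncation interval is degenerate (need lo < hi)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return out


# ---------------------------------------------------------------------------
# realisation drivers


def _counts_to_six(counts: dict, mode_kind: str, preset: str | None):
    """Map a single-taxon class dict onto the 6-class fast-loop layout
    (fp, fm, yp, ym, zp, zm); returns None if not representable."""
    fp = fm = yp = ym = zp = zm = 0
    for (sex, carriage, allele), c in counts.items():
        if not carriage <= {0}:
            return None
        car = 0 in carriage
        if sex == FEMALE:
            fp, fm = (fp + c, fm) if car else (fp, fm + c)
            continue
        if mode_kind == "modifier":
            if allele == M_MINUS:
                yp, ym = (yp + c, ym) if car else (yp, ym + c)
            elif allele == M_PLUS:
                zp, zm = (zp + c, zm) if car else (zp, zm + c)
            else:
                return None
        else:
            if allele is not None:
                return None
            if preset == "maternal":
                yp, ym = (yp + c, ym) if car else (yp, ym + c)
            else:
                zp, zm = (zp + c, zm) if car else (zp, zm + c)
    return fp, fm, yp, ym, zp, zm


def _six_to_counts(six, mode_kind: str, preset: str | None) -> dict:
    fp, fm, yp, ym, zp, zm = six
    car, empty = frozenset({0}), frozenset()
    counts = {}
    if mode_kind == "modifier":
        entries = [((FEMALE, car, None), fp), ((FEMALE, empty, None), fm),
                   ((MALE, car, M_MINUS), yp), ((MALE, empty, M_MINUS), ym),
                   ((MALE, car, M_PLUS), zp), ((MALE, empty, M_PLUS), zm)]
    else:
        entries = [((FEMALE, car, None), fp), ((FEMALE, empty, None), fm),
                   ((MALE, car, None), yp + zp), ((MALE, empty, None), ym + zm)]
    for k, c in entries:
        if c > 0:
            counts[k] = c
    return counts


def _fast_trajectory(recs, with_modifier: bool) -> pd.DataFrame:
    arr = np.asarray(recs, dtype=float)
    t = arr[:, 0]
    fp, fm, yp, ym, zp, zm = (arr[:, i] for i in range(1, 7))
    df = pd.DataFrame({
        "t": t,
        "n_plus": fp + yp + zp,
        "n_minus": fm + ym + zm,
        "n": fp + fm + yp + ym + zp + zm,
    })
    if with_modifier:
        n_m = yp + ym + zp + zm
        with np.errstate(invalid="ignore", divide="ignore"):
            p1, p2, p3, p4 = ym / n_m, yp / n_m, zm / n_m, zp / n_m
        df["p1"], df["p2"], df["p3"], df["p4"] = p1, p2, p3, p4
        df["D"] = p1 * p4 - p2 * p3
        df["m_minus_freq"] = p1 + p2
    return df


def run_realisation(init: PopulationState, dp: DemographyParams,
                    pool: SymbiontPool, mode, t_max: float = 200.0,
                    seed: int | None = None, sample_dt: float = 0.5,
                    focal_taxon: int = 0,
                    stop: str | None = "focal") -> RealisationResult:
    """Run one realisation until fixation/loss of the focal taxon, host
    extinction, or ``t_max``.

    ``stop="focal"`` terminates when the focal taxon is present in all or
    absent from all hosts; ``stop=None`` runs to ``t_max`` regardless
    (used e.g. for demographic baselines and ensemble/ODE overlays).
    Fully reproducible from ``seed``.
    """
    kind, tp = _resolve_mode(mode)
    preset = None
    if kind == "params":
        if (tp.alpha, tp.beta) == (1.0, 1.0):
            preset = "biparental"
        elif (tp.alpha, tp.beta) == (1.0, 0.0):
            preset = "maternal"
    six = None
    if len(pool) == 1 and focal_taxon == 0 and (kind == "modifier"
                                                or preset is not None):
        six = _counts_to_six(init.counts, kind, preset)
    if six is not None:
        outcome, t_end, recs, final = _fastloop.run_six_class(
            six, dp.b0, dp.d0, dp.dprime, dp.e0, pool.w_list[0],
            t_max, sample_dt, seed,
            stop_on_focal=(stop == "focal"), t0=init.t)
        traj = _fast_trajectory(recs, with_modifier=(kind == "modifier"))
        return RealisationResult(outcome, t_end, traj, seed,
                                 _six_to_counts(final, kind, preset),
                                 w=pool.w_list[0])
    return _run_general(init, dp, pool, mode, t_max, seed, sample_dt,
                        focal_taxon, stop)


def _run_general(init: PopulationState, dp, pool, mode, t_max, seed,
                 sample_dt, focal_taxon, stop) -> RealisationResult:
    state = init.copy(seed=seed)
    recs = []
    next_s = state.t
    outcome = None
    while True:
        n = state.n
        n_plus = state.n_plus(focal_taxon)
        if n == 0:
            outcome = "host_extinction"
            break
        if stop == "focal":
            if n_plus == 0:
                outcome = "loss"
                break
            if n_plus == n:
                outcome = "fixation"
                break
        while next_s <= min(state.t, t_max):
            recs.append((next_s, n_plus, n - n_plus))
            next_s += sample_dt
        if state.t >= t_max:
            state.t = t_max
            outcome = "timeout"
            break
        pre_t = state.t
        gillespie_step(state, dp, pool, mode, focal_taxon)
        while next_s <= min(state.t, t_max) and next_s > pre_t:
            recs.append((next_s, n_plus, n - n_plus))
            next_s += sample_dt
    n = state.n
    n_plus = state.n_plus(focal_taxon)
    recs.append((state.t, n_plus, n - n_plus))
    traj = pd.DataFrame(np.asarray(recs, dtype=float),
                        columns=["t", "n_plus", "n_minus"])
    traj["n"] = traj["n_plus"] + traj["n_minus"]
    return RealisationResult(outcome, state.t, traj, seed,
                             dict(state.counts))
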