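"""Ensemble drivers binding the stochastic engine to the experiment protocols.

Protocols:

* ``sieve`` -- single new symbiont with a fresh fitness effect drawn per
  realisation from the truncated normal pool; fate tracked to fixation or
  loss (the sieve experiment).
* ``multitaxon`` -- twenty taxa independently inoculated into a fraction of
  hosts; taxa-per-host histograms tracked over time.
* ``modifier`` -- Y-linked transmission-modifier alleles segregating during
  invasion of a deleterious symbiont; disequilibrium D tracked.
* ``overlay`` -- modifier run with horizontal uptake, sampled on a fixed
  time window for comparison against the six-type ODE solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gillespie import (
    FEMALE, MALE, M_PLUS, M_MINUS,
    DemographyParams, SymbiontPool, HostIndividual, PopulationState,
    RealisationResult, gillespie_step, run_realisation, sample_w,
)
from .ode import ODEState6

__all__ = [
    "MultiTaxonResult",
    "rep_seed_streams",
    "build_initial_population",
    "build_multitaxon_population",
    "overlay_initial_counts",
    "overlay_ode_init",
    "run_sieve_ensemble",
    "run_modifier_ensemble",
    "run_overlay_ensemble",
    "run_multitaxon_realisation",
    "run_multitaxon_ensemble",
    "run_ensemble",
]


def rep_seed_streams(root_seed: int, n_reps: int):
    """Per-realisation (init rng, run seed) pairs derived from one root seed.

    Each realisation gets an independent numpy generator (initial-condition
    and parameter draws) and an integer seed for the event loop, both spawned
    from the recorded root so ensembles are reproducible and
    order-independent.
    """
    children = np.random.SeedSequence(root_seed).spawn(n_reps)
    out = []
    for child in children:
        c_init, c_run = child.spawn(2)
        out.append((np.random.default_rng(c_init),
                    int(c_run.generate_state(1)[0])))
    return out


def build_initial_population(n_hosts: int, n_carriers: int,
                             rng: np.random.Generator,
                             m_minus_frac: float = 0.0,
                             modifier: bool = False,
                             exact_sex_split: bool = False) -> PopulationState:
    """Founding population: sexes 1:1 (random by default, exact on request),
    carriers of taxon 0 placed uniformly without replacement irrespective of
    sex, and (modifier runs) the suppressing allele assigned to a fraction
    of males uniformly at random."""
    if n_carriers > n_hosts:
        raise ValueError("more carriers than hosts")
    if exact_sex_split:
        is_female = np.zeros(n_hosts, dtype=bool)
        is_female[: n_hosts // 2] = True
    else:
        is_female = rng.random(n_hosts) < 0.5
    carrier = np.zeros(n_hosts, dtype=bool)
    carrier[rng.choice(n_hosts, size=n_carriers, replace=False)] = True
    allele = np.full(n_hosts, None, dtype=object)
    if modifier:
        males = np.flatnonzero(~is_female)
        allele[males] = M_PLUS
        n_minus = int(round(m_minus_frac * len(males)))
        if n_minus > 0:
            allele[rng.choice(males, size=n_minus, replace=False)] = M_MINUS
    inds = [HostIndividual(FEMALE if is_female[i] else MALE,
                           frozenset({0}) if carrier[i] else frozenset(),
                           allele[i] if not is_female[i] else None)
            for i in range(n_hosts)]
    return PopulationState.from_individuals(inds)


def build_multitaxon_population(n_hosts: int, n_taxa: int, n_inoculated: int,
                                rng: np.random.Generator,
                                exact_sex_split: bool = False) -> PopulationState:
    """Each taxon independently inoculated into ``n_inoculated`` hosts."""
    if exact_sex_split:
        is_female = np.zeros(n_hosts, dtype=bool)
        is_female[: n_hosts // 2] = True
    else:
        is_female = rng.random(n_hosts) < 0.5
    carriage = [set() for _ in range(n_hosts)]
    for taxon in range(n_taxa):
        for i in rng.choice(n_hosts, size=n_inoculated, replace=False):
            carriage[i].add(taxon)
    inds = [HostIndividual(FEMALE if is_female[i] else MALE,
                           frozenset(carriage[i]))
            for i in range(n_hosts)]
    return PopulationState.from_individuals(inds)


def run_sieve_ensemble(mode: str, n_reps: int, root_seed: int, *,
                       n_hosts: int = 1000, n_carriers: int = 10,
                       dp: DemographyParams | None = None,
                       t_max: float = 200.0, sample_dt: float = 0.5,
                       w_mean: float = 1.0, w_sd: float = 0.3,
                       w_lo: float = 0.0, w_hi: float = 2.5,
                       exact_sex_split: bool = False) -> list[RealisationResult]:
    """Fate of a single new symbiont; a fresh w is drawn per realisation."""
    dp = dp or DemographyParams()
    results = []
    for rng, run_seed in rep_seed_streams(root_seed, n_reps):
        w = float(sample_w(1, w_mean, w_sd, w_lo, w_hi, rng=rng)[0])
        init = build_initial_population(n_hosts, n_carriers, rng,
                                        exact_sex_split=exact_sex_split)
        res = run_realisation(init, dp, SymbiontPool([w]), mode,
                              t_max=t_max, seed=run_seed,
                              sample_dt=sample_dt)
        results.append(res)
    return results


def run_modifier_ensemble(n_reps: int, root_seed: int, *, w: float = 0.6,
                          n_hosts: int = 1000, n_carriers: int = 10,
                          m_minus_frac: float = 0.1,
                          dp: DemographyParams | None = None,
                          t_max: float = 200.0,
                          sample_dt: float = 0.5,
                          exact_sex_split: bool = False) -> list[RealisationResult]:
    """Invasion of a deleterious symbiont with segregating modifier alleles;
    runs terminate when the symbiont is fixed or lost (or at t_max)."""
    dp = dp or DemographyParams()
    results = []
    for rng, run_seed in rep_seed_streams(root_seed, n_reps):
        init = build_initial_population(n_hosts, n_carriers, rng,
                                        m_minus_frac=m_minus_frac,
                                        modifier=True,
                                        exact_sex_split=exact_sex_split)
        res = run_realisation(init, dp, SymbiontPool([w]), "modifier",
                              t_max=t_max, seed=run_seed,
                              sample_dt=sample_dt)
        results.append(res)
    return results


def overlay_initial_counts(n_hosts: int = 1000,
                           carrier_female_frac: float = 0.01,
                           m_minus_male_frac: float = 0.1) -> dict:
    """Deterministic founding counts shared by the stochastic ensemble and
    the six-type ODE: 1:1 sexes, carriers among females only, suppressing
    allele in a fraction of (non-carrier) males."""
    n_f = n_hosts // 2
    n_m = n_hosts - n_f
    fp = int(round(carrier_female_frac * n_f))
    ym = int(round(m_minus_male_frac * n_m))
    car, empty = frozenset({0}), frozenset()
    counts = {}
    if fp:
        counts[(FEMALE, car, None)] = fp
    counts[(FEMALE, empty, None)] = n_f - fp
    if ym:
        counts[(MALE, empty, M_MINUS)] = ym
    counts[(MALE, empty, M_PLUS)] = n_m - ym
    return counts


def overlay_ode_init(n_hosts: int = 1000, carrier_female_frac: float = 0.01,
                     m_minus_male_frac: float = 0.1) -> ODEState6:
    """Six-type ODE state matching :func:`overlay_initial_counts` (nu = 1)."""
    c = overlay_initial_counts(n_hosts, carrier_female_frac, m_minus_male_frac)
    car, empty = frozenset({0}), frozenset()
    return ODEState6(
        x_plus=c.get((FEMALE, car, None), 0),
        x_minus=c.get((FEMALE, empty, None), 0),
        y_plus=c.get((MALE, car, M_MINUS), 0),
        y_minus=c.get((MALE, empty, M_MINUS), 0),
        z_plus=c.get((MALE, car, M_PLUS), 0),
        z_minus=c.get((MALE, empty, M_PLUS), 0),
    )


def run_overlay_ensemble(n_reps: int, root_seed: int, *, w: float = 0.37,
                         e0: float = 0.1, n_hosts: int = 1000,
                         carrier_female_frac: float = 0.01,
                         m_minus_male_frac: float = 0.1,
                         b0: float = 4.0, d0: float = 1.0,
                         dprime: float = 0.001,
                         t_max: float = 50.0,
                         sample_dt: float = 0.5) -> list[RealisationResult]:
    """Modifier runs with horizontal uptake on a fixed window, from the
    deterministic overlay initial condition (stop only at t_max)."""
    dp = DemographyParams(b0=b0, d0=d0, dprime=dprime, e0=e0)
    counts = overlay_initial_counts(n_hosts, carrier_female_frac,
                                    m_minus_male_frac)
    results = []
    for _, run_seed in rep_seed_streams(root_seed, n_reps):
        init = PopulationState(dict(counts))
        res = run_realisation(init, dp, SymbiontPool([w]), "modifier",
                              t_max=t_max, seed=run_seed,
                              sample_dt=sample_dt, stop=None)
        results.append(res)
    return results


@dataclass
class MultiTaxonResult:
    """Record of one multi-taxon realisation.

    ``snapshots`` rows are (t, taxa-per-host histogram, per-taxon carrier
    counts); the histogram maps number-of-taxa-carried to host count.
    """

    outcome: str  # monomorphic | timeout | host_extinction
    t_end: float
    snapshots: list
    final_counts: dict
    w_list: tuple
    seed: int | None
    extras: dict = field(default_factory=dict)

    def modal_carriage(self) -> frozenset:
        """Most common carriage set at termination."""
        tally: dict = {}
        for (sex, carriage, allele), c in self.final_counts.items():
            tally[carriage] = tally.get(carriage, 0) + c
        return max(tally, key=tally.get)

    def per_taxon_fixed(self) -> list[bool]:
        n = sum(self.final_counts.values())
        out = []
        for taxon in range(len(self.w_list)):
            cnt = sum(c for (s, carriage, a), c in self.final_counts.items()
                      if taxon in carriage)
            out.append(cnt == n and n > 0)
        return out

    def carriage_sets_seen(self) -> set:
        return set().union(*(snap[3] for snap in self.snapshots
                             if len(snap) > 3)) if self.snapshots else set()


def _taxa_histogram(counts: dict) -> dict:
    hist: dict = {}
    for (sex, carriage, allele), c in counts.items():
        k = len(carriage)
        hist[k] = hist.get(k, 0) + c
    return hist


def _per_taxon_counts(counts: dict, n_taxa: int) -> list[int]:
    out = [0] * n_taxa
    for (sex, carriage, allele), c in counts.items():
        for taxon in carriage:
            out[taxon] += c
    return out


def run_multitaxon_realisation(mode: str, w_list, seed: int | None, *,
                               n_hosts: int = 1000, n_inoculated: int = 50,
                               dp: DemographyParams | None = None,
                               t_max: float = 150.0, sample_dt: float = 1.0,
                               init: PopulationState | None = None,
                               init_rng: np.random.Generator | None = None
                               ) -> MultiTaxonResult:
    """Simultaneous invasion by several taxa, tracked as carriage-set and
    taxa-count distributions; terminates when the population is monomorphic
    in carriage, extinct, or at t_max."""
    dp = dp or DemographyParams()
    pool = SymbiontPool(w_list)
    n_taxa = len(pool)
    if init is None:
        if init_rng is None:
            init_rng = np.random.default_rng(seed)
        init = build_multitaxon_population(n_hosts, n_taxa, n_inoculated,
                                           init_rng)
    state = init.copy(seed=seed)
    snapshots = []
    next_s = state.t
    outcome = None
    while True:
        if state.n == 0:
            outcome = "host_extinction"
            break
        sets = state.carriage_sets()
        if len(sets) == 1:
            outcome = "monomorphic"
            break
        if state.t >= t_max:
            state.t = t_max
            outcome = "timeout"
            break
        while next_s <= min(state.t, t_max):
            snapshots.append((next_s, _taxa_histogram(state.counts),
                              _per_taxon_counts(state.counts, n_taxa),
                              state.carriage_sets()))
            next_s += sample_dt
        gillespie_step(state, dp, pool, mode)
    snapshots.append((state.t, _taxa_histogram(state.counts),
                      _per_taxon_counts(state.counts, n_taxa),
                      state.carriage_sets()))
    return MultiTaxonResult(outcome, state.t, snapshots,
                            dict(state.counts), pool.w_list, seed)


def run_multitaxon_ensemble(mode: str, n_reps: int, root_seed: int, *,
                            n_taxa: int = 20, shared_pool: bool = True,
                            w_mean: float = 1.0, w_sd: float = 0.3,
                            w_lo: float = 0.0, w_hi: float = 2.5,
                            **kwargs) -> list[MultiTaxonResult]:
    """Ensemble of multi-taxon realisations.  With ``shared_pool`` the same
    taxon pool (drawn from the root seed) is used by every realisation;
    otherwise each realisation draws its own."""
    streams = rep_seed_streams(root_seed, n_reps)
    pool_rng = np.random.default_rng(np.random.SeedSequence(root_seed).spawn(
        n_reps + 1)[-1])
    shared = sample_w(n_taxa, w_mean, w_sd, w_lo, w_hi, rng=pool_rng)
    results = []
    for rng, run_seed in streams:
        w_list = shared if shared_pool else sample_w(n_taxa, w_mean, w_sd,
                                                     w_lo, w_hi, rng=rng)
        results.append(run_multitaxon_realisation(
            mode, w_list, run_seed, init_rng=rng, **kwargs))
    return results


_PROTOCOLS = {
    "sieve": run_sieve_ensemble,
    "modifier": run_modifier_ensemble,
    "overlay": run_overlay_ensemble,
    "multitaxon": run_multitaxon_ensemble,
}


def run_ensemble(protocol: str, n_reps: int, root_seed: int, **kwargs):
    """Dispatch an ensemble run by protocol name.

    ``protocol`` is one of ``sieve`` (per-realisation w draw), ``multitaxon``
    (several taxa, carriage histograms), ``modifier`` (Y-linked transmission
    modifiers, D trajectory) or ``overlay`` (modifier + horizontal uptake on
    a fixed window).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    try:
        fn = _PROTOCOLS[protocol]
    except KeyError:
        raise ValueError(
            f"unknown protocol {protocol!r}; valid: {sorted(_PROTOCOLS)}"
        ) from None
    if protocol in ("sieve", "multitaxon"):
        mode = kwargs.pop("mode")
        return fn(mode, n_reps, root_seed, **kwargs)
    return fn(n_reps, root_seed, **kwargs)
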