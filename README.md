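# symsieve

Models of host–symbiont vertical and horizontal transmission in a
two-sex host population, built around one question: which symbionts can
invade a host population, and how does the mode of vertical transmission
(biparental vs maternal-only) filter them?

Three model layers share a single parameterisation:

1. **`symsieve.algebraic`** — a discrete-generation recursion for the
   frequency `p` of hosts carrying an augmented symbiont community, with
   per-parent transmission probabilities `(alpha, beta)` and relative host
   fitness `w`. Includes the closed-form rare-symbiont invasion threshold
   `w0 = 1/(alpha + beta)` (1/2 biparental, 1 maternal-only).
2. **`symsieve.gillespie`** / **`symsieve.protocols`** — an exact
   continuous-time stochastic birth–death simulation (Gillespie algorithm)
   of individual hosts with sex, a carried set of symbiont taxa, logistic
   density-dependent death modified by `1/w`, optional horizontal uptake at
   rate `e0`, and optional Y-linked modifier alleles that switch a father's
   matings between the biparental and maternal transmission rules.
   Individuals within a (sex, carriage, allele) class are exchangeable, so
   the engine simulates exact class counts (~10⁶ events/s).
3. **`symsieve.ode`** — the deterministic mean-field counterpart: a
   two-type system for carrier/non-carrier female densities and a six-type
   system with explicit male modifier classes, plus boundary equilibria,
   invasion rates, the host-extinction threshold `w1 = 2 d0 / b0`, outcome
   classification (loss / fixation / bimorphic / host extinction) and
   `(w, e0)` phase-diagram scans.

## Command-line interface

```bash
symsieve sieve --mode maternal --reps 300 --seed 1 --preset desk --out out/sieve
symsieve multitaxon --mode biparental --seed 8 --out out/multi
symsieve modifier --w 0.6 --reps 50 --seed 1 --out out/mod
symsieve phase --preset desk --out out/phase
symsieve trajectory --w 0.37 --e0 0.1 --seed 31 --out out/traj
symsieve recursion --w 0.6 --out out/rec
symsieve summarise out/sieve
```

Experiments:

- `sieve` — fate (fixation/loss) of a single new symbiont whose fitness
  effect is drawn per realisation from a truncated normal
  (mean 1, sd 0.3, on [0, 2.5]).
- `multitaxon` — 20 taxa inoculated simultaneously; carriage histograms
  over time.
- `modifier` — invasion of a deleterious symbiont while Y-linked
  transmission-modifier alleles segregate; tracks the male-class
  disequilibrium `D = p1 p4 − p2 p3`.
- `phase` — `(w, e0)` outcome classification grid for both modes.
- `trajectory` — stochastic ensemble with horizontal uptake overlaid on
  the six-type deterministic solution.
- `recursion` — the discrete-generation frequency map for both modes.

Every run writes numeric CSVs, a `log.txt`, and a `manifest.json`
recording all resolved parameters, the root seed, and (for the `desk`
preset) each deviation from the full `paper`-scale protocol. Re-running
from a manifest reproduces the CSVs byte for byte
(`symsieve.experiments.rerun_from_manifest`). A flat YAML config file can
supply any parameter; command-line flags override it.

## Layout

```
src/symsieve/
  algebraic.py    frequency recursion, invasion condition
  gillespie.py    stochastic engine: types, events, realisations
  _fastloop.py    specialised exact SSA loop for single-taxon runs
  protocols.py    ensemble drivers and initial-condition builders
  ode.py          two- and six-type deterministic systems, phase scans
  experiments.py  presets, manifests, CSV outputs
  cli.py          click command-line interface
tests/            unit, property and acceptance tests
scripts/          acceptance.py
```
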