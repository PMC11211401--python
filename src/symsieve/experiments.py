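"""Experiment harness: named experiment protocols, presets, manifests, CSVs.

Each experiment resolves its parameters from a preset (``paper`` mirrors the
printed protocol values; ``desk`` is a documented reduction that runs in
minutes), applies user overrides, executes, and writes a results CSV plus a
JSON manifest recording every resolved parameter, the root seed, and -- for
the desk preset -- the explicit list of deviations from the paper protocol.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .algebraic import TransmissionParams, iterate_generations
from .gillespie import DemographyParams
from .ode import ODEParams, phase_scan, modifier_trajectory
from .protocols import (
    run_sieve_ensemble, run_modifier_ensemble, run_overlay_ensemble,
    run_multitaxon_ensemble, overlay_ode_init,
)

__all__ = ["ExperimentConfig", "PRESETS", "run_experiment", "summarise",
           "rerun_from_manifest"]

logger = logging.getLogger("symsieve")

EXPERIMENTS = ("sieve", "multitaxon", "modifier", "phase", "trajectory",
               "recursion")

# paper preset: the printed protocol values.  desk preset: reductions that
# keep every experiment within minutes on one CPU; each reduced key is
# reported in the manifest as a deviation.
PRESETS: dict = {
    "sieve": {
        "paper": dict(mode="biparental", n_reps=5000, n_hosts=1000,
                      n_carriers=10, b0=4.0, d0=1.0, dprime=0.001,
                      t_max=200.0, sample_dt=0.5,
                      w_mean=1.0, w_sd=0.3, w_lo=0.0, w_hi=2.5),
        "desk": dict(n_reps=300, n_hosts=200, dprime=0.005, t_max=100.0),
    },
    "multitaxon": {
        "paper": dict(mode="biparental", n_reps=1, n_hosts=1000, n_taxa=20,
                      n_inoculated=50, b0=4.0, d0=1.0, dprime=0.001,
                      t_max=300.0, sample_dt=1.0,
                      w_mean=1.0, w_sd=0.3, w_lo=0.0, w_hi=2.5),
        "desk": dict(n_reps=3),
    },
    "modifier": {
        "paper": dict(n_reps=1, n_hosts=1000, n_carriers=10,
                      m_minus_frac=0.1, w=0.6, b0=4.0, d0=1.0, dprime=0.001,
                      t_max=200.0, sample_dt=0.5),
        # larger inoculum and initial modifier frequency make the sweep the
        # typical outcome rather than an early-drift lottery; longer t_max
        # lets the post-sweep elimination complete
        "desk": dict(n_reps=50, n_carriers=50, m_minus_frac=0.2,
                     t_max=400.0),
    },
    "phase": {
        "paper": dict(w_min=0.01, w_max=1.5, w_step=0.01,
                      e0_min=0.0, e0_max=1.5, e0_step=0.01,
                      b0=4.0, d0=1.0, dprime=0.001, nu=1.0,
                      modes=("biparental", "maternal")),
        "desk": dict(w_step=0.05, e0_step=0.1),
    },
    "trajectory": {
        "paper": dict(n_reps=100, w=0.37, e0=0.1, n_hosts=1000,
                      carrier_female_frac=0.01, m_minus_male_frac=0.1,
                      b0=4.0, d0=1.0, dprime=0.001, t_max=50.0,
                      sample_dt=0.5),
        "desk": dict(),
    },
    "recursion": {
        "paper": dict(w=0.6, p0=0.01, n_gen=100,
                      modes=("biparental", "maternal")),
        "desk": dict(),
    },
}


@dataclass
class ExperimentConfig:
    """Resolved configuration for one experiment run."""

    experiment: str
    parameters: dict = field(default_factory=dict)
    n_reps: int | None = None
    root_seed: int = 0
    preset: str = "desk"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"valid: {EXPERIMENTS}")
        if self.preset not in ("paper", "desk"):
            raise ValueError(f"unknown preset {self.preset!r}")

    def resolve(self) -> tuple[dict, list[str]]:
        """Merge preset defaults and overrides; return (params, deviations).

        ``deviations`` lists every key where the desk preset or an explicit
        override departs from the paper protocol value.
        """
        paper = dict(PRESETS[self.experiment]["paper"])
        resolved = dict(paper)
        if self.preset == "desk":
            resolved.update(PRESETS[self.experiment]["desk"])
        unknown = set(self.parameters) - set(paper)
        if unknown:
            raise ValueError(
                f"invalid config key(s) for {self.experiment}: "
                f"{', '.join(sorted(unknown))}")
        resolved.update(self.parameters)
        if self.n_reps is not None:
            if "n_reps" not in paper:
                raise ValueError(
                    f"experiment {self.experiment} takes no n_reps")
            resolved["n_reps"] = self.n_reps
        deviations = [f"{k}: paper={paper[k]!r} run={resolved[k]!r}"
                      for k in sorted(paper) if resolved[k] != paper[k]]
        return resolved, deviations


def _write_manifest(out: Path, config: ExperimentConfig, resolved: dict,
                    deviations: list[str], files: list[str]) -> None:
    manifest = {
        "experiment": config.experiment,
        "preset": config.preset,
        "root_seed": config.root_seed,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in resolved.items()},
        "deviations_from_paper_protocol": deviations,
        "outputs": files,
        "version": _version,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _dp(p: dict) -> DemographyParams:
    return DemographyParams(b0=p["b0"], d0=p["d0"], dprime=p["dprime"],
                            e0=p.get("e0", 0.0))


def _run_sieve(p, seed, out: Path) -> list[str]:
    res = run_sieve_ensemble(
        p["mode"], p["n_reps"], seed, n_hosts=p["n_hosts"],
        n_carriers=p["n_carriers"], dp=_dp(p), t_max=p["t_max"],
        sample_dt=p["sample_dt"], w_mean=p["w_mean"], w_sd=p["w_sd"],
        w_lo=p["w_lo"], w_hi=p["w_hi"])
    rows = [dict(seed=r.seed, mode=p["mode"], w=r.w, outcome=r.outcome,
                 t_end=r.t_end,
                 final_n_plus=int(r.trajectory["n_plus"].iloc[-1]),
                 final_n=int(r.trajectory["n"].iloc[-1]))
            for r in res]
    pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
    return ["results.csv"]


def _run_modifier(p, seed, out: Path) -> list[str]:
    res = run_modifier_ensemble(
        p["n_reps"], seed, w=p["w"], n_hosts=p["n_hosts"],
        n_carriers=p["n_carriers"], m_minus_frac=p["m_minus_frac"],
        dp=_dp(p), t_max=p["t_max"], sample_dt=p["sample_dt"])
    rows = []
    for r in res:
        tr = r.trajectory
        rows.append(dict(seed=r.seed, w=r.w, outcome=r.outcome, t_end=r.t_end,
                         final_n_plus=int(tr["n_plus"].iloc[-1]),
                         final_n=int(tr["n"].iloc[-1]),
                         final_m_minus_freq=float(tr["m_minus_freq"].iloc[-1]),
                         max_D=float(tr["D"].max())))
    pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
    files = ["results.csv"]
    res[0].trajectory.to_csv(out / "trajectory_rep0.csv", index=False)
    files.append("trajectory_rep0.csv")
    return files


def _run_multitaxon(p, seed, out: Path) -> list[str]:
    res = run_multitaxon_ensemble(
        p["mode"], p["n_reps"], seed, n_taxa=p["n_taxa"],
        n_hosts=p["n_hosts"], n_inoculated=p["n_inoculated"],
        dp=_dp(p), t_max=p["t_max"], sample_dt=p["sample_dt"],
        w_mean=p["w_mean"], w_sd=p["w_sd"], w_lo=p["w_lo"], w_hi=p["w_hi"])
    rows = []
    for r in res:
        modal = r.modal_carriage()
        rows.append(dict(seed=r.seed, mode=p["mode"], outcome=r.outcome,
                         t_end=r.t_end, modal_size=len(modal),
                         modal_set=" ".join(map(str, sorted(modal))),
                         n_taxa_fixed=sum(r.per_taxon_fixed())))
    pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
    hist_rows = []
    for i, r in enumerate(res):
        for t, hist, per_taxon, _sets in r.snapshots:
            for k, c in sorted(hist.items()):
                hist_rows.append(dict(rep=i, t=t, taxa_per_host=k, hosts=c))
    pd.DataFrame(hist_rows).to_csv(out / "carriage_histograms.csv",
                                   index=False)
    return ["results.csv", "carriage_histograms.csv"]


def _run_phase(p, seed, out: Path) -> list[str]:
    ws = np.round(np.arange(p["w_min"], p["w_max"] + 1e-9, p["w_step"]), 6)
    e0s = np.round(np.arange(p["e0_min"], p["e0_max"] + 1e-9, p["e0_step"]), 6)
    params = ODEParams(b0=p["b0"], d0=p["d0"], dprime=p["dprime"], nu=p["nu"])
    rows = []
    for mode in p["modes"]:
        diagram = phase_scan(ws, e0s, mode, params)
        for i, e0 in enumerate(diagram.e0_grid):
            for j, w in enumerate(diagram.w_grid):
                rows.append(dict(w=float(w), e0=float(e0), mode=mode,
                                 label=diagram.labels[i, j]))
    pd.DataFrame(rows).to_csv(out / "phase.csv", index=False)
    return ["phase.csv"]


def _run_trajectory(p, seed, out: Path) -> list[str]:
    res = run_overlay_ensemble(
        p["n_reps"], seed, w=p["w"], e0=p["e0"], n_hosts=p["n_hosts"],
        carrier_female_frac=p["carrier_female_frac"],
        m_minus_male_frac=p["m_minus_male_frac"], b0=p["b0"], d0=p["d0"],
        dprime=p["dprime"], t_max=p["t_max"], sample_dt=p["sample_dt"])
    ts, idx = np.unique(res[0].trajectory["t"].values, return_index=True)
    carrier = np.array([(r.trajectory["n_plus"] / r.trajectory["n"])
                        .values[idx] for r in res])
    mminus = np.array([r.trajectory["m_minus_freq"].values[idx]
                       for r in res])
    dis = np.array([r.trajectory["D"].values[idx] for r in res])
    ode = modifier_trajectory(
        ODEParams(b0=p["b0"], d0=p["d0"], dprime=p["dprime"],
                  e0=p["e0"], w=p["w"]),
        overlay_ode_init(p["n_hosts"], p["carrier_female_frac"],
                         p["m_minus_male_frac"]),
        (ts[0], ts[-1]), t_eval=ts)
    pd.DataFrame({
        "t": ts,
        "carrier_freq_mean": carrier.mean(axis=0),
        "carrier_freq_se": carrier.std(axis=0, ddof=1) / np.sqrt(len(res)),
        "m_minus_freq_mean": mminus.mean(axis=0),
        "m_minus_freq_se": mminus.std(axis=0, ddof=1) / np.sqrt(len(res)),
        "D_mean": dis.mean(axis=0),
        "ode_carrier_freq": ode["carrier_freq"],
        "ode_m_minus_freq": ode["m_minus_freq"],
        "ode_D": ode["D"],
    }).to_csv(out / "overlay.csv", index=False)
    pd.DataFrame([dict(seed=r.seed, outcome=r.outcome, t_end=r.t_end)
                  for r in res]).to_csv(out / "results.csv", index=False)
    return ["overlay.csv", "results.csv"]


def _run_recursion(p, seed, out: Path) -> list[str]:
    files = []
    for mode in p["modes"]:
        traj = iterate_generations(p["p0"], p["w"],
                                   TransmissionParams.from_mode(mode),
                                   p["n_gen"])
        name = f"recursion_{mode}.csv"
        pd.DataFrame({"generation": np.arange(len(traj)), "p": traj}
                     ).to_csv(out / name, index=False)
        files.append(name)
    return files


_RUNNERS = {
    "sieve": _run_sieve,
    "modifier": _run_modifier,
    "multitaxon": _run_multitaxon,
    "phase": _run_phase,
    "trajectory": _run_trajectory,
    "recursion": _run_recursion,
}


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute a configured experiment; write CSVs, manifest and log.

    Returns the output directory.  Re-running with the same configuration
    (see :func:`rerun_from_manifest`) reproduces identical CSVs.
    """
    resolved, deviations = config.resolve()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        logger.info("experiment=%s preset=%s seed=%d", config.experiment,
                    config.preset, config.root_seed)
        for dev in deviations:
            logger.info("deviation from paper protocol -- %s", dev)
        files = _RUNNERS[config.experiment](resolved, config.root_seed, out)
        _write_manifest(out, config, resolved, deviations, files)
        logger.info("done in %.1f s; wrote %s", time.time() - t0,
                    ", ".join(files + ["manifest.json"]))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def rerun_from_manifest(manifest_path, out_dir) -> Path:
    """Re-execute an experiment from its manifest (reproducibility check)."""
    m = json.loads(Path(manifest_path).read_text())
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in m["parameters"].items()}
    config = ExperimentConfig(m["experiment"], parameters=params,
                              root_seed=m["root_seed"], preset="paper")
    # parameters are fully resolved, so preset defaults are overridden anyway
    return run_experiment(config, out_dir)


def summarise(results_path) -> pd.DataFrame:
    """Outcome counts by mode from a results CSV.

    Returns one row per mode with columns (mode, n_reps, n_fixed, n_lost,
    n_extinct, n_timeout); an empty input yields an empty table with the
    same schema.
    """
    path = Path(results_path)
    if path.is_dir():
        path = path / "results.csv"
    if not path.exists():
        raise FileNotFoundError(f"no results file at {path}")
    df = pd.read_csv(path)
    cols = ["mode", "n_reps", "n_fixed", "n_lost", "n_extinct", "n_timeout"]
    if df.empty or "outcome" not in df.columns:
        return pd.DataFrame(columns=cols)
    if "mode" not in df.columns:
        df = df.assign(mode="modifier")
    rows = []
    for mode, grp in df.groupby("mode", sort=True):
        rows.append(dict(
            mode=mode, n_reps=len(grp),
            n_fixed=int((grp.outcome == "fixation").sum()),
            n_lost=int((grp.outcome == "loss").sum()),
            n_extinct=int((grp.outcome == "host_extinction").sum()),
            n_timeout=int((grp.outcome == "timeout").sum()),
        ))
    return pd.DataFrame(rows, columns=cols)
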