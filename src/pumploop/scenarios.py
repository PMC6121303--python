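"""Scenario registry and deterministic fixture generation.

A scenario bundles a model run with its default configuration and
output files:

    fig3          two-pool plane-wave superposition, power spectrum
    fig4          the same with a 5 % ouabain-induced E2:E1 shift
    fig6_basal    calibrated oxidant loop, no perturbation
    fig6_ouabain  calibrated loop with 100 uM ouabain at t = 2500
    thermo_ness   default driven Post-Albers cycle: flux, entropy,
                  master-equation relaxation

Every scenario writes CSV/JSON artifacts plus a manifest with SHA-256
checksums; identical invocations produce identical checksums (the only
stochastic operation in the package, chain path sampling, is not part
of any scenario and is always explicitly seeded).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as pio
from . import loop as ploop
from . import markov as pmarkov
from . import thermo as pthermo
from . import waves as pwaves


class ScenarioError(ValueError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(name: str, overrides: dict, files: list[Path], out_prefix: Path) -> dict:
    manifest = {
        "scenario": name,
        "overrides": overrides,
        "files": [
            {"path": str(f.name), "sha256": _sha256(f)} for f in sorted(files)
        ],
    }
    mpath = out_prefix.parent / f"{out_prefix.name}_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = str(mpath)
    return manifest


def _run_waves(name: str, shift: float, overrides: dict, out_prefix: Path) -> dict:
    ov = dict(overrides)
    shift = float(ov.pop("shift", shift))
    duration = float(ov.pop("duration", pwaves.DEFAULT_DURATION))
    fs = float(ov.pop("sampling_rate", pwaves.DEFAULT_SAMPLING_RATE))
    if ov:
        raise ScenarioError(f"unknown overrides for {name}: {sorted(ov)}")
    pools = pwaves.apply_ouabain_shift(pwaves.default_pools(), shift)
    field = pwaves.build_field(pools, duration=duration, sampling_rate=fs)
    spec = pwaves.power_spectrum(field)
    peaks = pwaves.peak_locations(spec, 2)
    spec_path = out_prefix.parent / f"{out_prefix.name}_spectrum.csv"
    pio.write_spectrum(spec.frequencies, spec.power, spec_path)
    peaks_path = out_prefix.parent / f"{out_prefix.name}_peaks.json"
    with open(peaks_path, "w") as fh:
        json.dump(
            {
                "shift_fraction": shift,
                "peaks": [{"frequency_Hz": f, "height": h} for f, h in peaks],
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return _manifest(name, {"shift": shift}, [spec_path, peaks_path], out_prefix)


def _run_loop(name: str, perturbed: bool, overrides: dict, out_prefix: Path) -> dict:
    ov = dict(overrides)
    onset = float(ov.pop("onset", 2500.0))
    conc = float(ov.pop("ouabain_uM", 100.0))
    t_end = float(ov.pop("t_end", 5000.0))
    if ov:
        raise ScenarioError(f"unknown overrides for {name}: {sorted(ov)}")
    params = ploop.calibrate_basal()
    perts = (
        (ploop.Perturbation("ouabain", onset, conc),) if perturbed else ()
    )
    t_grid = np.linspace(0.0, t_end, int(t_end / 5) + 1)
    traj = ploop.simulate(params, perts, t_grid=t_grid)
    traj_path = out_prefix.parent / f"{out_prefix.name}_trajectory.csv"
    ploop.trajectory_to_csv(traj, traj_path)
    metrics_path = out_prefix.parent / f"{out_prefix.name}_metrics.json"
    ploop.metrics_to_json(ploop.summarize(traj), metrics_path)
    params_path = out_prefix.parent / f"{out_prefix.name}_params.yaml"
    pio.write_loop_params(params, params_path)
    return _manifest(
        name,
        {"onset": onset, "ouabain_uM": conc if perturbed else 0.0, "t_end": t_end},
        [traj_path, metrics_path, params_path],
        out_prefix,
    )


def _run_thermo(name: str, overrides: dict, out_prefix: Path) -> dict:
    ov = dict(overrides)
    t_end = float(ov.pop("t_end", 2.0))
    if ov:
        raise ScenarioError(f"unknown overrides for {name}: {sorted(ov)}")
    rates = pthermo.default_post_albers_rates()
    summary = pthermo.entropy_production(rates)
    p0 = pthermo.ProbabilityDensity(rates.states, np.array([1.0, 0.0, 0.0, 0.0]))
    traj = pthermo.integrate_master(p0, rates, np.linspace(0.0, t_end, 201))
    traj_path = out_prefix.parent / f"{out_prefix.name}_relaxation.csv"
    traj.to_csv(traj_path, index=False, float_format=pio.FLOAT_FMT)
    summary_path = out_prefix.parent / f"{out_prefix.name}_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(
            {
                "J_ness": summary.J_ness,
                "affinity": summary.affinity,
                "e_p": summary.e_p,
                "stationary": dict(
                    zip(rates.states.labels, summary.pi.tolist())
                ),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return _manifest(name, {"t_end": t_end}, [traj_path, summary_path], out_prefix)


REGISTRY = {
    "fig3": lambda ov, out: _run_waves("fig3", 0.0, ov, out),
    "fig4": lambda ov, out: _run_waves("fig4", 0.05, ov, out),
    "fig6_basal": lambda ov, out: _run_loop("fig6_basal", False, ov, out),
    "fig6_ouabain": lambda ov, out: _run_loop("fig6_ouabain", True, ov, out),
    "thermo_ness": lambda ov, out: _run_thermo("thermo_ness", ov, out),
}


def run_scenario(name: str, overrides: dict | None = None, out_prefix="scenario") -> dict:
    """Run a registered scenario; returns the written-artifact manifest."""
    if name not in REGISTRY:
        raise ScenarioError(
            f"unknown scenario {name!r}; registered: {sorted(REGISTRY)}"
        )
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    return REGISTRY[name](dict(overrides or {}), out_prefix)


def generate_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the example inputs used across the test suite.

    Seeded and reproducible: the same seed yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written = []

    tm = pmarkov.default_post_albers_chain()
    path = out_dir / "post_albers_P.csv"
    pio.write_transition_matrix(tm, path)
    written.append(path)

    raw = rng.uniform(0.05, 1.0, size=(4, 4))
    random_P = raw / raw.sum(axis=1, keepdims=True)
    path = out_dir / "random_P.csv"
    pio.write_transition_matrix(
        pmarkov.TransitionMatrix(pmarkov.StateSpace(), random_P), path
    )
    written.append(path)

    path = out_dir / "driven_rates.csv"
    pio.write_rate_set(pthermo.default_post_albers_rates(), path)
    written.append(path)

    k = rng.uniform(0.5, 5.0, size=4)
    balanced = pthermo.RateSet(pmarkov.StateSpace(), k, k.copy())
    path = out_dir / "detailed_balance_rates.csv"
    pio.write_rate_set(balanced, path)
    written.append(path)

    path = out_dir / "pools.yaml"
    pio.write_pools(pwaves.default_pools(), path)
    written.append(path)

    path = out_dir / "loop_params.yaml"
    pio.write_loop_params(ploop.LoopParams(), path)
    written.append(path)

    path = out_dir / "fig6_perturbation.yaml"
    pio.write_perturbations([ploop.Perturbation("ouabain", 2500.0, 100.0)], path)
    written.append(path)

    return written
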