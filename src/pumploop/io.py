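"""CSV / YAML round-trip I/O for model objects.

Transition matrices travel as CSV with the state labels as both header
row and index column; rate sets as (edge, k_plus, k_minus) tables;
loop parameters and pool configurations as YAML mappings.  All writers
are deterministic so identical inputs yield byte-identical files.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .loop import LoopParams, Perturbation
from .markov import StateSpace, TransitionMatrix
from .thermo import RateSet
from .waves import PoolConfig

FLOAT_FMT = "%.17g"


def write_transition_matrix(tm: TransitionMatrix, path) -> None:
    df = pd.DataFrame(tm.P, index=list(tm.states.labels), columns=list(tm.states.labels))
    df.to_csv(path, float_format=FLOAT_FMT)


def read_transition_matrix(path, dt: float = 1.0) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    labels = tuple(str(c) for c in df.columns)
    if tuple(df.index) != labels:
        raise ValueError("row and column labels disagree; not a transition matrix CSV")
    return TransitionMatrix(StateSpace(labels), df.to_numpy(dtype=float), dt=dt)


def write_rate_set(rates: RateSet, path) -> None:
    labels = rates.states.labels
    edges = [f"{labels[i]}->{labels[(i + 1) % rates.n]}" for i in range(rates.n)]
    df = pd.DataFrame(
        {"edge": edges, "k_plus": rates.k_plus, "k_minus": rates.k_minus}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_rate_set(path) -> RateSet:
    df = pd.read_csv(path, float_precision="round_trip")
    labels = tuple(e.split("->")[0] for e in df["edge"])
    return RateSet(
        StateSpace(labels),
        df["k_plus"].to_numpy(dtype=float),
        df["k_minus"].to_numpy(dtype=float),
    )


def write_pools(pools: list[PoolConfig], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(p) for p in pools], fh, sort_keys=True)


def read_pools(path) -> list[PoolConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [PoolConfig(**d) for d in raw]


def write_loop_params(params: LoopParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)


def read_loop_params(path) -> LoopParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return LoopParams(**raw)


def write_perturbations(perts: list[Perturbation], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(p) for p in perts], fh, sort_keys=True)


def read_perturbations(path) -> list[Perturbation]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [Perturbation(**d) for d in raw]


def write_spectrum(frequencies: np.ndarray, power: np.ndarray, path) -> None:
    df = pd.DataFrame({"frequency_Hz": frequencies, "power": power})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
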