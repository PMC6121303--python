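"""Feed-forward oxidant amplification loop of the Na/K-ATPase.

State variables (all non-negative, arbitrary units except pump counts):

    N_E1    plasma-membrane pumps in the E1 (Src-inhibiting) conformation
    N_E2    plasma-membrane pumps in the E2 conformation
    N_endo  endocytosed pumps (no recycling; degraded at ``deg_endo``)
    Src_p   phosphorylated Src
    ROS     reactive oxygen species
    Age     cumulative aging signal (pure accumulator, no feedback)

Couplings (the loop's axioms): E1 pumps tonically inhibit their
associated Src; ROS and cardiotonic-steroid (ouabain) occupancy shift
pumps from E1 to E2; dis-inhibited Src phosphorylates and drives ROS
production (the Src-EGFR cascade lumped into one gain); ROS is
detoxified in proportion to its concentration; ROS drives endocytosis
of plasma pumps, which removes E1 inhibition entirely; aging
accumulates from ROS and — about a thousandfold more efficiently —
from the endocytosis flux.

The dis-inhibited fraction of the pump-controlled Src pool is

    D = 1 - N_E1 / (N_E1 + N_E2 + N_endo),

so both conversion to E2 and endocytosis release Src.

Equations (additive-in-rate ROS coupling, the default):

    r12      = k_12 + g_ros_shift*ROS + g_cts_shift*occ
    endo_i   = g_endo * ROS * N_i          (i = E1, E2)
    dN_E1/dt = synth_rate + k_21*N_E2 - r12*N_E1 - endo_E1
    dN_E2/dt = r12*N_E1 - k_21*N_E2 - endo_E2
    dN_endo/dt = endo_E1 + endo_E2 - deg_endo*N_endo
    dSrc_p/dt  = k_src_act * max(0, frac*src_total*D - Src_p)
                 - delta_srcp*Src_p
    dROS/dt  = rho_basal + g_src_ros*Src_p - delta_ros*ROS
    dAge/dt  = a_ros * (ROS + endo_aging_factor*(endo_E1 + endo_E2))

``occ`` is the equilibrium ouabain receptor occupancy
conc / (conc + IC50).  Time is in arbitrary simulation ticks; no
mapping to seconds is claimed.  All default rate constants are
calibrated by :func:`calibrate_basal` against two anchors — a basal E1
fraction of 50 % of plasma pumps and a stationary pre-perturbation
state — not transcribed from measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import least_squares, root

STATE_COLUMNS = ("N_E1", "N_E2", "N_endo", "Src_p", "ROS", "Age")


class LoopError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LoopParams:
    """Rate constants and gains of the oxidant amplification loop.

    Defaults are the package's calibrated basal parameter set (see
    module docstring); time unit is the arbitrary simulation tick.
    """

    synth_rate: float = 1500.0      # basal pump synthesis, count/tick
    k_12: float = 0.01              # basal E1->E2 rate, 1/tick
    k_21: float = 0.01675           # basal E2->E1 rate, 1/tick (calibrated)
    g_ros_shift: float = 0.005      # added E1->E2 rate per ROS unit
    rho_basal: float = 0.1          # basal ROS production, units/tick
    g_src_ros: float = 0.4          # ROS production per Src_p unit
    delta_ros: float = 0.1          # ROS detoxification rate, 1/tick
    g_endo: float = 5.0e-4          # endocytosis rate per ROS unit, 1/tick
    k_src_act: float = 0.01         # Src phosphorylation rate, 1/tick
    delta_srcp: float = 0.01        # phospho-Src decay rate, 1/tick
    src_total: float = 1.0          # total Src pool, arb units
    frac_src_controlled: float = 0.5  # fraction of Src under pump control
    pump_total_surface: float = 2.0e6  # basal surface pump count target
    IC50_ouabain: float = 1000.0    # uM; 100 uM is ~10% of IC50
    g_cts_shift: float = 0.3        # added E1->E2 rate at full occupancy
    a_ros: float = 1.0e-6           # aging gain per ROS unit
    endo_aging_factor: float = 1000.0  # endocytosis vs ROS aging efficiency
    deg_endo: float = 0.01          # degradation of endocytosed pumps, 1/tick
    endo_from: str = "both"         # "both" (proportional) or "e2_only"
    ros_shift_mode: str = "additive"  # or "multiplicative"

    def __post_init__(self):
        numeric = {
            k: v for k, v in asdict(self).items() if isinstance(v, (int, float))
        }
        if any(v < 0 for v in numeric.values()):
            raise LoopError("all rates and gains must be non-negative")
        if not 0.0 <= self.frac_src_controlled <= 1.0:
            raise LoopError("frac_src_controlled must be in [0, 1]")
        if self.endo_from not in ("both", "e2_only"):
            raise LoopError("endo_from must be 'both' or 'e2_only'")
        if self.ros_shift_mode not in ("additive", "multiplicative"):
            raise LoopError("ros_shift_mode must be 'additive' or 'multiplicative'")


@dataclass(frozen=True)
class Perturbation:
    """A step perturbation applied from ``onset_time`` onward.

    ``ouabain``: constant bath concentration (uM) appearing at onset.
    ``ros_bolus``: instantaneous addition of ``magnitude`` ROS units.
    """

    kind: str
    onset_time: float
    magnitude: float

    def __post_init__(self):
        if self.kind not in ("ouabain", "ros_bolus"):
            raise LoopError(f"unknown perturbation kind {self.kind!r}")
        if self.onset_time < 0 or self.magnitude < 0:
            raise LoopError("onset_time and magnitude must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed record of a loop simulation."""

    frame: pd.DataFrame = field(repr=False)
    events: tuple[Perturbation, ...] = ()
    runaway: bool = False

    @property
    def t(self) -> np.ndarray:
        return self.frame["t"].to_numpy()

    def state_at(self, index: int) -> np.ndarray:
        return self.frame.iloc[index][list(STATE_COLUMNS)].to_numpy(dtype=float)


def ouabain_occupancy(conc: float, IC50: float) -> float:
    """Equilibrium receptor occupancy conc / (conc + IC50), Hill slope 1."""
    if IC50 <= 0:
        raise LoopError("IC50 must be positive")
    if conc < 0:
        raise LoopError("concentration must be non-negative")
    return conc / (conc + IC50)


def derivatives(
    state: np.ndarray,
    params: LoopParams,
    t: float = 0.0,
    ouabain_conc: float = 0.0,
) -> np.ndarray:
    """Right-hand side of the loop ODE system (see module docstring)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise LoopError("state must have 6 components " + str(STATE_COLUMNS))
    if np.any(y < -1e-9 * max(1.0, params.pump_total_surface)):
        raise LoopError("negative state input")
    n1, n2, nendo, srcp, ros, _age = np.clip(y, 0.0, None)
    p = params

    occ = ouabain_occupancy(ouabain_conc, p.IC50_ouabain) if ouabain_conc else 0.0
    shift = p.g_ros_shift * ros + p.g_cts_shift * occ
    if p.ros_shift_mode == "additive":
        r12 = p.k_12 + shift
    else:
        r12 = p.k_12 * (1.0 + shift)

    endo1 = p.g_endo * ros * n1 if p.endo_from == "both" else 0.0
    endo2 = p.g_endo * ros * n2
    endo_flux = endo1 + endo2

    total = n1 + n2 + nendo
    disinhibited = 1.0 - n1 / total if total > 0 else 0.0
    pool = p.frac_src_controlled * p.src_total * disinhibited
    free = max(0.0, pool - srcp)

    d_n1 = p.synth_rate + p.k_21 * n2 - r12 * n1 - endo1
    d_n2 = r12 * n1 - p.k_21 * n2 - endo2
    d_nendo = endo_flux - p.deg_endo * nendo
    d_srcp = p.k_src_act * free - p.delta_srcp * srcp
    d_ros = p.rho_basal + p.g_src_ros * srcp - p.delta_ros * ros
    d_age = p.a_ros * (ros + p.endo_aging_factor * endo_flux)
    return np.array([d_n1, d_n2, d_nendo, d_srcp, d_ros, d_age])


def _state_scale(params: LoopParams) -> np.ndarray:
    n = max(params.pump_total_surface, 1.0)
    return np.array([n, n, n, 1.0, 1.0, 1.0])


def basal_fixed_point(params: LoopParams, guess: np.ndarray | None = None) -> np.ndarray:
    """Basal (no perturbation) fixed point of the non-Age subsystem.

    Returns a full 6-state vector with Age = 0.
    """
    p = params
    if guess is None:
        ros0 = p.rho_basal / max(p.delta_ros, 1e-12) + 1.0
        plasma = (
            p.synth_rate / max(p.g_endo * ros0, 1e-12)
            if p.g_endo > 0
            else p.pump_total_surface
        )
        plasma = min(plasma, 10 * p.pump_total_surface)
        guess = np.array(
            [0.5 * plasma, 0.5 * plasma, p.synth_rate / max(p.deg_endo, 1e-12),
             0.1 * p.src_total, ros0]
        )
    else:
        guess = np.asarray(guess, dtype=float)[:5]

    def fun(z):
        y = np.concatenate([np.abs(z), [0.0]])
        return derivatives(y, p)[:5]

    sol = root(fun, guess, method="hybr", options={"xtol": 1e-12, "maxfev": 5000})
    if not sol.success:
        # continuation fallback: relax the ODE toward the attractor,
        # then polish the endpoint with the root solver
        y0 = np.concatenate([guess, [0.0]])
        slowest = min(
            filter(None, [p.delta_ros, p.delta_srcp, p.deg_endo, p.k_12, p.k_21]),
            default=0.01,
        )
        horizon = 50.0 / max(slowest, 1e-6)
        traj = simulate(p, t_grid=np.linspace(0.0, horizon, 101), y0=y0)
        sol = root(
            fun, traj.state_at(-1)[:5], method="hybr",
            options={"xtol": 1e-12, "maxfev": 5000},
        )
    if not sol.success:
        raise LoopError(f"fixed-point solve failed: {sol.message}")
    y = np.concatenate([np.abs(sol.x), [0.0]])
    resid = derivatives(y, p)[:5]
    scale = _state_scale(p)[:5]
    if np.max(np.abs(resid) / np.maximum(scale, 1.0)) > 1e-9:
        raise LoopError("fixed-point residual too large")
    return y


def e1_fraction(y: np.ndarray) -> float:
    """E1 share of plasma-membrane pumps, N_E1 / (N_E1 + N_E2)."""
    n1, n2 = y[0], y[1]
    return float(n1 / (n1 + n2)) if n1 + n2 > 0 else float("nan")


def simulate(
    params: LoopParams,
    perturbations: tuple[Perturbation, ...] = (),
    t_grid: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the loop ODEs on ``t_grid`` (default 0..5000, step 5).

    The initial state defaults to the basal fixed point, so the
    pre-perturbation segment is stationary.  Ouabain perturbations are
    constant-concentration steps from their onset; ROS boluses are
    instantaneous state jumps.  A diverging trajectory (any state
    exceeding 1e12 x its scale) sets ``runaway=True`` instead of
    raising.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 5000.0, 1001)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise LoopError("t_grid must be strictly increasing")
    perturbations = tuple(perturbations)
    y = basal_fixed_point(params) if y0 is None else np.asarray(y0, dtype=float).copy()

    scale = _state_scale(params)
    atol = rtol * scale * 1e-2
    onsets = sorted({pb.onset_time for pb in perturbations if pb.onset_time > t_grid[0]})
    breakpoints = [t_grid[0], *[t for t in onsets if t < t_grid[-1]], t_grid[-1]]

    rows, times = [], []
    runaway = False
    for si, (seg_start, seg_end) in enumerate(zip(breakpoints[:-1], breakpoints[1:])):
        last = si == len(breakpoints) - 2
        conc = sum(
            pb.magnitude
            for pb in perturbations
            if pb.kind == "ouabain" and pb.onset_time <= seg_start
        )
        for pb in perturbations:
            if pb.kind == "ros_bolus" and pb.onset_time == seg_start:
                y[4] += pb.magnitude

        if last:
            pts = t_grid[(t_grid >= seg_start) & (t_grid <= seg_end)]
        else:
            pts = t_grid[(t_grid >= seg_start) & (t_grid < seg_end)]
        t_eval = np.unique(np.concatenate([pts, [seg_start, seg_end]]))
        sol = solve_ivp(
            lambda t, yy: derivatives(yy, params, t, ouabain_conc=conc),
            (seg_start, seg_end),
            y,
            t_eval=t_eval,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        keep = np.isin(sol.t, pts)
        for k in np.where(keep)[0]:
            times.append(sol.t[k])
            rows.append(np.clip(sol.y[:, k], 0.0, None))
        if np.any(np.abs(sol.y) > 1e12 * scale[:, None]):
            runaway = True
            break
        if not sol.success:
            raise LoopError(f"ODE solver failed: {sol.message}")
        y = sol.y[:, -1].copy()

    frame = pd.DataFrame(np.array(rows), columns=list(STATE_COLUMNS))
    frame.insert(0, "t", np.array(times))
    return Trajectory(frame=frame, events=perturbations, runaway=runaway)


@dataclass(frozen=True)
class CalibrationTargets:
    """Anchors for basal calibration."""

    e1_fraction: float = 0.5
    horizon: float = 2500.0
    e1_tol: float = 0.01


def calibrate_basal(
    params: LoopParams | None = None,
    targets: CalibrationTargets = CalibrationTargets(),
) -> LoopParams:
    """Calibrate ``k_21`` and ``synth_rate`` to the basal anchors.

    Anchors: the basal fixed point has an E1 plasma fraction equal to
    ``targets.e1_fraction`` (within ``e1_tol``), a total plasma pump
    count of ``pump_total_surface``, and the unperturbed system is
    stationary and stable through ``targets.horizon``.  If the supplied
    parameters already satisfy the anchors they are returned unchanged;
    otherwise the joint fixed-point/anchor system is solved for
    (state, k_21, synth_rate).  Deterministic: no randomness is used.
    """
    p = params or LoopParams()

    def _ok(cand: LoopParams) -> bool:
        try:
            fp = basal_fixed_point(cand)
        except LoopError:
            return False
        if abs(e1_fraction(fp) - targets.e1_fraction) > targets.e1_tol:
            return False
        if abs((fp[0] + fp[1]) / cand.pump_total_surface - 1.0) > 0.05:
            return False
        return _stable_through_horizon(cand, fp, targets.horizon)

    if _ok(p):
        return p

    ft = targets.e1_fraction
    ptot = p.pump_total_surface

    def fun(z):
        n1, n2, nendo, srcp, ros, k21, synth = np.abs(z)
        cand = replace(p, k_21=float(k21), synth_rate=float(synth))
        y = np.array([n1, n2, nendo, srcp, ros, 0.0])
        d = derivatives(y, cand)[:5]
        scale = np.array([ptot, ptot, ptot, 1.0, 1.0])
        return np.concatenate(
            [d / scale, [n1 / (n1 + n2) - ft, (n1 + n2) / ptot - 1.0]]
        )

    ros0 = (p.rho_basal + p.g_src_ros * 0.5 * p.frac_src_controlled * p.src_total) / max(
        p.delta_ros, 1e-12
    )
    z0 = np.array(
        [
            ft * ptot,
            (1 - ft) * ptot,
            p.synth_rate / max(p.deg_endo, 1e-12),
            0.25 * p.frac_src_controlled * p.src_total,
            ros0,
            p.k_21,
            max(p.g_endo * ros0 * ptot, p.synth_rate),
        ]
    )
    sol = root(fun, z0, method="hybr", options={"xtol": 1e-13})
    if not sol.success:
        raise CalibrationError(
            f"basal calibration found no root near the initial bracket: {sol.message}"
        )
    n1, n2, nendo, srcp, ros, k21, synth = np.abs(sol.x)
    calibrated = replace(p, k_21=float(k21), synth_rate=float(synth))
    fp = basal_fixed_point(calibrated, guess=np.array([n1, n2, nendo, srcp, ros]))
    if abs(e1_fraction(fp) - ft) > targets.e1_tol:
        raise CalibrationError(
            f"calibrated E1 fraction {e1_fraction(fp):.4f} misses target {ft}"
        )
    if not _stable_through_horizon(calibrated, fp, targets.horizon):
        raise CalibrationError("calibrated fixed point is not stable to the horizon")
    return calibrated


def _stable_through_horizon(params: LoopParams, fp: np.ndarray, horizon: float) -> bool:
    """Nudge the fixed point and require relaxation back by ``horizon``."""
    y0 = fp.copy()
    y0[4] *= 1.05  # 5% ROS excursion
    traj = simulate(
        params, t_grid=np.linspace(0.0, horizon, 201), y0=y0, rtol=1e-10
    )
    if traj.runaway:
        return False
    y_end = traj.state_at(-1)
    d_end = derivatives(y_end, params)
    scale = _state_scale(params)
    return bool(np.max(np.abs(d_end[:5]) / np.maximum(scale[:5], 1.0)) < 1e-6)


def jacobian(params: LoopParams, y: np.ndarray | None = None, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the non-Age subsystem at ``y``."""
    if y is None:
        y = basal_fixed_point(params)
    y = np.asarray(y, dtype=float)
    scale = _state_scale(params)[:5]
    J = np.zeros((5, 5))
    f0 = derivatives(y, params)[:5]
    for j in range(5):
        dy = y.copy()
        h = eps * max(abs(y[j]), 0.01 * scale[j])
        dy[j] += h
        J[:, j] = (derivatives(dy, params)[:5] - f0) / h
    return J


def leading_eigenvalue(params: LoopParams, y: np.ndarray | None = None) -> float:
    """Largest real part of the Jacobian spectrum at the basal fixed point."""
    return float(np.max(np.linalg.eigvals(jacobian(params, y)).real))


def summarize(traj: Trajectory) -> dict:
    """Read out the panel metrics of a loop trajectory.

    Pre/post windows split at the earliest perturbation onset; without
    any perturbation the post-onset metrics are reported as None.
    """
    f = traj.frame
    plasma = f["N_E1"] + f["N_E2"]
    e1_frac = f["N_E1"] / plasma
    onset = min((pb.onset_time for pb in traj.events), default=None)

    if onset is None:
        pre = f.index
        post = f.index[:0]
    else:
        pre = f.index[f["t"] < onset]
        post = f.index[f["t"] >= onset]

    basal_e1 = float(e1_frac.loc[pre].iloc[-1]) if len(pre) else float("nan")
    basal_ros = float(f.loc[pre, "ROS"].iloc[-1]) if len(pre) else float("nan")
    basal_srcp = float(f.loc[pre, "Src_p"].iloc[-1]) if len(pre) else float("nan")
    basal_plasma = float(plasma.loc[pre].iloc[-1]) if len(pre) else float("nan")

    def _slope(idx):
        if len(idx) < 2:
            return float("nan")
        tt = f.loc[idx, "t"].to_numpy()
        aa = f.loc[idx, "Age"].to_numpy()
        return float(np.polyfit(tt, aa, 1)[0])

    out = {
        "basal_e1_fraction": basal_e1,
        "basal_ros": basal_ros,
        "aging_slope_pre": _slope(pre),
        "runaway": traj.runaway,
    }
    if onset is None or not len(post):
        out.update(
            {
                "min_e1_fraction_post": None,
                "peak_ros_fold": None,
                "peak_srcp_fold": None,
                "plasma_pump_loss": None,
                "aging_slope_post": None,
            }
        )
    else:
        out.update(
            {
                "min_e1_fraction_post": float(e1_frac.loc[post].min()),
                "peak_ros_fold": float(f.loc[post, "ROS"].max() / basal_ros),
                "peak_srcp_fold": float(f.loc[post, "Src_p"].max() / basal_srcp),
                "plasma_pump_loss": float(1.0 - plasma.loc[post].min() / basal_plasma),
                "aging_slope_post": _slope(post),
            }
        )
    return out


def mass_balance_residual(traj: Trajectory, params: LoopParams) -> np.ndarray:
    """Pump bookkeeping error along a trajectory.

    Cumulative synthesis minus cumulative endo-degradation must equal
    the change in total pump count N_E1 + N_E2 + N_endo at every sample
    (up to integration tolerance).
    """
    f = traj.frame
    t = f["t"].to_numpy()
    total = (f["N_E1"] + f["N_E2"] + f["N_endo"]).to_numpy()
    influx = np.full_like(t, params.synth_rate, dtype=float)
    outflux = params.deg_endo * f["N_endo"].to_numpy()
    net = cumulative_trapezoid(influx - outflux, t, initial=0.0)
    return (total - total[0]) - net


def fit_ros_parameters(
    observed: Trajectory,
    params: LoopParams,
    x0: tuple[float, float],
    perturbations: tuple[Perturbation, ...] = (),
) -> tuple[float, float]:
    """Least-squares recovery of (g_src_ros, delta_ros) from a trajectory.

    All other parameters are held at ``params``; candidate values are
    judged by re-simulating on the observed time grid and matching the
    ROS and Src_p time series.
    """
    t_grid = observed.frame["t"].to_numpy()
    y0 = observed.state_at(0)
    obs = observed.frame[["ROS", "Src_p"]].to_numpy()
    obs_scale = np.maximum(np.abs(obs).max(axis=0), 1e-12)

    def residual(x):
        cand = replace(params, g_src_ros=abs(x[0]), delta_ros=abs(x[1]))
        sim = simulate(cand, perturbations, t_grid=t_grid, y0=y0)
        mod = sim.frame[["ROS", "Src_p"]].to_numpy()
        return ((mod - obs) / obs_scale).ravel()

    fit = least_squares(residual, x0=np.asarray(x0, dtype=float), xtol=1e-12, ftol=1e-12)
    return float(abs(fit.x[0])), float(abs(fit.x[1]))


def trajectory_to_csv(traj: Trajectory, path) -> None:
    traj.frame.to_csv(path, index=False)


def metrics_to_json(metrics: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
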