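"""Scripted simulation experiments over the HSR model.

Each runner reproduces one experimental or in-silico scenario: the typical
step heat shock, kinase/chaperone inhibitor titrations, double heat shocks
with an arylsulfatase (ARS) reporter, HP expression time courses, a diel
temperature cycle, ramp-time scans, acclimation at sustained high
temperature, steady-state temperature scans, an HSP accumulation map, and a
robustness sweep over the Hill parameters.  Runners are pure functions of
their arguments; repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import HSRState
from .params import RateParameters
from .protocols import (
    DAY,
    HOUR,
    MINUTE,
    Constant,
    CosineRamp,
    DoublePulse,
    Pulse,
    Sinusoid,
    Step,
    TemperatureProtocol,
)
from .simulator import (
    SteadyStateError,
    Trajectory,
    integrate,
    steady_state,
    summarize,
)


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one experiment run (used by the CLI)."""

    name: str
    protocol: TemperatureProtocol | None = None
    scale_factors: dict[str, float] = field(default_factory=dict)
    t_end: float | None = None
    n_points: int = 1201
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        from .params import RateParameters as RP
        import dataclasses as dc
        valid = {f.name for f in dc.fields(RP)}
        for name, factor in self.scale_factors.items():
            if name not in valid:
                raise ValueError(f"unknown parameter {name!r} in scale_factors")
            if factor <= 0:
                raise ValueError(f"scale factor for {name} must be positive")

    def apply_scales(self, params: RateParameters) -> RateParameters:
        return params.scaled(**self.scale_factors) if self.scale_factors else params


@dataclass(frozen=True)
class ArsExtension:
    """Arylsulfatase reporter under the heat-shock promoter.

    The reporter is transcribed from the active gene complex and translated
    like the core genes but feeds nothing back into the network, so its
    dynamics are driven entirely by the FaG occupancy trace.  Translation is
    slower and the enzyme much more stable than HP, giving the reporter
    activity its characteristic lag and near-cumulative build-up.
    """

    pi_mA: float = 1.0e-2   # transcription from FaG, s^-1
    pi_A: float = 1.0e-4    # translation, s^-1
    eta_mA: float = 8.5e-4  # mRNA degradation, s^-1
    eta_A: float = 1.0e-5   # enzyme degradation, s^-1 (stable reporter)

    def __post_init__(self):
        for name in ("pi_mA", "pi_A", "eta_mA", "eta_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def attach_ars_reporter(traj: Trajectory, ars: ArsExtension = ArsExtension(),
                        ) -> dict[str, np.ndarray]:
    """Integrate the reporter equations driven by the trajectory's FaG trace.

    Because the reporter has no feedback, its two linear ODEs are solved
    against the (interpolated) gene-occupancy signal of an existing run;
    initial condition is the reporter steady state under the initial FaG.
    """
    t, fag = traj.t, traj.species("FaG")

    def drive(ti: float) -> float:
        return float(np.interp(ti, t, fag))

    fag0 = fag[0]
    mA0 = ars.pi_mA * fag0 / ars.eta_mA
    A0 = ars.pi_A * mA0 / ars.eta_A

    def f(ti, y):
        mA, A = y
        return [ars.pi_mA * drive(ti) - ars.eta_mA * mA,
                ars.pi_A * mA - ars.eta_A * A]

    sol = solve_ivp(f, (t[0], t[-1]), [mA0, A0], t_eval=t, method="LSODA",
                    rtol=1e-8, atol=1e-15)
    if not sol.success:  # pragma: no cover - linear system, robust
        raise RuntimeError(f"ARS reporter integration failed: {sol.message}")
    return {"mA": np.clip(sol.y[0], 0.0, None),
            "A": np.clip(sol.y[1], 0.0, None)}


def run_typical_hs(params: RateParameters, *, T_low: float = 25.0,
                   T_high: float = 42.0, t_shift: float = 20 * MINUTE,
                   t_end: float = 4 * HOUR + 20 * MINUTE,
                   n_points: int = 1201) -> tuple[Trajectory, dict]:
    """Standard laboratory heat shock: sudden step, pre-equilibrated start.

    Returns the trajectory and a summary holding the peak misfolded and
    active-kinase fractions and the peak times of every species.
    """
    protocol = Step(T_low, T_high, t_shift)
    traj = integrate(params, protocol, t_end, n_points=n_points)
    return traj, summarize(traj)


_INHIBITOR_TARGETS = {
    # drug -> (scaled rate constant, reported mRNA, default dose scales)
    "staurosporine": ("kp_F", "mF", (1.0, 0.6, 0.1)),
    "radicicol": ("k_P", "mH", (1.0, 0.6, 0.3)),
}


def run_inhibitor(params: RateParameters, drug: str,
                  scales: tuple[float, ...] | None = None, *,
                  T_low: float = 25.0, T_high: float = 40.0,
                  t_end: float = 3 * HOUR, n_points: int = 801) -> dict:
    """Inhibitor titration: scale one rate constant and re-run the shock.

    Staurosporine (kinase inhibitor) scales the HSF phosphorylation constant
    kp_F and is read out on HSF mRNA; radicicol (HSP90 inhibitor) scales the
    refolding constant k_P and is read out on HP mRNA.  Cultures grow without
    the drug, so every run starts from the untreated steady state.
    """
    if drug not in _INHIBITOR_TARGETS:
        raise ValueError(f"unknown drug {drug!r}; expected one of "
                         f"{sorted(_INHIBITOR_TARGETS)}")
    target, readout, default_scales = _INHIBITOR_TARGETS[drug]
    scales = default_scales if scales is None else tuple(scales)
    if any(not 0 < s <= 1 for s in scales):
        raise ValueError("scales must lie in (0, 1]")

    protocol = Step(T_low, T_high, 0.0)
    init = steady_state(params, T_low)
    out = {"drug": drug, "target": target, "readout": readout, "runs": {}}
    for scale in scales:
        scaled = params.scaled(**{target: scale})
        traj = integrate(scaled, protocol, t_end, init=init, n_points=n_points)
        series = traj.species(readout)
        i = int(np.argmax(series))
        out["runs"][scale] = {
            "trajectory": traj,
            "normalized": traj.normalized(readout),
            "peak": float(series[i]),
            "t_peak": float(traj.t[i]),
        }
    return out


def run_double_hs(params: RateParameters,
                  intervals: tuple[float, ...] = (2 * HOUR, 3 * HOUR,
                                                  4 * HOUR, 5 * HOUR),
                  ars: ArsExtension = ArsExtension(), *,
                  T_low: float = 25.0, T_high: float = 42.0,
                  duration: float = 30 * MINUTE,
                  full_response_threshold: float = 0.9,
                  n_points: int = 1601) -> dict:
    """Two heat pulses separated by a recovery interval (end-to-start).

    For each interval the runner reports the first- and second-response peak
    heights of HP mRNA and of the ARS reporter, their second/first ratios,
    and internal species not accessible experimentally (peak misfolded
    fraction and active-kinase fraction per response).
    """
    if any(g <= 0 for g in intervals):
        raise ValueError("intervals must be positive")
    init = steady_state(params, T_low)
    results = {}
    for gap in intervals:
        protocol = DoublePulse(T_low, T_high, 0.0, duration, gap)
        t_end = protocol.second_start + duration + 5 * HOUR
        traj = integrate(params, protocol, t_end, init=init, n_points=n_points)
        reporter = attach_ars_reporter(traj, ars)
        first = traj.t < protocol.second_start
        second = ~first
        mH = traj.species("mH")
        # reporter activity accumulates; compare per-response increments
        A = reporter["A"]
        a_rise_1 = float(A[first].max() - A[0])
        a_rise_2 = float(A[second].max() - A[first].max())
        pm = traj.misfolded_fraction
        sk = traj.active_kinase_fraction
        entry = {
            "trajectory": traj,
            "ars": reporter,
            "mH_peak_first": float(mH[first].max()),
            "mH_peak_second": float(mH[second].max()),
            "ars_rise_first": a_rise_1,
            "ars_rise_second": a_rise_2,
            "pm_peak_first": float(pm[first].max()),
            "pm_peak_second": float(pm[second].max()),
            "sk_peak_first": float(sk[first].max()),
            "sk_peak_second": float(sk[second].max()),
        }
        entry["mH_ratio"] = entry["mH_peak_second"] / entry["mH_peak_first"]
        entry["ars_ratio"] = (a_rise_2 / a_rise_1) if a_rise_1 > 0 else np.nan
        entry["full_second_response"] = (
            entry["mH_ratio"] >= full_response_threshold)
        results[gap] = entry
    return results


@dataclass(frozen=True)
class HPExpressionResult:
    trajectory: Trajectory
    t_peak: float
    initially_slow: bool        # positive curvature (acceleration) early on
    late_decline: bool          # concentration falls after its maximum

    @property
    def sigmoid_then_decline(self) -> bool:
        return self.initially_slow and self.late_decline


def run_hp_expression(params: RateParameters, *, T_low: float = 25.0,
                      T_high: float = 42.0, t_end: float = 12 * HOUR,
                      n_points: int = 1441) -> HPExpressionResult:
    """HP accumulation after a sudden shock at t = 0.

    Flags the characteristic shape: the rise is initially slow and
    accelerates (positive second derivative while rising), and at late times
    the concentration declines slowly again.
    """
    traj = integrate(params, Step(T_low, T_high, 0.0), t_end, n_points=n_points)
    H = traj.species("H")
    t = traj.t
    i_peak = int(np.argmax(H))
    dH = np.gradient(H, t)
    d2H = np.gradient(dH, t)
    rising = slice(1, max(i_peak, 2))
    initially_slow = bool(np.any(d2H[rising] > 0))
    late_decline = bool(H[-1] < H[i_peak] and i_peak < len(H) - 1)
    return HPExpressionResult(trajectory=traj, t_peak=float(t[i_peak]),
                              initially_slow=initially_slow,
                              late_decline=late_decline)


def run_diel(params: RateParameters, *, T_min: float = 22.0,
             T_max: float = 40.0, days: int = 2, spin_up_days: int = 1,
             onset_threshold: float = 0.005, n_points: int = 2881) -> dict:
    """Idealized hot day: sinusoidal 24 h forcing, maximum at 15:00.

    The run starts from the steady state at the midnight temperature and
    discards ``spin_up_days`` full days before metrics are read.  Onset is
    the first clock time the active-kinase fraction rises through the
    (configurable) threshold; the response maximum is the clock time of the
    kinase peak.
    """
    protocol = Sinusoid(T_min, T_max)
    t_end = (spin_up_days + days) * DAY
    traj = integrate(params, protocol, t_end, n_points=n_points)
    sel = traj.t >= spin_up_days * DAY
    t = traj.t[sel]
    pm = traj.misfolded_fraction[sel]
    sk = traj.active_kinase_fraction[sel]

    i_sk = int(np.argmax(sk))
    rising = np.nonzero((sk[1:] >= onset_threshold)
                        & (sk[:-1] < onset_threshold))[0]
    onset_clock = float((t[rising[0] + 1] % DAY) / HOUR) if len(rising) else np.nan
    return {
        "trajectory": traj,
        "max_misfolded_fraction": float(pm.max()),
        "max_active_kinase_fraction": float(sk.max()),
        "response_max_clock_h": float((t[i_sk] % DAY) / HOUR),
        "onset_clock_h": onset_clock,
    }


def run_tau_scan(params: RateParameters,
                 taus: np.ndarray | None = None, *,
                 T_low: float = 25.0, T_high: float = 42.0,
                 settle: float = 6 * HOUR, n_points: int = 801,
                 fast_tau: float = 0.1 * MINUTE,
                 slow_tau: float = 1000 * MINUTE) -> dict:
    """Peak misfolded fraction versus temperature-ramp duration tau.

    For each tau the temperature rises from T_low to T_high along a
    half-cosine of that duration and then stays high; the metric is the
    maximum misfolded fraction over the whole run.  The fast plateau is the
    value at tau <= ``fast_tau``, the slow plateau at tau >= ``slow_tau``.
    """
    if taus is None:
        taus = np.logspace(np.log10(6.0), np.log10(6.0e4), 9)  # 0.1..1000 min
    taus = np.asarray(sorted(set(np.atleast_1d(taus).tolist()
                                 + [fast_tau, slow_tau])), dtype=float)
    if np.any(taus <= 0):
        raise ValueError("tau values must be positive")
    init = steady_state(params, T_low)
    peaks = np.empty_like(taus)
    for i, tau in enumerate(taus):
        protocol = CosineRamp(T_low, T_high, 0.0, tau)
        traj = integrate(params, protocol, tau + settle, init=init,
                         n_points=n_points)
        peaks[i] = traj.misfolded_fraction.max()
    fast = float(peaks[taus <= fast_tau].max())
    slow = float(peaks[taus >= slow_tau].min())
    return {
        "tau_s": taus,
        "max_misfolded_fraction": peaks,
        "fast_plateau": fast,
        "slow_plateau": slow,
        "plateau_ratio": fast / slow,
    }


def run_acclimation(params: RateParameters, T_high: float = 42.0,
                    duration: float = 10 * HOUR, *, T_low: float = 25.0,
                    window: float = 1 * HOUR, drift_tol: float = 2e-3,
                    n_points: int = 1201) -> dict:
    """Sustained heat: transient response followed by a new steady state.

    The late quasi-steady (acclimated) phase is declared at the first time
    after which every species' relative change over a trailing ``window``
    stays below ``drift_tol``.  Reports the late-phase state, the residual
    drift, and the distance to the true steady state at T_high.
    """
    traj = integrate(params, Step(T_low, T_high, 0.0), duration,
                     n_points=n_points)
    t, y = traj.t, traj.y
    scale = np.maximum(y.max(axis=0), 1e-30)
    acclimated_from = None
    for i in range(len(t)):
        if t[-1] - t[i] < window:
            break
        sel = t >= t[i]
        rel_span = (y[sel].max(axis=0) - y[sel].min(axis=0)) / scale
        if np.all(rel_span < drift_tol):
            acclimated_from = float(t[i])
            break
    out = {
        "trajectory": traj,
        "acclimated": acclimated_from is not None,
        "acclimated_from_s": acclimated_from,
        "final_state": traj.final_state(),
        "residual_drift": None,
        "steady_state": None,
        "distance_to_steady_state": None,
    }
    if acclimated_from is not None:
        sel = t >= acclimated_from
        out["residual_drift"] = float(
            ((y[sel].max(axis=0) - y[sel].min(axis=0)) / scale).max())
        try:
            ss = steady_state(params, T_high)
            out["steady_state"] = ss
            out["distance_to_steady_state"] = float(
                np.max(np.abs(traj.y[-1] - ss.to_array()) / scale))
        except SteadyStateError:
            out["steady_state"] = None
    return out


def run_steady_state_scan(params: RateParameters, T_grid: np.ndarray, *,
                          viability_threshold: float = 0.5) -> dict:
    """Steady state at each temperature, with per-point viability flags.

    A point is flagged non-viable when no steady state is reached or when
    the steady-state misfolded fraction exceeds ``viability_threshold`` —
    the regime where the response can no longer keep degenerated protein in
    check.  The scan continues past flagged points.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("temperature grid must be non-empty")
    states: list[HSRState | None] = []
    flags: list[bool] = []
    for T in T_grid:
        try:
            ss = steady_state(params, float(T))
            states.append(ss)
            flags.append(ss.misfolded_fraction > viability_threshold)
        except SteadyStateError:
            states.append(None)
            flags.append(True)
    pm = np.array([s.misfolded_fraction if s is not None else np.nan
                   for s in states])
    return {"T_celsius": T_grid, "states": states, "non_viable": np.array(flags),
            "misfolded_fraction": pm}


def run_hsp_map(params: RateParameters, T_grid: np.ndarray,
                duration_grid: np.ndarray, *, T_low: float = 25.0,
                n_points: int = 401) -> dict:
    """Accumulated HP at the end of a (temperature, duration) heat pulse.

    Values are relative to the pre-shock baseline HP level; duration 0 maps
    to exactly 1.  Failed cells are flagged and left NaN.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    duration_grid = np.asarray(duration_grid, dtype=float)
    if T_grid.size == 0 or duration_grid.size == 0:
        raise ValueError("grids must be non-empty")
    init = steady_state(params, T_low)
    baseline = init.H
    hp = np.full((len(T_grid), len(duration_grid)), np.nan)
    failed = np.zeros_like(hp, dtype=bool)
    for i, T in enumerate(T_grid):
        for j, dur in enumerate(duration_grid):
            if dur == 0:
                hp[i, j] = 1.0
                continue
            try:
                traj = integrate(params, Pulse(T_low, float(T), 0.0, float(dur)),
                                 float(dur), init=init, n_points=n_points)
                hp[i, j] = traj.species("H")[-1] / baseline
            except Exception:
                failed[i, j] = True
    return {"T_celsius": T_grid, "duration_s": duration_grid,
            "relative_HP": hp, "failed": failed}


def run_hill_robustness(params: RateParameters,
                        m_values: tuple[float, ...] = (2.0, 2.354, 3.0),
                        P0_values: tuple[float, ...] = (0.0073, 0.0146, 0.0292),
                        *, ratio_threshold: float = 5.0,
                        taus: np.ndarray | None = None) -> dict:
    """Tau-scan family across Hill parameters (m, P0).

    Checks that the two-plateau structure of the ramp-time scan (a high fast
    plateau, a steep fall, a low slow plateau) is robust: for every tested
    pair the plateau ratio must exceed ``ratio_threshold``.
    """
    if taus is None:
        taus = np.array([6.0, 600.0, 6.0e4])  # 0.1, 10, 1000 min
    scans = {}
    for m in m_values:
        for P0 in P0_values:
            p = params.replace(m=m, P0=P0)
            scans[(m, P0)] = run_tau_scan(p, taus)
    robust = all(s["plateau_ratio"] > ratio_threshold for s in scans.values())
    return {"scans": scans, "robust": robust,
            "ratio_threshold": ratio_threshold}
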