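"""Integration of the HSR ODE system under temperature protocols.

Runs start from a pre-equilibrated steady state at the protocol's initial
temperature unless an explicit initial condition is given.  The integrator is
restarted at every protocol discontinuity so the stiff solver never steps
across a temperature jump.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import N_SPECIES, SPECIES, HSRState, rhs_array, species_index
from .params import RateParameters
from .protocols import Constant, TemperatureProtocol, kelvin_to_celsius

#: Default solver tolerances.  atol is far below the smallest resting
#: concentrations (~1e-9 mM) so that near-zero species stay non-negative.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-13

#: Output clipping threshold: concentrations above -1e-12 are clipped to 0.
CLIP_THRESHOLD = 1e-12


class IntegrationError(RuntimeError):
    """Integration failed; carries the failure time and last state."""

    def __init__(self, message: str, t: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.state = state


class SteadyStateError(RuntimeError):
    """No steady state was reached within the equilibration horizon."""


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed solution of the HSR system.

    ``y`` holds one row per time point in :data:`hsrsim.model_core.SPECIES`
    order, clipped to be non-negative; ``raw_min`` is the most negative value
    seen before clipping (a solver-accuracy diagnostic).
    """

    t: np.ndarray
    y: np.ndarray
    protocol: TemperatureProtocol
    params: RateParameters
    raw_min: float = 0.0

    def __post_init__(self):
        if len(self.t) != self.y.shape[0]:
            raise ValueError("time grid and state matrix disagree in length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        """Concentration series of one species."""
        return self.y[:, species_index(name)]

    def normalized(self, name: str) -> np.ndarray:
        """Series divided by its own maximum (flat zero if identically zero)."""
        s = self.species(name)
        peak = s.max()
        return s / peak if peak > 0 else s.copy()

    @property
    def misfolded_fraction(self) -> np.ndarray:
        """P# / (P + P#)."""
        return self.species("Pm") / (self.species("P") + self.species("Pm"))

    @property
    def active_kinase_fraction(self) -> np.ndarray:
        """SK* / (SK + SK*)."""
        return self.species("SKa") / (self.species("SK") + self.species("SKa"))

    @property
    def gene_occupancy(self) -> dict[str, np.ndarray]:
        """Fractions of the gene pool that are free / HSF-bound / HSF*-bound."""
        total = self.species("G") + self.species("FG") + self.species("FaG")
        return {name: self.species(name) / total for name in ("G", "FG", "FaG")}

    @property
    def temperature(self) -> np.ndarray:
        """Temperature trace in degC on the output grid."""
        return np.array([kelvin_to_celsius(self.protocol.temperature_at(ti))
                         for ti in self.t])

    def pool_drift(self) -> dict[str, float]:
        """Max relative drift of each conserved pool along the trajectory."""
        pools = {
            "protein": self.species("P") + self.species("Pm"),
            "kinase": self.species("SK") + self.species("SKa"),
            "gene": self.species("G") + self.species("FG") + self.species("FaG"),
        }
        return {name: float(np.abs(series / series[0] - 1.0).max())
                for name, series in pools.items()}

    def interpolate(self, name: str, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of one species onto arbitrary times."""
        return np.interp(times, self.t, self.species(name))

    def final_state(self) -> HSRState:
        return HSRState.from_array(self.y[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_s, species, value, normalized_value)."""
        frames = []
        for name in SPECIES:
            value = self.species(name)
            peak = value.max()
            frames.append(pd.DataFrame({
                "time_s": self.t,
                "species": name,
                "value": value,
                "normalized_value": value / peak if peak > 0 else value,
            }))
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, csv_path: str | Path,
                  json_path: str | Path | None = None,
                  config: dict | None = None) -> None:
        """Write the tidy CSV and an optional JSON summary sidecar."""
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        if json_path is not None:
            payload = {
                "summary": summarize(self),
                "protocol": repr(self.protocol),
                "pool_drift": self.pool_drift(),
                "config": config or {},
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


def read_trajectory_frame(csv_path: str | Path) -> pd.DataFrame:
    """Read back a trajectory CSV written by :meth:`Trajectory.write_csv`."""
    return pd.read_csv(csv_path, float_precision="round_trip",
                       dtype={"species": str, "time_s": float,
                              "value": float, "normalized_value": float})


def _initial_guess(params: RateParameters) -> np.ndarray:
    y = np.zeros(N_SPECIES)
    y[species_index("P")] = params.total_P * (1.0 - 1e-6)
    y[species_index("Pm")] = params.total_P * 1e-6
    y[species_index("SK")] = params.total_SK
    y[species_index("G")] = params.total_G
    y[species_index("F")] = 1e-4
    y[species_index("mF")] = 1e-8
    y[species_index("mH")] = 1e-8
    y[species_index("H")] = 1e-8
    return y


# Reduced coordinates for the root polish: the complement of one member of
# each conserved pool, recovered from the pool totals.
_FREE = ("Pm", "SKa", "F", "Fa", "FG", "FaG", "mF", "mH", "H")
_FREE_IDX = tuple(species_index(n) for n in _FREE)


def _full_state(u: np.ndarray, params: RateParameters) -> np.ndarray:
    y = np.zeros(N_SPECIES)
    for value, idx in zip(u, _FREE_IDX):
        y[idx] = value
    y[species_index("P")] = params.total_P - y[species_index("Pm")]
    y[species_index("SK")] = params.total_SK - y[species_index("SKa")]
    y[species_index("G")] = (params.total_G - y[species_index("FG")]
                             - y[species_index("FaG")])
    return y


def steady_state(params: RateParameters, T: float, *,
                 tol: float = 1e-9, horizon: float = 4.0e7,
                 rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                 init: HSRState | np.ndarray | None = None,
                 polish: bool = True) -> HSRState:
    """Steady state of the network at a constant temperature T (degC).

    Obtained by long-horizon integration followed by a Newton polish on the
    pool-reduced coordinates; ``tol`` bounds the max-norm of the right-hand
    side (mM/s).  Raises :class:`SteadyStateError` when the horizon is
    exhausted without convergence.
    """
    protocol = Constant(T)
    temp_fn = protocol.temperature_at
    fun = lambda t, y: rhs_array(t, y, params, temp_fn)

    if init is None:
        y = _initial_guess(params)
    else:
        y = init.to_array() if isinstance(init, HSRState) else np.asarray(init, float)

    t, chunk = 0.0, horizon / 16.0
    converged = False
    while t < horizon:
        sol = solve_ivp(fun, (t, t + chunk), y, method="LSODA",
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise SteadyStateError(
                f"equilibration at {T} degC failed at t={sol.t[-1]:.3g} s: "
                f"{sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        t += chunk
        if np.max(np.abs(fun(t, y))) < tol:
            converged = True
            break

    if polish:
        # root-polish in log coordinates (positivity-preserving); clip the
        # probe exponent so hybr's trial steps cannot overflow
        res = root(lambda u: rhs_array(0.0,
                                       _full_state(np.exp(np.clip(u, -700.0,
                                                                  700.0)),
                                                   params),
                                       params, temp_fn)[list(_FREE_IDX)],
                   np.log(np.clip(y[list(_FREE_IDX)], 1e-300, None)),
                   method="hybr")
        if res.success:
            y_pol = _full_state(np.exp(res.x), params)
            if np.all(y_pol >= 0) and np.max(np.abs(fun(0.0, y_pol))) < tol:
                y, converged = y_pol, True

    if not converged:
        raise SteadyStateError(
            f"no steady state at {T} degC within {horizon:.3g} s "
            f"(residual {np.max(np.abs(fun(t, y))):.3g} mM/s); the response "
            "may be unable to balance denaturation at this temperature")
    return HSRState.from_array(np.clip(y, 0.0, None))


def _segment_bounds(protocol: TemperatureProtocol, t0: float,
                    t1: float) -> list[float]:
    cuts = [t for t in protocol.discontinuity_times() if t0 < t < t1]
    return [t0, *sorted(set(cuts)), t1]


def integrate(params: RateParameters, protocol: TemperatureProtocol,
              t_end: float, init: HSRState | np.ndarray | None = None, *,
              t_start: float = 0.0, t_eval: np.ndarray | None = None,
              n_points: int = 1201, method: str = "LSODA",
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
              check_conservation: bool = True) -> Trajectory:
    """Integrate the network under a protocol and return a Trajectory.

    If ``init`` is omitted the run starts from the steady state at the
    protocol's initial temperature.  The solver is restarted at every protocol
    discontinuity inside (t_start, t_end); output lands on ``t_eval`` or on a
    uniform grid of ``n_points``.
    """
    if t_eval is None:
        grid = np.linspace(t_start, t_end, n_points)
    else:
        grid = np.asarray(t_eval, dtype=float)
        if grid[0] < t_start or grid[-1] > t_end:
            raise ValueError("t_eval must lie within [t_start, t_end]")

    if init is None:
        # pre-equilibrate at the temperature just before t_start, so a shock
        # applied exactly at t_start starts from the unstressed culture
        T0 = kelvin_to_celsius(protocol.temperature_at(t_start - 1e-9))
        y0 = steady_state(params, T0, rtol=rtol, atol=atol).to_array()
    else:
        y0 = init.to_array() if isinstance(init, HSRState) else np.asarray(init, float)

    bounds = _segment_bounds(protocol, t_start, grid[-1])
    out = np.empty((len(grid), N_SPECIES))
    filled = np.zeros(len(grid), dtype=bool)
    y = y0.copy()
    raw_min = float(y.min())

    for a, b in zip(bounds[:-1], bounds[1:]):
        # clamp so piecewise protocols are evaluated strictly inside (a, b)
        eps = max((b - a) * 1e-12, 1e-9)
        temp_fn = lambda t, _a=a, _b=b, _e=eps: protocol.temperature_at(
            min(max(t, _a + _e), _b - _e))
        fun = lambda t, yy, _f=temp_fn: rhs_array(t, yy, params, _f)
        sel = (grid >= a) & (grid <= b) & ~filled
        seg_eval = np.unique(np.concatenate([grid[sel], [b]]))
        sol = solve_ivp(fun, (a, b), y, method=method, t_eval=seg_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"integration failed at t={sol.t[-1]:.6g} s: {sol.message}",
                t=float(sol.t[-1]), state=sol.y[:, -1])
        raw_min = min(raw_min, float(sol.y.min()))
        vals = {ti: sol.y[:, k] for k, ti in enumerate(sol.t)}
        for i in np.nonzero(sel)[0]:
            out[i] = vals[grid[i]]
            filled[i] = True
        y = sol.y[:, -1]

    if not filled.all():  # pragma: no cover - defensive
        raise IntegrationError("output grid not fully covered")

    traj = Trajectory(t=grid, y=np.clip(out, 0.0, None), protocol=protocol,
                      params=params, raw_min=raw_min)
    if check_conservation:
        drift = max(traj.pool_drift().values())
        if drift > 1e-6:
            warnings.warn(f"conserved-pool drift {drift:.3g} exceeds 1e-6; "
                          "tighten solver tolerances", RuntimeWarning)
    return traj


def _series_summary(t: np.ndarray, s: np.ndarray) -> dict[str, float]:
    i = int(np.argmax(s))  # earliest index wins ties by argmax convention
    return {"max": float(s[i]), "t_max": float(t[i]), "final": float(s[-1])}


def summarize(traj: Trajectory) -> dict:
    """Per-species maxima, times of maxima and final values, plus the peak
    misfolded and active-kinase fractions."""
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    out: dict = {name: _series_summary(traj.t, traj.species(name))
                 for name in SPECIES}
    out["misfolded_fraction"] = _series_summary(traj.t, traj.misfolded_fraction)
    out["active_kinase_fraction"] = _series_summary(
        traj.t, traj.active_kinase_fraction)
    return out
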