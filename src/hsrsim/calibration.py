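"""Calibration of rate constants against relative mRNA time courses.

The observations are max-normalized ("relative") time courses of the two
mRNA species, so simulated curves are likewise max-normalized over the
observation window before comparison.  The pipeline mirrors a standard
work flow: a pooled RMS objective, a Monte Carlo scan of a flat prior around
a fiducial set, selection of the best draws for projection plots, a steepest
descent refinement with finite-difference gradients in log-parameter space,
and a one-at-a-time local sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import KINETIC_CONSTANTS, RateParameters
from .protocols import Step, TemperatureProtocol
from .simulator import IntegrationError, SteadyStateError, integrate

#: Observable species: the two mRNAs quantified in feeding-experiment controls.
OBSERVABLE_SPECIES = ("mF", "mH")

#: Association-rate ceiling (mM^-1 s^-1) approximating the diffusion limit of
#: enzymatic association; second-order constants should stay below it.
DIFFUSION_LIMIT = 1.0e6


@dataclass(frozen=True)
class CalibrationDataset:
    """Relative mRNA time courses (one or more curves per species).

    ``observations`` columns: time_s, species ("mF"/"mH"), value (relative,
    in [0, 1] after per-curve max-normalization), curve_id.
    """

    observations: pd.DataFrame
    protocol: TemperatureProtocol = Step(25.0, 40.0, 0.0)

    def __post_init__(self):
        obs = self.observations
        required = {"time_s", "species", "value", "curve_id"}
        if missing := required - set(obs.columns):
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if unknown := set(obs["species"]) - set(OBSERVABLE_SPECIES):
            raise ValueError(f"unknown observed species: {sorted(unknown)}")
        for sp in OBSERVABLE_SPECIES:
            if not (obs["species"] == sp).any():
                raise ValueError(f"need at least one observation of {sp}")
        if (obs["time_s"] < 0).any():
            raise ValueError("observation times must be >= 0")
        if ((obs["value"] < 0) | (obs["value"] > 1 + 1e-12)).any():
            raise ValueError("relative values must lie in [0, 1]")

    @property
    def t_max(self) -> float:
        return float(self.observations["time_s"].max())

    def curve_counts(self) -> dict[str, int]:
        return {sp: self.observations.loc[self.observations["species"] == sp,
                                          "curve_id"].nunique()
                for sp in OBSERVABLE_SPECIES}

    def write_csv(self, path: str | Path) -> None:
        """Tidy CSV with a JSON comment header recording the protocol."""
        header = json.dumps({"protocol": repr(self.protocol)})
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            self.observations.to_csv(fh, index=False, float_format="%.17g")


def read_calibration_csv(path: str | Path,
                         protocol: TemperatureProtocol | None = None,
                         ) -> CalibrationDataset:
    """Read a dataset written by :meth:`CalibrationDataset.write_csv`.

    The JSON header records the generating protocol for provenance; pass
    ``protocol`` to set it explicitly (default: the standard 25->40 degC step).
    """
    obs = pd.read_csv(path, comment="#", float_precision="round_trip",
                      dtype={"time_s": float, "value": float,
                             "species": str, "curve_id": str})
    if protocol is None:
        return CalibrationDataset(observations=obs)
    return CalibrationDataset(observations=obs, protocol=protocol)


@dataclass(frozen=True)
class ScanResult:
    """Monte Carlo scan: sampled parameter sets and their RMS values."""

    samples: pd.DataFrame           # one column per scanned parameter
    rms: np.ndarray
    seed: int | None
    prior_range: tuple[float, float]
    fiducial: RateParameters

    def __post_init__(self):
        if len(self.samples) != len(self.rms):
            raise ValueError("samples and rms lengths disagree")
        if np.any(self.rms[np.isfinite(self.rms)] < 0):
            raise ValueError("RMS values must be non-negative")

    def __len__(self) -> int:
        return len(self.samples)

    def write(self, csv_path: str | Path,
              json_path: str | Path | None = None) -> None:
        out = self.samples.copy()
        out["rms"] = self.rms
        out.to_csv(csv_path, index=False, float_format="%.17g")
        if json_path is not None:
            Path(json_path).write_text(json.dumps({
                "seed": self.seed,
                "prior_range": list(self.prior_range),
                "n": len(self),
                "fiducial": {k: getattr(self.fiducial, k)
                             for k in self.samples.columns},
            }, indent=2))


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a steepest-descent refinement."""

    start: RateParameters
    final: RateParameters
    rms_history: list[float]
    converged: bool
    reason: str
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        h = np.asarray(self.rms_history)
        if len(h) == 0:
            raise ValueError("empty RMS history")
        if np.any(np.diff(h) > 0):
            raise ValueError("RMS history must be non-increasing")

    @property
    def rms_start(self) -> float:
        return self.rms_history[0]

    @property
    def rms_final(self) -> float:
        return self.rms_history[-1]

    def write(self, json_path: str | Path) -> None:
        Path(json_path).write_text(json.dumps({
            "rms_history": list(map(float, self.rms_history)),
            "converged": self.converged,
            "reason": self.reason,
            "options": self.options,
            "start": self.start.as_dict(),
            "final": self.final.as_dict(),
        }, indent=2))


def simulate_observables(params: RateParameters, data: CalibrationDataset,
                         n_points: int = 401) -> dict[str, np.ndarray]:
    """Max-normalized simulated curves at the dataset's observation times.

    Normalization uses the maximum over the species' observation times (not
    the dense grid), mirroring how relative data are normalized over their
    own sampling schedule.
    """
    t_end = data.t_max
    grid = np.union1d(np.linspace(0.0, t_end, n_points),
                      data.observations["time_s"].to_numpy(float))
    traj = integrate(params, data.protocol, t_end, t_eval=grid)
    out = {}
    for sp in OBSERVABLE_SPECIES:
        series = traj.species(sp)
        times = data.observations.loc[data.observations["species"] == sp,
                                      "time_s"].to_numpy(float)
        at_obs = np.interp(times, grid, series)
        peak = np.interp(np.unique(times), grid, series).max()
        out[sp] = at_obs / peak if peak > 0 else at_obs
    return out


def rms_objective(params: RateParameters, data: CalibrationDataset) -> float:
    """Pooled RMS between max-normalized simulation and relative data.

    All observation points of both species and all curves enter with equal
    weight.  An integration failure makes the parameter set infeasible and
    returns +inf (with a warning).
    """
    try:
        sim = simulate_observables(params, data)
    except (IntegrationError, SteadyStateError, ValueError) as exc:
        warnings.warn(f"objective infeasible: {exc}", RuntimeWarning)
        return float("inf")
    sq_sum, n = 0.0, 0
    for sp in OBSERVABLE_SPECIES:
        observed = data.observations.loc[data.observations["species"] == sp,
                                         "value"].to_numpy(float)
        sq_sum += float(((sim[sp] - observed) ** 2).sum())
        n += len(observed)
    return float(np.sqrt(sq_sum / n))


def validate_association_rates(params: RateParameters,
                               ceiling: float = DIFFUSION_LIMIT) -> list[str]:
    """Warn-level check that second-order constants stay below the
    diffusion-controlled limit; returns the offending parameter names."""
    offenders = [name for name in ("k_P", "k_FG", "k_FaG")
                 if getattr(params, name) > ceiling]
    for name in offenders:
        warnings.warn(f"{name} = {getattr(params, name):.3g} mM^-1 s^-1 "
                      f"exceeds the association-rate ceiling {ceiling:.3g}",
                      RuntimeWarning)
    return offenders


def mc_scan(data: CalibrationDataset, fiducial: RateParameters, n: int,
            prior_range: tuple[float, float] = (0.5, 2.0),
            seed: int | None = None,
            param_names: tuple[str, ...] = KINETIC_CONSTANTS,
            evaluate: bool = True) -> ScanResult:
    """Monte Carlo scan with a flat prior around the fiducial values.

    Each scanned parameter is drawn independently and uniformly (linear
    scale) in [low x fiducial, high x fiducial].  ``evaluate=False`` skips
    the objective (useful for studying the prior itself); the RMS column is
    then NaN.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    low, high = prior_range
    if not low < high and not low == high:
        raise ValueError("prior range must satisfy low <= high")
    rng = np.random.default_rng(seed)
    base = np.array([getattr(fiducial, k) for k in param_names])
    draws = rng.uniform(low * base, high * base, size=(n, len(param_names)))
    samples = pd.DataFrame(draws, columns=list(param_names))
    if evaluate:
        rms = np.empty(n)
        for i in range(n):
            p = fiducial.replace(**{k: draws[i, j]
                                    for j, k in enumerate(param_names)})
            rms[i] = rms_objective(p, data)
    else:
        rms = np.full(n, np.nan)
    return ScanResult(samples=samples, rms=rms, seed=seed,
                      prior_range=(low, high), fiducial=fiducial)


def select_best(scan: ScanResult, k: int) -> ScanResult:
    """The k lowest-RMS draws, ties broken by draw order."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scan):
        raise ValueError(f"k={k} exceeds the sample count {len(scan)}")
    order = np.argsort(scan.rms, kind="stable")[:k]
    order = np.sort(order)  # preserve draw order within the selection
    return ScanResult(samples=scan.samples.iloc[order].reset_index(drop=True),
                      rms=scan.rms[order], seed=scan.seed,
                      prior_range=scan.prior_range, fiducial=scan.fiducial)


def steepest_descent(data: CalibrationDataset, start: RateParameters,
                     param_names: tuple[str, ...] = KINETIC_CONSTANTS,
                     *, grad_step: float = 1e-3, alpha0: float = 0.1,
                     tol: float = 1e-4, max_iter: int = 200,
                     min_alpha: float = 1e-6) -> CalibrationResult:
    """Steepest descent on the RMS objective in log-parameter space.

    The gradient is estimated by central finite differences with relative
    step ``grad_step``; the step size is backtracked (halved) until the
    objective decreases, so the RMS history is non-increasing by
    construction.  Iteration stops when the relative improvement falls
    below ``tol``, the line search stalls, or ``max_iter`` is reached.
    """
    x = np.log([getattr(start, k) for k in param_names])

    def params_at(xv: np.ndarray) -> RateParameters:
        return start.replace(**{k: float(np.exp(v))
                                for k, v in zip(param_names, xv)})

    def f(xv: np.ndarray) -> float:
        return rms_objective(params_at(xv), data)

    current = f(x)
    if not np.isfinite(current):
        raise ValueError("objective is not finite at the starting parameters")
    history = [current]
    alpha = alpha0
    reason, converged = "max_iter", False

    for _ in range(max_iter):
        grad = np.empty_like(x)
        for j in range(len(x)):
            e = np.zeros_like(x)
            e[j] = grad_step
            grad[j] = (f(x + e) - f(x - e)) / (2.0 * grad_step)
        gnorm = np.max(np.abs(grad))
        if gnorm == 0 or not np.isfinite(gnorm):
            reason, converged = "zero_gradient", True
            break
        alpha = min(alpha * 2.0, alpha0)
        new = np.inf
        while alpha >= min_alpha:
            candidate = x - alpha * grad / gnorm
            new = f(candidate)
            if new < current:
                break
            alpha *= 0.5
        if not new < current:
            reason, converged = "line_search_stalled", True
            break
        x, improvement = candidate, (current - new) / max(current, 1e-300)
        current = new
        history.append(current)
        if improvement < tol:
            reason, converged = "tolerance", True
            break

    return CalibrationResult(
        start=start, final=params_at(x), rms_history=history,
        converged=converged, reason=reason,
        options={"param_names": list(param_names), "grad_step": grad_step,
                 "alpha0": alpha0, "tol": tol, "max_iter": max_iter})


def sensitivity(params: RateParameters, data: CalibrationDataset,
                epsilon: float = 0.05,
                param_names: tuple[str, ...] = KINETIC_CONSTANTS,
                ) -> pd.DataFrame:
    """One-at-a-time RMS response to +/- epsilon relative perturbations.

    Returns a frame indexed by parameter with the perturbed RMS values and
    their deltas against the unperturbed objective; non-finite entries mark
    infeasible perturbations.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    base = rms_objective(params, data)
    if not np.isfinite(base):
        raise ValueError("objective is not finite at the given parameters")
    rows = []
    for name in param_names:
        value = getattr(params, name)
        rms_minus = rms_objective(params.replace(**{name: (1 - epsilon) * value}),
                                  data) if epsilon > 0 else base
        rms_plus = rms_objective(params.replace(**{name: (1 + epsilon) * value}),
                                 data) if epsilon > 0 else base
        rows.append({"parameter": name, "rms_minus": rms_minus,
                     "rms_plus": rms_plus, "delta_minus": rms_minus - base,
                     "delta_plus": rms_plus - base})
    return pd.DataFrame(rows).set_index("parameter")
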