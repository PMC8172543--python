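"""Fit transport parameters, the global quantum correction, and cooling rates.

Three estimation problems:

* transport coefficients (D_B, D_C, k_h) from MD-like ensemble-averaged
  residue-energy traces, by least squares over all residues and times;
* a single quantum correction Q applied identically to all intramolecular
  channels of all variants, from experimental sensor peak times;
* the solvent cooling rate k_s from the exponential tail of a transient.

All fits are bounded derivative-free optimizations (coarse log-grid pre-scan
followed by Nelder–Mead / bounded scalar refinement) — objectives are cheap
(one exact master-equation integration each) and gradients are not available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._peaks import quadratic_peak
from .master_eq import EnergyTrajectory, integrate_master_equation, \
    sensor_transient
from .structure_net import EnergyNetwork, TransportParams, \
    apply_quantum_correction

#: optimizer bounds per parameter (1/ps or Å²/ps)
BOUNDS = {"D_B": (1e-6, 1e3), "D_C": (1e-6, 1e3), "k_h": (1e-6, 1e2),
          "Q": (1.0, 10.0)}


@dataclass
class FitResult:
    params: dict
    objective: float
    n_iter: int
    converged: bool
    model_traces: EnergyTrajectory | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"params": {k: float(v) for k, v in self.params.items()},
                "objective": float(self.objective),
                "n_iter": int(self.n_iter),
                "converged": bool(self.converged), **self.extras}


def _residual_sum(observed: EnergyTrajectory, model: EnergyTrajectory,
                  nodes: Sequence) -> float:
    r = 0.0
    for n in nodes:
        d = observed.node_series(n) - model.node_series(n)
        r += float(d @ d)
    return r


def fit_transport_coefficients(
        observed: EnergyTrajectory,
        build_network: Callable[[TransportParams], EnergyNetwork],
        free: Sequence[str],
        fixed: TransportParams,
) -> FitResult:
    """Least-squares fit of a subset of {D_B, D_C, k_h} to observed traces.

    ``build_network`` rebuilds the rate network for candidate parameters (the
    cooling rate k_s stays fixed at its experimental value, carried in
    ``fixed``). Residuals are summed squared energy differences over all
    residue nodes and all grid times. With ``free`` empty the fixed
    parameters are evaluated as-is.
    """
    free = list(free)
    for name in free:
        if name not in ("D_B", "D_C", "k_h"):
            raise ValueError(f"cannot free parameter {name!r}")
    grid = observed.times
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("observed traces need a time grid")
    res_nodes = [n for n in observed.nodes
                 if n not in ("HEATER_POOL", "SOLVENT")]

    def model_for(values: Mapping[str, float]) -> EnergyTrajectory:
        p = fixed.replace(**{k: float(v) for k, v in values.items()})
        net = build_network(p)
        if set(net.nodes) != set(observed.nodes):
            raise ValueError("observed traces and network template disagree "
                             "on the node set")
        return integrate_master_equation(net, grid=grid)

    if not free:
        model = model_for({})
        return FitResult({k: getattr(fixed, k) for k in ("D_B", "D_C", "k_h")},
                         _residual_sum(observed, model, res_nodes), 0, True,
                         model_traces=model)

    def objective(logx: np.ndarray) -> float:
        vals = {}
        for name, lx in zip(free, logx):
            lo, hi = BOUNDS[name]
            v = float(np.exp(lx))
            if not lo <= v <= hi:
                return 1e12 * (1 + abs(lx))
            vals[name] = v
        try:
            return _residual_sum(observed, model_for(vals), res_nodes)
        except FloatingPointError:
            return 1e12

    # coarse log-grid pre-scan around the fixed values
    best_x, best_f = None, np.inf
    start = np.log([max(getattr(fixed, n), 1e-3) for n in free])
    for shift in np.log([0.25, 0.5, 1.0, 2.0, 4.0]):
        x = start + shift
        f = objective(x)
        if f < best_f:
            best_x, best_f = x, f

    opt = minimize(objective, best_x, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 4000})
    values = {n: float(np.exp(v)) for n, v in zip(free, opt.x)}
    params = {k: values.get(k, getattr(fixed, k)) for k in ("D_B", "D_C", "k_h")}
    model = model_for(values)
    return FitResult(params, float(opt.fun), int(opt.nit), bool(opt.success),
                     model_traces=model)


def fit_quantum_correction(
        classical_networks: Mapping[str, EnergyNetwork],
        experimental_peak_times: Mapping[str, float],
        sensors: Mapping[str, object],
        grid: np.ndarray | None = None,
) -> FitResult:
    """Global fit of one quantum correction Q to all variants' peak times.

    Q scales every BB/HB/HC/HEAT rate of every variant identically (cooling
    untouched); the objective is the summed squared difference between each
    variant's modelled sensor peak time and its experimental peak time.
    The profile is scanned over [1, 10] and refined with a bounded scalar
    minimizer; a non-unimodal scan profile is flagged in ``extras``.
    """
    names = list(classical_networks)
    if not names:
        raise ValueError("need at least one variant")
    missing = [n for n in names if n not in experimental_peak_times]
    if missing:
        raise ValueError(f"missing experimental peak times for {missing}")
    if grid is None:
        grid = np.linspace(0.0, 50.0, 1001)

    def model_peaks(q: float) -> dict[str, float]:
        out = {}
        for n in names:
            net = apply_quantum_correction(classical_networks[n], q)
            traj = integrate_master_equation(net, grid=grid)
            out[n], _ = quadratic_peak(traj.times,
                                       sensor_transient(traj, sensors[n]))
        return out

    def objective(q: float) -> float:
        peaks = model_peaks(q)
        return sum((peaks[n] - experimental_peak_times[n]) ** 2 for n in names)

    q_scan = np.linspace(1.0, 10.0, 46)
    f_scan = np.array([objective(q) for q in q_scan])
    k = int(np.argmin(f_scan))
    unimodal = _is_unimodal(f_scan)
    lo = q_scan[max(k - 1, 0)]
    hi = q_scan[min(k + 1, q_scan.size - 1)]
    if lo == hi:
        q_best, f_best, nit = float(q_scan[k]), float(f_scan[k]), 0
    else:
        opt = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-5})
        q_best, f_best, nit = float(opt.x), float(opt.fun), int(opt.nfev)
    # boundary: Q is constrained to >= 1
    if objective(1.0) <= f_best:
        q_best, f_best = 1.0, float(objective(1.0))
    return FitResult({"Q": q_best}, f_best, nit, True,
                     extras={"model_peak_times_ps": model_peaks(q_best),
                             "scan_unimodal": unimodal})


def _is_unimodal(f: np.ndarray) -> bool:
    d = np.sign(np.diff(f))
    d = d[d != 0]
    return bool(np.all(np.diff(d) >= 0))   # decreasing then increasing


def fit_cooling_rate(times: np.ndarray, signal: np.ndarray,
                     tail_start: float) -> FitResult:
    """Cooling rate k_s from a log-linear fit of the post-peak transient tail.

    The tail beyond ``tail_start`` must lie past the transient's peak and be
    strictly positive; the fitted decay rate is reported with the dissipation
    time 1/k_s.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    t_peak, _ = quadratic_peak(times, signal)
    if tail_start < t_peak:
        raise ValueError(f"tail_start {tail_start} precedes the peak at "
                         f"{t_peak:.3g} ps")
    mask = times >= tail_start
    if mask.sum() < 2:
        raise ValueError("tail window contains fewer than two points")
    y = signal[mask]
    if np.any(y <= 0):
        raise ValueError("non-positive values in the fit tail")
    slope, intercept = np.polyfit(times[mask], np.log(y), 1)
    k_s = -float(slope)
    return FitResult({"k_s": k_s}, 0.0, 1, True,
                     extras={"dissipation_time_ps": 1.0 / k_s if k_s > 0
                             else np.inf,
                             "log_intercept": float(intercept)})
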