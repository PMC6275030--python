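"""Multi-arm calibration of the two-site model to tumor-volume time series.

The objective is the sum over all experimental arms, both sites and all
measurement times of squared *relative* volume errors,

    ERR(p) = sum_arms sum_{j=1,2} sum_ti ((V_j(ti; p) - V_j,data(ti)) / V_j,data(ti))^2
           + sum_{infiltration arms} (E_2(35; p)/E_2,ctrl(35; p) - R_data)^2,

where the second term compares the simulated Day-35 effector density of the
*non-irradiated* secondary tumor, relative to the untreated control, with the
measured immune-infiltration ratio.

Thirteen parameters are free -- K, a, d, w, w2, e, clr plus the per-dose
survival (SF) and immunogenic-death (AI) fractions at the three tested doses
(6, 8, 20 Gy) -- while the growth rate r and the exhaustion rate l are held
fixed.  Estimation runs a bounded trust-region least-squares solver from many
random (log-uniform) initializations and clusters the terminal parameter
vectors to report the dominant solution and the fraction of starts reaching
it.  The inner model solves use the batched fixed-step RK4 core, which makes
a full multistart affordable; see :func:`objective` for the adaptive-solver
evaluation of the same criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import _fastsim
from .dynamics import InitialConditionSpec, initial_state, simulate
from .parameters import (
    DoseResponseTable,
    ImmunotherapyProtocol,
    ModelParameters,
    RadiationProtocol,
)

__all__ = [
    "CalibrationArm",
    "CalibrationDataset",
    "FitReport",
    "FREE_PARAMETER_NAMES",
    "default_bounds",
    "params_from_vector",
    "objective",
    "residuals",
    "fit",
    "infiltration_ratio",
    "goodness_report",
]

#: Names and order of the 13 calibrated quantities.
FREE_PARAMETER_NAMES = ("K", "a", "d", "w", "w2", "e", "clr",
                        "SF6", "SF8", "SF20", "AI6", "AI8", "AI20")

_RATE_NAMES = FREE_PARAMETER_NAMES[:7]
_FRACTION_NAMES = FREE_PARAMETER_NAMES[7:]
_DOSE_OF = {"SF6": 6.0, "SF8": 8.0, "SF20": 20.0,
            "AI6": 6.0, "AI8": 8.0, "AI20": 20.0}


def default_bounds() -> dict[str, tuple[float, float]]:
    """Box bounds per free parameter (positivity + physiological plausibility).

    Rates span a few orders of magnitude around their plausible scales; the
    carrying capacity is bounded to [100, 1e4] mm^3 and SF/AI to (0, 1].
    """
    b = {"K": (100.0, 1e4), "a": (1e-4, 1.0), "d": (1e-3, 10.0),
         "w": (1e-3, 10.0), "w2": (0.1, 1e3), "e": (0.1, 1e3),
         "clr": (0.01, 10.0)}
    for name in _FRACTION_NAMES:
        b[name] = (1e-3, 1.0)
    return b


@dataclass
class CalibrationArm:
    """One experimental arm: protocols plus measured volume series.

    ``days`` are the measurement days; ``v1``/``v2`` the measured volumes
    (mm^3, must be positive -- they divide the residual).  An optional
    relative immune-infiltration ratio at ``infiltration_day`` contributes
    the second objective term.
    """

    arm_id: str
    rt: RadiationProtocol
    it: ImmunotherapyProtocol
    days: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    infiltration_ratio: float | None = None
    infiltration_day: float = 35.0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.v1 = np.asarray(self.v1, dtype=float)
        self.v2 = np.asarray(self.v2, dtype=float)
        if not (self.days.size == self.v1.size == self.v2.size):
            raise ValueError(f"arm {self.arm_id}: days/v1/v2 length mismatch")
        if np.any(self.v1 <= 0) or np.any(self.v2 <= 0):
            raise ValueError(f"arm {self.arm_id}: measured volumes must be > 0")

    @property
    def is_control(self) -> bool:
        return not self.rt.events and not self.it.injection_times

    @property
    def n_points(self) -> int:
        return 2 * self.days.size


@dataclass
class CalibrationDataset:
    """All arms of one bilateral-tumor experiment."""

    arms: list[CalibrationArm]
    ic: InitialConditionSpec = field(default_factory=InitialConditionSpec)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a.infiltration_ratio is not None for a in self.arms) \
                and not any(a.is_control for a in self.arms):
            raise ValueError("a control arm is required when infiltration "
                             "ratios are present")

    @property
    def n_points(self) -> int:
        return sum(a.n_points for a in self.arms)


def params_from_vector(x: np.ndarray,
                       fixed: dict[str, float] | None = None
                       ) -> tuple[ModelParameters, DoseResponseTable]:
    """Assemble (ModelParameters, DoseResponseTable) from a free vector.

    ``fixed`` supplies r and l (defaults: the published 0.195 and 0.03/day).
    """
    fixed = fixed or {}
    kv = dict(zip(FREE_PARAMETER_NAMES, np.asarray(x, dtype=float)))
    params = ModelParameters(r=fixed.get("r", 0.195), l=fixed.get("l", 0.03),
                             K=kv["K"], a=kv["a"], d=kv["d"], w=kv["w"],
                             w2=kv["w2"], e=kv["e"], clr=kv["clr"])
    table = DoseResponseTable(entries={
        6.0: (kv["SF6"], kv["AI6"]),
        8.0: (kv["SF8"], kv["AI8"]),
        20.0: (kv["SF20"], kv["AI20"])})
    return params, table


def _vector_from(params: ModelParameters, table: DoseResponseTable) -> np.ndarray:
    vals = [params.K, params.a, params.d, params.w, params.w2, params.e,
            params.clr]
    for prefix in ("SF", "AI"):
        for dose in (6.0, 8.0, 20.0):
            sf, ai = table.lookup(dose)
            vals.append(sf if prefix == "SF" else ai)
    return np.array(vals)


# ---------------------------------------------------------------------------
# Residuals

def _arm_schedules(arms: list[CalibrationArm], table: DoseResponseTable):
    schedules = []
    for arm in arms:
        impulses = [(t, *table.lookup(dose)) for t, dose in arm.rt.events]
        schedules.append(_fastsim.ArmSchedule(
            impulses=impulses, injections=list(arm.it.injection_times),
            dose_scale=arm.it.dose_scale))
    return schedules


def _fast_residuals(x: np.ndarray, data: CalibrationDataset,
                    fixed: dict[str, float] | None, step: float) -> np.ndarray:
    """Residual vector via the batched RK4 core; non-finite solves are
    mapped to a large flat penalty so the optimizer backs away."""
    params, table = params_from_vector(x, fixed)
    try:
        site_init = initial_state(data.ic, params)
        schedules = _arm_schedules(data.arms, table)
    except ValueError:
        return np.full(_n_residuals(data), 1e3)

    query = sorted({float(t) for arm in data.arms for t in arm.days}
                   | {arm.infiltration_day for arm in data.arms
                      if arm.infiltration_ratio is not None})
    query = np.asarray(query)
    t_end = max(query[-1],
                max((arm.rt.times[-1] for arm in data.arms if arm.rt.events),
                    default=0.0))
    states = _fastsim.batch_simulate(params, schedules, site_init, t_end,
                                     query, step=step)
    if not np.isfinite(states).all():
        return np.full(_n_residuals(data), 1e3)

    qidx = {t: i for i, t in enumerate(query)}
    out: list[np.ndarray] = []
    ctrl_idx = next((k for k, a in enumerate(data.arms) if a.is_control), None)
    for k, arm in enumerate(data.arms):
        sel = [qidx[float(t)] for t in arm.days]
        v1 = states[k, sel, 0:3].sum(axis=1)
        v2 = states[k, sel, 4:7].sum(axis=1)
        out.append((v1 - arm.v1) / arm.v1)
        out.append((v2 - arm.v2) / arm.v2)
    for k, arm in enumerate(data.arms):
        if arm.infiltration_ratio is None:
            continue
        i35 = qidx[arm.infiltration_day]
        e2 = _e2(states, k, i35)
        e2_ctrl = _e2(states, ctrl_idx, i35)
        if e2_ctrl <= 0:
            out.append(np.array([1e3]))
        else:
            out.append(np.array([e2 / e2_ctrl - arm.infiltration_ratio]))
    return np.concatenate(out)


def _e2(states: np.ndarray, k: int, i: int) -> float:
    v2 = states[k, i, 4:7].sum()
    return states[k, i, 7] / max(v2, 1e-10)


def _n_residuals(data: CalibrationDataset) -> int:
    return data.n_points + sum(a.infiltration_ratio is not None
                               for a in data.arms)


def residuals(x: np.ndarray, data: CalibrationDataset,
              fixed: dict[str, float] | None = None,
              step: float = 0.05) -> np.ndarray:
    """Unsquared residual vector entering the least-squares objective."""
    return _fast_residuals(np.asarray(x, dtype=float), data, fixed, step)


def objective(x: np.ndarray | tuple[ModelParameters, DoseResponseTable],
              data: CalibrationDataset,
              fixed: dict[str, float] | None = None,
              accurate: bool = False,
              step: float = 0.05) -> float:
    """Calibration error: squared relative volume errors + infiltration terms.

    ``x`` is either the 13-vector (order :data:`FREE_PARAMETER_NAMES`) or a
    (params, table) pair.  With ``accurate=True`` each arm is re-solved with
    the adaptive 1e-8-tolerance integrator instead of the fast RK4 core.
    """
    if isinstance(x, tuple):
        params, table = x
        x = _vector_from(params, table)
    if not accurate:
        r = residuals(x, data, fixed, step)
        return float(r @ r)

    params, table = params_from_vector(x, fixed)
    total = 0.0
    ctrl = next((a for a in data.arms if a.is_control), None)
    for arm in data.arms:
        horizon = max(float(arm.days.max()),
                      arm.rt.times[-1] if arm.rt.events else 0.0,
                      arm.infiltration_day if arm.infiltration_ratio is not None else 0.0)
        res = simulate(params, table, arm.rt, arm.it, data.ic, horizon=horizon,
                       output_grid=np.unique(np.concatenate(
                           [arm.days, [horizon]])))
        for site, obs in ((1, arm.v1), (2, arm.v2)):
            sim = np.array([res.volume(site, t) for t in arm.days])
            total += float(np.sum(((sim - obs) / obs) ** 2))
        if arm.infiltration_ratio is not None:
            ratio = infiltration_ratio(params, table, arm, ctrl, data.ic,
                                       day=arm.infiltration_day)
            total += (ratio - arm.infiltration_ratio) ** 2
    return total


def infiltration_ratio(params: ModelParameters, table: DoseResponseTable,
                       arm: CalibrationArm, control_arm: CalibrationArm | None,
                       ic: InitialConditionSpec | None = None,
                       day: float = 35.0) -> float:
    """Day-``day`` secondary-site effector density relative to control.

    Both the treated arm and the untreated control are simulated with the
    same parameters; the ratio E2(day)/E2_ctrl(day) is what the infiltration
    readout measures.
    """
    ic = ic or InitialConditionSpec()
    grid = np.array([day])
    e2 = simulate(params, table, arm.rt, arm.it, ic, horizon=day,
                  output_grid=grid).effector_density(2, day)
    if control_arm is None:
        ctrl_rt, ctrl_it = RadiationProtocol(), ImmunotherapyProtocol()
    else:
        ctrl_rt, ctrl_it = control_arm.rt, control_arm.it
    e2c = simulate(params, table, ctrl_rt, ctrl_it, ic, horizon=day,
                   output_grid=grid).effector_density(2, day)
    if e2c <= 0:
        raise ZeroDivisionError("control-arm E2 is zero at the readout day")
    return e2 / e2c


# ---------------------------------------------------------------------------
# Multistart fit

@dataclass
class FitReport:
    """Result of a multistart calibration."""

    parameters: dict[str, float]
    params: ModelParameters
    table: DoseResponseTable
    objective: float
    per_arm_residuals: dict[str, float]
    convergence_fraction: float
    clusters: list[dict]
    n_starts: int
    seed: int
    sensitivity: dict = field(default_factory=dict)


def _sample_starts(rng: np.random.Generator, bounds: dict, n: int) -> np.ndarray:
    """Log-uniform starts for rates, uniform for SF/AI fractions."""
    cols = []
    for name in FREE_PARAMETER_NAMES:
        lo, hi = bounds[name]
        if name in _FRACTION_NAMES:
            cols.append(rng.uniform(lo, hi, size=n))
        else:
            cols.append(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)))
    return np.column_stack(cols)


def _to_opt_space(x: np.ndarray) -> np.ndarray:
    z = x.copy()
    z[:7] = np.log10(z[:7])
    return z


def _from_opt_space(z: np.ndarray) -> np.ndarray:
    x = z.copy()
    x[:7] = 10.0 ** x[:7]
    return x


def fit(data: CalibrationDataset,
        fixed: dict[str, float] | None = None,
        n_starts: int = 50,
        seed: int = 0,
        bounds: dict[str, tuple[float, float]] | None = None,
        step: float = 0.05,
        max_nfev: int = 120,
        n_polish: int = 5,
        cluster_rtol: float = 0.01,
        x0: np.ndarray | None = None,
        verbose: int = 0) -> FitReport:
    """Multistart bounded trust-region estimation of the 13 free parameters.

    From ``n_starts`` random initializations (log-uniform within the bounds,
    uniform for the SF/AI fractions) a trust-region-reflective least-squares
    solve is run in log-rate space; the ``n_polish`` lowest-cost solutions
    are refined with a larger evaluation budget.  Terminal vectors are
    clustered at ``cluster_rtol`` relative tolerance; the report carries the
    best cluster's representative and the fraction of starts landing in it.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bounds = {**default_bounds(), **(bounds or {})}
    rng = np.random.default_rng(seed)
    starts = _sample_starts(rng, bounds, n_starts)
    if x0 is not None:
        starts[0] = np.asarray(x0, dtype=float)
    lo = _to_opt_space(np.array([bounds[n][0] for n in FREE_PARAMETER_NAMES]))
    hi = _to_opt_space(np.array([bounds[n][1] for n in FREE_PARAMETER_NAMES]))

    def res_opt(z):
        return residuals(_from_opt_space(z), data, fixed, step)

    solutions = []
    for i in range(n_starts):
        z0 = _to_opt_space(starts[i])
        try:
            sol = least_squares(res_opt, z0, bounds=(lo, hi), method="trf",
                                max_nfev=max_nfev)
        except Exception:
            continue
        solutions.append((float(sol.cost), sol.x.copy()))
        if verbose >= 2:
            print(f"start {i + 1}/{n_starts}: cost={sol.cost:.4g}")
    if not solutions:
        raise RuntimeError("all multistart optimizations failed")

    # Polish the best few candidates with a larger budget.
    solutions.sort(key=lambda s: s[0])
    polished = []
    for cost, z in solutions[:n_polish]:
        sol = least_squares(res_opt, z, bounds=(lo, hi), method="trf",
                            max_nfev=8 * max_nfev, xtol=1e-12, ftol=1e-12,
                            gtol=1e-12)
        polished.append((float(sol.cost), sol.x.copy()))
    polished.sort(key=lambda s: s[0])
    best_cost, best_z = polished[0]
    solutions[:n_polish] = polished

    # Cluster terminal vectors at relative tolerance (original scale).
    reps: list[dict] = []
    for cost, z in solutions:
        x = _from_opt_space(z)
        for cl in reps:
            ref = cl["x"]
            if np.all(np.abs(x - ref) <= cluster_rtol * np.maximum(np.abs(ref), 1e-12)):
                cl["count"] += 1
                if cost < cl["cost"]:
                    cl["cost"], cl["x"] = cost, x
                break
        else:
            reps.append({"cost": cost, "x": x, "count": 1})
    reps.sort(key=lambda c: c["cost"])
    best_cluster = reps[0]
    conv_fraction = best_cluster["count"] / n_starts

    x_best = _from_opt_space(best_z)
    params, table = params_from_vector(x_best, fixed)
    per_arm = {}
    pos = 0
    r_best = residuals(x_best, data, fixed, step)
    for arm in data.arms:
        n = arm.n_points
        per_arm[arm.arm_id] = float(np.sum(r_best[pos:pos + n] ** 2))
        pos += n

    return FitReport(
        parameters=dict(zip(FREE_PARAMETER_NAMES, x_best)),
        params=params, table=table,
        objective=float(r_best @ r_best),
        per_arm_residuals=per_arm,
        convergence_fraction=conv_fraction,
        clusters=[{"cost": c["cost"], "count": c["count"],
                   "parameters": dict(zip(FREE_PARAMETER_NAMES, c["x"]))}
                  for c in reps],
        n_starts=n_starts, seed=seed,
        sensitivity=_local_sensitivity(x_best, data, fixed, step),
    )


def _local_sensitivity(x: np.ndarray, data: CalibrationDataset,
                       fixed, step, rel_step: float = 1e-4) -> dict:
    """Finite-difference Jacobian diagnostics at the optimum.

    Reports per-parameter sensitivity norms and strongly correlated
    (weakly separable) parameter pairs such as the killing-rate /
    recruitment-rate pair.
    """
    r0 = residuals(x, data, fixed, step)
    J = np.empty((r0.size, x.size))
    for j in range(x.size):
        dx = x.copy()
        h = max(abs(x[j]) * rel_step, 1e-12)
        dx[j] += h
        J[:, j] = (residuals(dx, data, fixed, step) - r0) / h
    norms = np.linalg.norm(J, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Jn = J / np.where(norms > 0, norms, 1.0)
        corr = Jn.T @ Jn
    pairs = []
    for i in range(x.size):
        for j in range(i + 1, x.size):
            if abs(corr[i, j]) > 0.99:
                pairs.append((FREE_PARAMETER_NAMES[i], FREE_PARAMETER_NAMES[j],
                              float(corr[i, j])))
    return {"jacobian_norms": dict(zip(FREE_PARAMETER_NAMES, norms)),
            "correlated_pairs": pairs}


def goodness_report(x: np.ndarray | tuple[ModelParameters, DoseResponseTable],
                    data: CalibrationDataset,
                    fixed: dict[str, float] | None = None,
                    step: float = 0.05) -> dict:
    """Mean +/- SD of absolute and relative volumetric deviations.

    Deviations are computed per measurement point (both sites) and then
    aggregated; ``n_points`` equals the dataset size.
    """
    if isinstance(x, tuple):
        x = _vector_from(*x)
    params, table = params_from_vector(np.asarray(x, dtype=float), fixed)
    site_init = initial_state(data.ic, params)
    schedules = _arm_schedules(data.arms, table)
    query = sorted({float(t) for arm in data.arms for t in arm.days})
    t_end = max(max(query),
                max((arm.rt.times[-1] for arm in data.arms if arm.rt.events),
                    default=0.0))
    states = _fastsim.batch_simulate(params, schedules, site_init, t_end,
                                     np.asarray(query), step=step)
    qidx = {t: i for i, t in enumerate(query)}
    abs_dev, rel_dev = [], []
    for k, arm in enumerate(data.arms):
        sel = [qidx[float(t)] for t in arm.days]
        for cols, obs in (((0, 3), arm.v1), ((4, 7), arm.v2)):
            sim = states[k, sel, cols[0]:cols[1]].sum(axis=1)
            abs_dev.append(np.abs(sim - obs))
            rel_dev.append(np.abs(sim - obs) / obs)
    abs_dev = np.concatenate(abs_dev)
    rel_dev = np.concatenate(rel_dev)
    return {"n_points": int(abs_dev.size),
            "abs_mean_mm3": float(abs_dev.mean()),
            "abs_sd_mm3": float(abs_dev.std()),
            "rel_mean": float(rel_dev.mean()),
            "rel_sd": float(rel_dev.std())}
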