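"""Continuous tumor-immune dynamics and the event-driven simulator.

Per site i (i = 1, 2), with V_i = C_i + Dv_i + I_i and p_i = V_i/(V_1+V_2):

    dC_i/dt = r*C_i*(1 - V_i/K) - a*C_i*E_i
    dDv_i/dt = r*C_i*V_i/K + a*C_i*E_i - d*Dv_i
    dI_i/dt = -d*I_i
    d(V_i*E_i)/dt = -l*E_i*V_i + (1 + u(t))*p_i*w * sum_j (1 + w2*I_j/V_j)*V_j

Viable tumor grows logistically and is killed by effector cells; crowding and
immune kills route volume into the non-immunogenically dying compartment,
which clears at rate d.  The immunogenic compartment I is fed only by
radiation impulses (applied to the primary site between integration segments)
and clears at the same rate.  Effector recruitment at a site is proportional
to its share p_i of total burden and is amplified by immunogenic death
(w2*I/V) and by the checkpoint-blockade signal u(t), a sum of exponentially
cleared boluses.

The integrator state per site is (C, Dv, I, A) with A = V*E, because the
effector balance is written for the product; the user-facing quantity is the
density E = A / max(V, 1e-10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import (
    DoseResponseTable,
    ImmunotherapyProtocol,
    ModelParameters,
    RadiationProtocol,
    SystemState,
    TumorSiteState,
)
from .radiation import DoseResponseModel

__all__ = [
    "InitialConditionSpec",
    "SimulationResult",
    "immunotherapy_signal",
    "extravasation_probability",
    "rhs",
    "apply_radiation_impulse",
    "initial_state",
    "logistic_backsolve",
    "simulate",
]

#: Guard for E = A/V at vanishing volume, mm^3.
_EPS_VOLUME = 1e-10


@dataclass
class InitialConditionSpec:
    """Reconstruction of the experiment's initial conditions.

    Tumors are implanted at ``injection_days`` (primary first) and reach the
    palpable ``palpable_volumes`` at ``palpable_day`` when treatment starts.
    Viable volumes at the injection days are back-solved assuming pure
    logistic growth; dying compartments and (by default) effector density
    start at zero.
    """

    palpable_day: float = 12.0
    palpable_volumes: tuple[float, float] = (32.0, 21.0)
    injection_days: tuple[float, float] = (0.0, 2.0)
    initial_effector_density: float = 0.0

    def __post_init__(self) -> None:
        if not all(self.palpable_day > t for t in self.injection_days):
            raise ValueError("palpable_day must exceed both injection days")
        if not all(v > 0 for v in self.palpable_volumes):
            raise ValueError("palpable volumes must be > 0")
        if self.initial_effector_density < 0:
            raise ValueError("initial_effector_density must be >= 0")


def logistic_backsolve(Vp: float, dt: float, r: float, K: float) -> float:
    """Volume ``dt`` days before a logistic trajectory reaches ``Vp``.

    Closed form of the logistic curve: V0 = K*Vp / (Vp + (K - Vp)*exp(r*dt)).
    """
    if not Vp < K:
        raise ValueError(f"palpable volume {Vp} must be below carrying capacity {K}")
    if Vp <= 0:
        raise ValueError("palpable volume must be > 0")
    return K * Vp / (Vp + (K - Vp) * math.exp(r * dt))


def initial_state(spec: InitialConditionSpec,
                  params: ModelParameters) -> list[tuple[float, TumorSiteState]]:
    """Per-site (injection_day, state) pairs anchoring the simulation.

    Each site's viable volume at its injection day is the logistic back-solve
    of its palpable volume over the interval to ``palpable_day``.
    """
    out = []
    for day, vp in zip(spec.injection_days, spec.palpable_volumes):
        v0 = logistic_backsolve(vp, spec.palpable_day - day, params.r, params.K)
        out.append((day, TumorSiteState(C=v0, Dv=0.0, I=0.0,
                                        E=spec.initial_effector_density)))
    return out


def immunotherapy_signal(t: float, proto: ImmunotherapyProtocol,
                         e: float, clr: float) -> float:
    """Checkpoint-blockade recruitment signal u(t).

    Each bolus at time tbar contributes e*exp(-clr*(t - tbar)) for t >= tbar
    (the closed form of the convolution of Dirac administration with
    first-order clearance); zero before the first injection.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    amp = e * proto.dose_scale
    return sum(amp * math.exp(-clr * (t - tb))
               for tb in proto.injection_times if tb <= t)


def extravasation_probability(states: SystemState) -> tuple[float, float]:
    """Probability that a circulating effector cell exits at each site.

    Proportional to each site's share of total tumor volume; (0.5, 0.5) in
    the degenerate case of two empty sites (the recruitment term is then
    zero anyway).
    """
    v1 = states.site1.volume
    v2 = states.site2.volume
    tot = v1 + v2
    if tot <= 0:
        return 0.5, 0.5
    return v1 / tot, v2 / tot


def _rhs_packed(t: float, y: np.ndarray, p: ModelParameters, u: float) -> np.ndarray:
    """Derivatives of the packed state [C1, Dv1, I1, A1, C2, Dv2, I2, A2]."""
    out = np.empty(8)
    C1, D1, I1, A1, C2, D2, I2, A2 = y
    V1 = C1 + D1 + I1
    V2 = C2 + D2 + I2
    tot = V1 + V2
    if tot > 0:
        p1, p2 = V1 / tot, V2 / tot
    else:
        p1 = p2 = 0.5
    # (1 + w2*I_j/V_j)*V_j == V_j + w2*I_j, with the I/V -> 0 convention at V=0
    S = tot + p.w2 * (I1 + I2)
    rec = (1.0 + u) * p.w * S
    E1 = A1 / max(V1, _EPS_VOLUME)
    E2 = A2 / max(V2, _EPS_VOLUME)
    out[0] = p.r * C1 * (1.0 - V1 / p.K) - p.a * C1 * E1
    out[1] = p.r * C1 * V1 / p.K + p.a * C1 * E1 - p.d * D1
    out[2] = -p.d * I1
    out[3] = -p.l * A1 + rec * p1
    out[4] = p.r * C2 * (1.0 - V2 / p.K) - p.a * C2 * E2
    out[5] = p.r * C2 * V2 / p.K + p.a * C2 * E2 - p.d * D2
    out[6] = -p.d * I2
    out[7] = -p.l * A2 + rec * p2
    return out


def rhs(state: SystemState, params: ModelParameters, u: float) -> np.ndarray:
    """Time derivatives (dC1, dDv1, dI1, dA1, dC2, dDv2, dI2, dA2).

    ``u`` is the instantaneous immunotherapy signal.  A_i = V_i*E_i is the
    effector balance variable.  Negative state components are rejected.
    """
    y = np.array([state.site1.C, state.site1.Dv, state.site1.I,
                  state.site1.volume * state.site1.E,
                  state.site2.C, state.site2.Dv, state.site2.I,
                  state.site2.volume * state.site2.E])
    if np.any(y < 0):
        raise ValueError("state components must be non-negative")
    return _rhs_packed(state.t, y, params, u)


def apply_radiation_impulse(state: TumorSiteState, sf: float, ai: float) -> TumorSiteState:
    """Instantaneous redistribution of viable volume by one radiation fraction.

    C -> C*sf; the killed volume C*(1-sf) splits into immunogenic (fraction
    ai, into I) and non-immunogenic (into Dv) death.  Total volume and the
    effector density are unchanged across the impulse.
    """
    if not (0.0 <= sf <= 1.0):
        raise ValueError("sf must lie in [0, 1]")
    if not (0.0 <= ai <= 1.0):
        raise ValueError("ai must lie in [0, 1]")
    killed = state.C * (1.0 - sf)
    return TumorSiteState(C=state.C * sf,
                          Dv=state.Dv + killed * (1.0 - ai),
                          I=state.I + killed * ai,
                          E=state.E)


@dataclass
class SimulationResult:
    """Trajectories of both sites on a common output grid.

    ``trajectories[site][name]`` for site in {"site1", "site2"} and name in
    {"C", "Dv", "I", "E", "V"}.  Grid values at an exact event time are the
    post-impulse (right-continuous) state; ``events`` records the pre/post
    primary-site states of every radiation impulse.
    """

    times: np.ndarray
    trajectories: dict[str, dict[str, np.ndarray]]
    protocol_echo: dict = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    solver_info: dict = field(default_factory=dict)

    def volume(self, site: int, t: float | None = None) -> float | np.ndarray:
        v = self.trajectories[f"site{site}"]["V"]
        if t is None:
            return v
        return float(np.interp(t, self.times, v))

    def burden(self, t: float | None = None) -> float | np.ndarray:
        """Total tumor burden V1 + V2 (at time t if given, else the series)."""
        v = self.trajectories["site1"]["V"] + self.trajectories["site2"]["V"]
        if t is None:
            return v
        return float(np.interp(t, self.times, v))

    def effector_density(self, site: int, t: float) -> float:
        e = self.trajectories[f"site{site}"]["E"]
        return float(np.interp(t, self.times, e))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_day, site, compartment, value)."""
        rows = []
        for site, comps in self.trajectories.items():
            for name, vals in comps.items():
                rows.append(pd.DataFrame({
                    "time_day": self.times, "site": site,
                    "compartment": name, "value": vals}))
        return pd.concat(rows, ignore_index=True)


def _resolve_sf_ai(dose: float,
                   dose_response: Union[DoseResponseTable, DoseResponseModel]) -> tuple[float, float]:
    if isinstance(dose_response, DoseResponseTable):
        try:
            return dose_response.lookup(dose)
        except KeyError:
            raise KeyError(
                f"dose {dose} Gy not in the calibrated table and no continuous "
                "dose-response model was supplied to interpolate it") from None
    return dose_response.sf_ai(dose)


def _make_segment_rhs(params: ModelParameters, it: ImmunotherapyProtocol,
                      t_seg_start: float):
    """RHS closure for one smooth segment.

    The set of active boluses is frozen at the segment start: injection times
    are segment boundaries, so a bolus delivered at a segment's right edge
    belongs to the next segment.  This keeps u(t) smooth inside every solver
    step.
    """
    inj = np.asarray(it.injection_times, dtype=float)
    active = inj[inj <= t_seg_start + 1e-12]
    amp = params.e * it.dose_scale
    clr = params.clr

    def f(t, y):
        u = float(np.sum(amp * np.exp(-clr * (t - active)))) if active.size else 0.0
        return _rhs_packed(t, y, params, u)

    return f


def _unpack_site(y: np.ndarray, site_idx: int) -> TumorSiteState:
    C, Dv, I, A = (max(v, 0.0) for v in y[4 * site_idx:4 * site_idx + 4])
    V = C + Dv + I
    return TumorSiteState(C=C, Dv=Dv, I=I, E=A / max(V, _EPS_VOLUME))


def simulate(params: ModelParameters,
             dose_response: Union[DoseResponseTable, DoseResponseModel, None] = None,
             rt: RadiationProtocol | None = None,
             it: ImmunotherapyProtocol | None = None,
             ic: InitialConditionSpec | None = None,
             horizon: float = 32.0,
             output_grid: np.ndarray | None = None,
             rtol: float = 1e-8,
             atol: float = 1e-8,
             method: str = "RK45") -> SimulationResult:
    """Integrate the two-site model under a treatment protocol.

    The ODE system is integrated between consecutive discontinuities
    (radiation impulses, the secondary-site implantation, and immunotherapy
    injection times, at which u(t) jumps); at each radiation event the
    integrator is stopped, the impulse map applied to the target site with
    the (SF, AI) pair resolved for that event's dose, and integration
    restarted.  Default tolerances are 1e-8 absolute and relative; the
    default output grid has 0.1-day spacing.
    """
    rt = rt or RadiationProtocol()
    it = it or ImmunotherapyProtocol()
    ic = ic or InitialConditionSpec()
    if rt.events and dose_response is None:
        raise ValueError("a dose-response table or model is required when "
                         "radiation events are present")
    if any(t > horizon for t in rt.times):
        raise ValueError("radiation event after the simulation horizon")

    site_init = initial_state(ic, params)
    t0 = min(day for day, _ in site_init)
    if output_grid is None:
        output_grid = np.arange(t0, horizon + 1e-9, 0.1)
        if output_grid[-1] < horizon - 1e-9:
            output_grid = np.append(output_grid, horizon)
    grid = np.asarray(output_grid, dtype=float)
    if grid.size and (np.any(np.diff(grid) <= 0) or grid[0] < t0 - 1e-12
                      or grid[-1] > horizon + 1e-9):
        raise ValueError("output grid must be strictly increasing within "
                         f"[{t0}, {horizon}]")

    # Pre-resolve impulses; fail fast on unknown doses.
    impulses = {t: (dose, _resolve_sf_ai(dose, dose_response))
                for t, dose in rt.events}
    target_idx = rt.target_site - 1

    # Initial packed state at t0; sites implanted later start at zero and are
    # activated at their implantation day (before which they contribute
    # nothing to trafficking or recruitment).
    y = np.zeros(8)
    activations: dict[float, list[tuple[int, np.ndarray]]] = {}
    for site_idx, (day, st) in enumerate(site_init):
        packed = np.array([st.C, st.Dv, st.I, st.volume * st.E])
        if day <= t0 + 1e-12:
            y[4 * site_idx:4 * site_idx + 4] = packed
        else:
            activations.setdefault(day, []).append((site_idx, packed))

    breakpoints = set(impulses) | set(activations)
    breakpoints |= {t for t in it.injection_times if t0 < t < horizon}
    segment_edges = sorted({t0, horizon} | {t for t in breakpoints
                                            if t0 < t <= horizon})

    times_out: list[float] = []
    states_out: list[np.ndarray] = []
    events_log: list[dict] = []

    gi = 0
    while gi < grid.size and grid[gi] <= t0 + 1e-12:
        times_out.append(grid[gi])
        states_out.append(y.copy())
        gi += 1

    t_now = t0
    for t_next in segment_edges[1:]:
        seg_eval = []
        while gi < grid.size and grid[gi] <= t_next + 1e-12:
            seg_eval.append(min(grid[gi], t_next))
            gi += 1
        f = _make_segment_rhs(params, it, t_now)
        sol = solve_ivp(f, (t_now, t_next), y, method=method,
                        rtol=rtol, atol=atol,
                        t_eval=None, dense_output=bool(seg_eval))
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{t_now}, {t_next}]: {sol.message}")
        for tg in seg_eval:
            times_out.append(tg)
            states_out.append(sol.sol(tg))
        y = sol.y[:, -1].copy()

        for site_idx, packed in activations.get(t_next, []):
            y[4 * site_idx:4 * site_idx + 4] += packed
        if t_next in impulses:
            dose, (sf, ai) = impulses[t_next]
            pre = _unpack_site(y, target_idx)
            post = apply_radiation_impulse(pre, sf, ai)
            y[4 * target_idx:4 * target_idx + 4] = np.array(
                [post.C, post.Dv, post.I, post.volume * post.E])
            events_log.append({"time": t_next, "dose_gy": dose, "sf": sf,
                               "ai": ai, "pre": pre, "post": post})
        # grid points at an event time report the post-impulse state
        if (t_next in impulses or t_next in activations) and times_out \
                and abs(times_out[-1] - t_next) <= 1e-12:
            states_out[-1] = y.copy()
        t_now = t_next

    times = np.array(times_out)
    states = np.array(states_out)  # (n_t, 8)
    if states.size and states.min() < -1e-6:
        import warnings
        warnings.warn(f"compartment undershot to {states.min():.3g}; "
                      "clamping to 0 for reporting", stacklevel=2)
    states = np.clip(states, 0.0, None)

    trajectories = {}
    for site_idx in (0, 1):
        C = states[:, 4 * site_idx]
        Dv = states[:, 4 * site_idx + 1]
        I = states[:, 4 * site_idx + 2]
        A = states[:, 4 * site_idx + 3]
        V = C + Dv + I
        E = A / np.maximum(V, _EPS_VOLUME)
        trajectories[f"site{site_idx + 1}"] = {
            "C": C, "Dv": Dv, "I": I, "E": E, "V": V}

    return SimulationResult(
        times=times,
        trajectories=trajectories,
        protocol_echo={"radiation": rt, "immunotherapy": it,
                       "initial_conditions": ic},
        events=events_log,
        solver_info={"method": method, "rtol": rtol, "atol": atol,
                     "segment_edges": segment_edges},
    )
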