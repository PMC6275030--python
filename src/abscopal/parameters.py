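"""Core domain types: model parameters, dose-response tables, states, protocols.

The model tracks, at each of two spatially separated tumor sites, three tissue
compartments measured in mm^3 -- viable tumor ``C``, non-immunogenically dying
tissue ``Dv`` and immunogenically dying tissue ``I`` -- plus the local density
``E`` (cells/mm^3) of activated tumor-specific cytotoxic T lymphocytes.  The
measurable tumor volume is the sum ``V = C + Dv + I``; effector cells are
assumed not to contribute to caliper volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

__all__ = [
    "ModelParameters",
    "DoseResponseTable",
    "TumorSiteState",
    "SystemState",
    "RadiationProtocol",
    "ImmunotherapyProtocol",
    "total_volume",
    "default_parameters",
    "read_parameters",
    "write_parameters",
    "read_protocols",
    "write_protocols",
]


@dataclass
class ModelParameters:
    """Rate constants of the two-site tumor-immune model.

    Parameters
    ----------
    r : float
        Viable tumor volumetric growth rate, 1/day.
    K : float
        Tumor carrying capacity, mm^3 (shared by both sites).
    a : float
        CTL killing rate, mm^3/(cell*day).
    d : float
        Clearance rate of dying tissue, 1/day.
    l : float
        Effector-cell exhaustion (decay) rate, 1/day.
    w : float
        Baseline T-cell recruitment rate, cell/(mm^3*day).
    w2 : float
        Fold-change in recruitment per unit immunogenic-death fraction,
        dimensionless.
    e : float
        Initial fold-change in recruitment caused by one dose of the 9H10
        anti-CTLA-4 antibody, dimensionless.
    clr : float
        9H10 clearance rate, 1/day.
    """

    r: float = 0.195
    K: float = 1423.1
    a: float = 0.0177
    d: float = 0.264
    l: float = 0.03
    w: float = 0.135
    w2: float = 15.37
    e: float = 8.495
    clr: float = 0.967

    def __post_init__(self) -> None:
        for name in ("r", "K", "a", "d", "l", "w", "w2", "e", "clr"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if not self.r > 0:
            raise ValueError("r must be > 0")

    def replace(self, **kwargs) -> "ModelParameters":
        d = asdict(self)
        d.update(kwargs)
        return ModelParameters(**d)


@dataclass
class DoseResponseTable:
    """Calibrated per-dose survival (SF) and immunogenic-death (AI) fractions.

    ``entries`` maps dose in Gy to the pair ``(sf, ai)`` where ``sf`` is the
    fraction of viable tumor volume surviving one fraction of that dose and
    ``ai`` the fraction of the killed volume that dies immunogenically.
    """

    entries: dict[float, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dose, (sf, ai) in self.entries.items():
            if not dose > 0:
                raise ValueError(f"dose must be > 0, got {dose}")
            if not (0.0 <= sf <= 1.0 and 0.0 <= ai <= 1.0):
                raise ValueError(f"SF/AI at {dose} Gy must lie in [0, 1]")

    @property
    def doses(self) -> list[float]:
        return sorted(self.entries)

    def _match(self, dose: float, tol: float = 1e-9) -> float | None:
        for d in self.entries:
            if abs(d - dose) <= tol:
                return d
        return None

    def lookup(self, dose: float) -> tuple[float, float]:
        """Return (sf, ai) for a tabulated dose; KeyError otherwise."""
        d = self._match(dose)
        if d is None:
            raise KeyError(f"dose {dose} Gy not in table {self.doses}")
        return self.entries[d]

    def __contains__(self, dose: float) -> bool:
        return self._match(dose) is not None


@dataclass
class TumorSiteState:
    """Compartment state of one tumor site.

    ``C``, ``Dv``, ``I`` are volumes in mm^3 (viable, non-immunogenically
    dying, immunogenically dying); ``E`` is effector-cell density, cells/mm^3.
    """

    C: float = 0.0
    Dv: float = 0.0
    I: float = 0.0
    E: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C", "Dv", "I", "E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def volume(self) -> float:
        return self.C + self.Dv + self.I


def total_volume(state: TumorSiteState) -> float:
    """Measurable tumor volume V = C + Dv + I (mm^3)."""
    return state.C + state.Dv + state.I


@dataclass
class SystemState:
    """Full system state: time plus both tumor sites."""

    t: float
    site1: TumorSiteState
    site2: TumorSiteState

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be >= 0")


@dataclass
class RadiationProtocol:
    """Impulsive irradiation schedule for the target (primary) site.

    ``events`` is an ordered list of ``(day, dose_gy)``; times must be
    strictly increasing and doses positive.
    """

    events: list[tuple[float, float]] = field(default_factory=list)
    target_site: int = 1

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("radiation event times must be strictly increasing")
        if any(dose <= 0 for _, dose in self.events):
            raise ValueError("radiation doses must be > 0")
        if self.target_site not in (1, 2):
            raise ValueError("target_site must be 1 or 2")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.events]

    @classmethod
    def daily(cls, start_day: float, n_fractions: int, dose_gy: float) -> "RadiationProtocol":
        """n equal fractions on consecutive days starting at start_day."""
        if n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        return cls(events=[(start_day + k, dose_gy) for k in range(n_fractions)])


@dataclass
class ImmunotherapyProtocol:
    """Checkpoint-blockade (9H10) bolus injection schedule.

    Each injection multiplies the T-cell recruitment term through the signal
    u(t); ``dose_scale`` rescales the per-injection impact relative to the
    calibrated parameter ``e``.
    """

    injection_times: list[float] = field(default_factory=list)
    dose_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(t2 < t1 for t1, t2 in zip(self.injection_times, self.injection_times[1:])):
            raise ValueError("injection times must be non-decreasing")
        if self.dose_scale < 0:
            raise ValueError("dose_scale must be >= 0")


# ---------------------------------------------------------------------------
# Defaults and file I/O

#: Calibrated SF/AI values at the three experimentally tested doses (Gy).
_DEFAULT_TABLE = {
    20.0: (0.265, 0.194),
    8.0: (0.664, 0.984),
    6.0: (0.783, 0.367),
}


def default_parameters() -> tuple[ModelParameters, DoseResponseTable]:
    """Calibrated model parameters and per-dose response table.

    These are the published best-fit values for the bilateral TSA
    mouse-carcinoma experiment the model was trained on.
    """
    return ModelParameters(), DoseResponseTable(entries=dict(_DEFAULT_TABLE))


def write_parameters(path: Union[str, Path], params: ModelParameters,
                     table: DoseResponseTable | None = None) -> None:
    """Write a flat JSON parameter file (keys r, K, a, d, l, w, w2, e, clr,
    SF, AI with SF/AI as dose-keyed maps)."""
    doc: dict = asdict(params)
    if table is not None:
        doc["SF"] = {str(d): sf for d, (sf, _) in sorted(table.entries.items())}
        doc["AI"] = {str(d): ai for d, (_, ai) in sorted(table.entries.items())}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_parameters(path: Union[str, Path]) -> tuple[ModelParameters, DoseResponseTable | None]:
    doc = json.loads(Path(path).read_text())
    table = None
    sf = doc.pop("SF", None)
    ai = doc.pop("AI", None)
    if sf is not None or ai is not None:
        sf = sf or {}
        ai = ai or {}
        if set(sf) != set(ai):
            raise ValueError("SF and AI maps must share the same doses")
        table = DoseResponseTable(
            entries={float(k): (float(sf[k]), float(ai[k])) for k in sf})
    try:
        params = ModelParameters(**doc)
    except TypeError as exc:
        raise ValueError(f"unrecognised parameter key in {path}: {exc}") from exc
    return params, table


def write_protocols(path: Union[str, Path], rt: RadiationProtocol,
                    it: ImmunotherapyProtocol) -> None:
    """Write a protocol JSON file: radiation events plus immunotherapy days."""
    doc = {
        "radiation": [{"day": t, "dose_gy": d} for t, d in rt.events],
        "immunotherapy": {"days": list(it.injection_times),
                          "dose_scale": it.dose_scale},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_protocols(path: Union[str, Path]) -> tuple[RadiationProtocol, ImmunotherapyProtocol]:
    doc = json.loads(Path(path).read_text())
    try:
        events = [(float(ev["day"]), float(ev["dose_gy"]))
                  for ev in doc.get("radiation", [])]
    except KeyError as exc:
        raise ValueError(f"radiation event missing key {exc} in {path}") from exc
    it_doc = doc.get("immunotherapy", {})
    if not isinstance(it_doc, dict) or ("days" not in it_doc and it_doc):
        raise ValueError(f"malformed 'immunotherapy' section in {path}: expected key 'days'")
    rt = RadiationProtocol(events=events)
    it = ImmunotherapyProtocol(injection_times=[float(t) for t in it_doc.get("days", [])],
                               dose_scale=float(it_doc.get("dose_scale", 1.0)))
    return rt, it
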