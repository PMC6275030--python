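"""File formats: tidy CSV datasets and trajectories, JSON sidecars.

All artifacts are plain CSV/JSON.  Every metadata sidecar embeds the package
version, the seed and a hash of the generating configuration so that
identical (config, seed) runs are identifiable as such.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationArm, CalibrationDataset
from .dynamics import InitialConditionSpec, SimulationResult
from .parameters import ImmunotherapyProtocol, RadiationProtocol

__all__ = [
    "write_dataset", "read_dataset", "write_trajectory", "config_hash",
    "package_version",
]


def package_version() -> str:
    from . import __version__
    return __version__


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar(config: dict, seed=None) -> dict:
    return {"package_version": package_version(), "seed": seed,
            "config_hash": config_hash(config), "config": config}


def write_dataset(dataset: CalibrationDataset, data_csv, protocols_json,
                  infiltration_csv=None, seed=None) -> None:
    """Write a calibration dataset.

    ``data_csv``: tidy columns (arm_id, site, day, volume_mm3);
    ``protocols_json``: per-arm radiation/immunotherapy schedules plus
    initial-condition spec and metadata; ``infiltration_csv`` (optional):
    (arm_id, day, ratio) rows for arms carrying an infiltration readout.
    """
    rows = []
    for arm in dataset.arms:
        for site, vols in ((1, arm.v1), (2, arm.v2)):
            for day, v in zip(arm.days, vols):
                rows.append({"arm_id": arm.arm_id, "site": site,
                             "day": day, "volume_mm3": v})
    pd.DataFrame(rows).to_csv(data_csv, index=False)

    protos = {}
    for arm in dataset.arms:
        protos[arm.arm_id] = {
            "radiation": [{"day": t, "dose_gy": d} for t, d in arm.rt.events],
            "immunotherapy": {"days": list(arm.it.injection_times),
                              "dose_scale": arm.it.dose_scale},
        }
    ic = dataset.ic
    doc = {"arms": protos,
           "initial_conditions": {
               "palpable_day": ic.palpable_day,
               "palpable_volumes": list(ic.palpable_volumes),
               "injection_days": list(ic.injection_days),
               "initial_effector_density": ic.initial_effector_density},
           "metadata": {**dataset.metadata, **_sidecar(protos, seed)}}
    Path(protocols_json).write_text(json.dumps(doc, indent=2, default=float) + "\n")

    if infiltration_csv is not None:
        inf_rows = [{"arm_id": a.arm_id, "day": a.infiltration_day,
                     "ratio": a.infiltration_ratio}
                    for a in dataset.arms if a.infiltration_ratio is not None]
        pd.DataFrame(inf_rows, columns=["arm_id", "day", "ratio"]).to_csv(
            infiltration_csv, index=False)


def read_dataset(data_csv, protocols_json, infiltration_csv=None) -> CalibrationDataset:
    """Inverse of :func:`write_dataset`."""
    df = pd.read_csv(data_csv)
    required = {"arm_id", "site", "day", "volume_mm3"}
    if not required.issubset(df.columns):
        raise ValueError(f"{data_csv}: missing columns {required - set(df.columns)}")
    doc = json.loads(Path(protocols_json).read_text())
    ic_doc = doc.get("initial_conditions", {})
    ic = InitialConditionSpec(
        palpable_day=ic_doc.get("palpable_day", 12.0),
        palpable_volumes=tuple(ic_doc.get("palpable_volumes", (32.0, 21.0))),
        injection_days=tuple(ic_doc.get("injection_days", (0.0, 2.0))),
        initial_effector_density=ic_doc.get("initial_effector_density", 0.0))

    infiltration = {}
    if infiltration_csv is not None and Path(infiltration_csv).exists():
        for _, row in pd.read_csv(infiltration_csv).iterrows():
            infiltration[row["arm_id"]] = (float(row["ratio"]), float(row["day"]))

    arms = []
    for arm_id, proto in doc["arms"].items():
        sub = df[df["arm_id"] == arm_id]
        if sub.empty:
            raise ValueError(f"{data_csv}: no rows for arm '{arm_id}'")
        days = np.array(sorted(sub["day"].unique()), dtype=float)

        def series(site):
            s = sub[sub["site"] == site].set_index("day")["volume_mm3"]
            return np.array([s.loc[d] for d in days])

        try:
            rt = RadiationProtocol(events=[(float(ev["day"]), float(ev["dose_gy"]))
                                           for ev in proto.get("radiation", [])])
        except KeyError as exc:
            raise ValueError(f"{protocols_json}: arm '{arm_id}' radiation event "
                             f"missing key {exc}") from exc
        it_doc = proto.get("immunotherapy", {})
        it = ImmunotherapyProtocol(
            injection_times=[float(t) for t in it_doc.get("days", [])],
            dose_scale=float(it_doc.get("dose_scale", 1.0)))
        ratio, day = infiltration.get(arm_id, (None, 35.0))
        arms.append(CalibrationArm(arm_id=arm_id, rt=rt, it=it, days=days,
                                   v1=series(1), v2=series(2),
                                   infiltration_ratio=ratio,
                                   infiltration_day=day))
    return CalibrationDataset(arms=arms, ic=ic,
                              metadata=doc.get("metadata", {}))


def write_trajectory(result: SimulationResult, csv_path, meta_path=None,
                     seed=None, config: dict | None = None) -> None:
    """Tidy trajectory CSV (time_day, site, compartment, value) + sidecar."""
    result.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        config = config or {}
        meta = _sidecar(config, seed)
        meta["solver"] = result.solver_info
        meta["events"] = [{"time": ev["time"], "dose_gy": ev["dose_gy"],
                           "sf": ev["sf"], "ai": ev["ai"]}
                          for ev in result.events]
        Path(meta_path).write_text(json.dumps(meta, indent=2, default=float) + "\n")
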