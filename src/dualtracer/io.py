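"""Reading and writing the package's plain-text interchange formats.

TAC CSV
    Columns ``frame_start_min, frame_end_min, region, value_kBq_per_mL``
    with ``#``-prefixed header lines recording the decay-correction state,
    its reference time and the units.  All curves in one file share one
    frame schedule and decay state.

Study descriptor
    A YAML (or JSON) mapping with the injections (tracer, activity in MBq,
    injection time in minutes, half-life), the body weight and the name of
    the input-function region.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import FrameSchedule, InjectionEvent, TimeActivityCurve
from .pipeline import DualTracerStudy

__all__ = [
    "write_tacs_csv",
    "read_tacs_csv",
    "write_study_descriptor",
    "read_study_descriptor",
    "load_study",
    "write_report",
]


def write_tacs_csv(path, curves: dict) -> None:
    """Write named TACs (shared schedule and decay state) to CSV."""
    curves = dict(curves)
    if not curves:
        raise ValueError("no curves to write")
    first = next(iter(curves.values()))
    for name, tac in curves.items():
        if tac.decay_corrected != first.decay_corrected:
            raise ValueError("all curves in one file must share a decay state")
        if tac.schedule.n_frames != first.schedule.n_frames or not np.allclose(
            tac.schedule.start, first.schedule.start
        ):
            raise ValueError(f"curve {name!r} does not share the file schedule")
    rows = []
    for name, tac in curves.items():
        sched = tac.schedule
        for s, e, v in zip(sched.start, sched.end, tac.values):
            rows.append((s, e, name, v))
    frame = pd.DataFrame(rows, columns=[
        "frame_start_min", "frame_end_min", "region", "value_kBq_per_mL"])
    header = [
        f"# decay_corrected: {str(first.decay_corrected).lower()}",
        f"# decay_reference_min: {first.decay_reference_time if first.decay_corrected else ''}",
        "# units: kBq/mL",
    ]
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False)


def read_tacs_csv(path) -> dict:
    """Read a TAC CSV back into named :class:`TimeActivityCurve` objects."""
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, comment="#")
    decay_corrected = meta.get("decay_corrected", "false") == "true"
    ref_raw = meta.get("decay_reference_min", "")
    ref = float(ref_raw) if decay_corrected and ref_raw else None
    curves = {}
    for name, grp in frame.groupby("region", sort=False):
        grp = grp.sort_values("frame_start_min")
        start = grp["frame_start_min"].to_numpy(dtype=float)
        end = grp["frame_end_min"].to_numpy(dtype=float)
        sched = FrameSchedule(start, end - start)
        curves[name] = TimeActivityCurve(
            sched, grp["value_kBq_per_mL"].to_numpy(dtype=float),
            region_label=name, decay_corrected=decay_corrected,
            decay_reference_time=ref)
    return curves


def write_study_descriptor(path, injections, body_weight: float,
                           input_region: str = "blood") -> None:
    doc = {
        "body_weight_kg": float(body_weight),
        "input_region": input_region,
        "injections": [
            {
                "tracer": inj.tracer_name,
                "activity_mbq": float(inj.injected_activity),
                "time_min": float(inj.injection_time),
                "half_life_min": float(inj.half_life),
            }
            for inj in injections
        ],
    }
    path = Path(path)
    with path.open("w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_study_descriptor(path) -> dict:
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    doc["injections"] = [
        InjectionEvent(
            tracer_name=item["tracer"],
            injected_activity=float(item["activity_mbq"]),
            injection_time=float(item["time_min"]),
            half_life=float(item.get("half_life_min", 109.77)),
        )
        for item in doc["injections"]
    ]
    return doc


def load_study(descriptor_path, tacs_path) -> DualTracerStudy:
    """Assemble a :class:`DualTracerStudy` from a descriptor and a TAC file."""
    doc = read_study_descriptor(descriptor_path)
    curves = read_tacs_csv(tacs_path)
    input_region = doc.get("input_region", "blood")
    if input_region not in curves:
        raise ValueError(f"input region {input_region!r} missing from TAC file")
    input_curve = curves.pop(input_region)
    injections = doc["injections"]
    if len(injections) != 2:
        raise ValueError("study descriptor must list exactly two injections")
    return DualTracerStudy(
        injections=tuple(sorted(injections, key=lambda i: i.injection_time)),
        input_curve=input_curve,
        tissue_curves=curves,
        body_weight=float(doc["body_weight_kg"]),
    )


def write_report(report: dict, path) -> None:
    """Serialise an analysis report to JSON (deterministic key order)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
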