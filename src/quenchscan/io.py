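"""File formats: trace CSVs, fit tables, plate maps, TIFF image pairs,
protocol/parameter YAML.

Traces travel as long-format CSV (time_s, fluorescence, plate, well,
genotype, condition); predicted traces as CSV (time_s, unbound_fraction,
Cl_in_mM, I_in_mM, Vm_mV); images as one 16-bit TIFF per channel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image_quant import ImagePair
from .quench_model import Addition, PredictedTrace, ProtocolSpec, QuenchModelParams
from .trace_fit import FitResult, QuenchTrace

__all__ = [
    "write_predicted_trace",
    "read_traces_csv",
    "write_traces_csv",
    "write_fit_results",
    "read_protocol_yaml",
    "write_protocol_yaml",
    "read_params_yaml",
    "write_image_pair",
    "read_image_pair",
]


def write_predicted_trace(pred: PredictedTrace, path) -> None:
    pd.DataFrame({
        "time_s": pred.times,
        "unbound_fraction": pred.unbound_fraction,
        "Cl_in_mM": pred.Cl_in,
        "I_in_mM": pred.I_in,
        "Vm_mV": pred.Vm,
    }).to_csv(path, index=False)


def write_traces_csv(traces: list[QuenchTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "time_s": tr.times, "fluorescence": tr.fluorescence,
            "plate": tr.plate, "well": tr.well,
            "genotype": tr.genotype, "condition": tr.condition,
            "addition_times": ";".join(str(t) for t in tr.addition_times),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[QuenchTrace]:
    df = pd.read_csv(path, dtype={"plate": str, "well": str})
    traces = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=False):
        grp = grp.sort_values("time_s")
        adds = ()
        if "addition_times" in grp and isinstance(grp["addition_times"].iloc[0], str):
            adds = tuple(float(t) for t in grp["addition_times"].iloc[0].split(";") if t)
        traces.append(QuenchTrace(
            times=grp["time_s"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
            addition_times=adds,
            plate=str(plate), well=str(well),
            genotype=str(grp["genotype"].iloc[0]) if "genotype" in grp else "",
            condition=str(grp["condition"].iloc[0]) if "condition" in grp else "",
        ))
    return traces


def write_fit_results(results: list[tuple[QuenchTrace, FitResult]], path) -> None:
    rows = []
    for trace, res in results:
        row = {"plate": trace.plate, "well": trace.well,
               "genotype": trace.genotype, "condition": trace.condition}
        row.update(res.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_protocol_yaml(protocol: ProtocolSpec, path) -> None:
    doc = {
        "well_volume_start": protocol.well_volume_start,
        "frame_interval": protocol.frame_interval,
        "baseline_duration": protocol.baseline_duration,
        "total_duration": protocol.total_duration,
        "start_concentrations": dict(protocol.start_concentrations),
        "additions": [
            {"time": a.time, "volume": a.volume,
             "concentrations": dict(a.concentrations)}
            for a in protocol.additions
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_protocol_yaml(path) -> ProtocolSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return ProtocolSpec(
        well_volume_start=float(doc.get("well_volume_start", 100.0)),
        additions=tuple(
            Addition(float(a["time"]), float(a["volume"]),
                     {k: float(v) for k, v in a.get("concentrations", {}).items()})
            for a in doc.get("additions", [])
        ),
        frame_interval=float(doc.get("frame_interval", 2.0)),
        baseline_duration=float(doc.get("baseline_duration", 20.0)),
        total_duration=float(doc.get("total_duration", 290.0)),
        start_concentrations={
            k: float(v) for k, v in doc.get(
                "start_concentrations", {"Cl": 140.0, "I": 0.0, "fsk": 0.0}
            ).items()
        },
    )


def read_params_yaml(path) -> QuenchModelParams:
    doc = yaml.safe_load(Path(path).read_text())
    kw = {}
    for key in ("Vm", "G", "G_trans", "tau_trans"):
        if key in doc:
            kw[key] = float(doc[key])
    params = QuenchModelParams(**kw)
    if "constants" in doc:
        merged = dict(params.constants)
        merged.update({k: float(v) for k, v in doc["constants"].items()})
        params = params.with_(constants=merged)
    return params


def write_image_pair(pair: ImagePair, directory, stem: str) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p_mch = directory / f"{stem}_mcherry.tif"
    p_yfp = directory / f"{stem}_yfp.tif"
    tifffile.imwrite(p_mch, pair.mcherry.astype(np.uint16))
    tifffile.imwrite(p_yfp, pair.yfp.astype(np.uint16))
    return p_mch, p_yfp


def read_image_pair(mcherry_path, yfp_path, pixel_size: float, **meta) -> ImagePair:
    return ImagePair(
        mcherry=tifffile.imread(mcherry_path),
        yfp=tifffile.imread(yfp_path),
        pixel_size=pixel_size, **meta,
    )
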