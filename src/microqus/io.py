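"""On-disk formats.

A ScanSet is a directory: RF arrays in an HDF5 container (``scans.h5``,
datasets ``rf``, ``reference_no_tissue``, ``reference_with_tissue``,
``quartz_scan_for_incident``), a ``meta.json`` sidecar with all geometry,
seeds and the ground-truth phantom, and a ``ground_truth.csv`` per-layer
table. TER series travel as tidy CSV. All writers are deterministic
(HDF5 timestamps disabled, JSON keys sorted) so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .segmentation import ROIMask
from .synth.bscan import BScan, ReferenceEcho
from .synth.phantom import LayeredPhantom
from .synth.scanset import ScanConfig, ScanSet
from .synth.ter import TERTimeSeries

SCANS_FILENAME = "scans.h5"
META_FILENAME = "meta.json"
GROUND_TRUTH_FILENAME = "ground_truth.csv"


def _reference_meta(ref: ReferenceEcho) -> dict:
    return {
        "sampling_rate": ref.sampling_rate,
        "reflector_impedance": ref.reflector_impedance,
        "reflection_coefficient": ref.reflection_coefficient,
        "with_tissue": ref.with_tissue,
        "tissue_thickness": ref.tissue_thickness,
        "echo_time": ref.echo_time,
    }


def write_scan_set(scan_set: ScanSet, path) -> Path:
    """Write a ScanSet directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with h5py.File(path / SCANS_FILENAME, "w") as f:
        f.create_dataset("rf", data=scan_set.sample_scan.rf, track_times=False)
        for name, ref in [
            ("reference_no_tissue", scan_set.reference_no_tissue),
            ("reference_with_tissue", scan_set.reference_with_tissue),
            ("quartz_scan_for_incident", scan_set.quartz_scan_for_incident),
        ]:
            f.create_dataset(name, data=ref.waveform, track_times=False)

    scan = scan_set.sample_scan
    meta = {
        "seed": scan_set.seed,
        "config": scan_set.config.to_dict(),
        "bscan": {
            "sampling_rate": scan.sampling_rate,
            "line_pitch": scan.line_pitch,
            "sound_speed_assumed": scan.sound_speed_assumed,
            "depth_origin": scan.depth_origin,
        },
        "references": {
            "reference_no_tissue": _reference_meta(scan_set.reference_no_tissue),
            "reference_with_tissue": _reference_meta(scan_set.reference_with_tissue),
            "quartz_scan_for_incident": _reference_meta(scan_set.quartz_scan_for_incident),
        },
        "ground_truth": scan_set.ground_truth.to_dict(),
    }
    (path / META_FILENAME).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    truth = pd.DataFrame([
        {
            "layer_index": i,
            "name": layer.name,
            "thickness_mm": layer.thickness,
            "impedance_mrayl": layer.impedance,
            "attenuation_db_per_mm": layer.attenuation,
            "backscatter_strength": layer.backscatter_strength,
            "scatterer_density_per_mm2": layer.scatterer_density,
            "sound_speed_m_per_s": layer.sound_speed,
        }
        for i, layer in enumerate(scan_set.ground_truth.layers)
    ])
    truth.to_csv(path / GROUND_TRUTH_FILENAME, index=False)
    return path


def read_scan_set(path) -> ScanSet:
    """Read a ScanSet directory written by :func:`write_scan_set`."""
    path = Path(path)
    meta = json.loads((path / META_FILENAME).read_text())
    with h5py.File(path / SCANS_FILENAME, "r") as f:
        rf = f["rf"][...]
        waveforms = {
            name: f[name][...]
            for name in (
                "reference_no_tissue",
                "reference_with_tissue",
                "quartz_scan_for_incident",
            )
        }

    scan = BScan(rf=rf, **meta["bscan"])
    refs = {
        name: ReferenceEcho(waveform=waveforms[name], **meta["references"][name])
        for name in waveforms
    }
    config = ScanConfig.from_dict(meta["config"])
    return ScanSet(
        sample_scan=scan,
        reference_no_tissue=refs["reference_no_tissue"],
        reference_with_tissue=refs["reference_with_tissue"],
        quartz_scan_for_incident=refs["quartz_scan_for_incident"],
        ground_truth=LayeredPhantom.from_dict(meta["ground_truth"]),
        config=config,
        seed=meta["seed"],
    )


# ---------------------------------------------------------------- TER CSV

TER_COLUMNS = [
    "well_id",
    "condition",
    "time_min",
    "resistance_ohm",
    "blank_resistance_ohm",
    "membrane_area_cm2",
]


def write_ter_csv(series_list, path) -> Path:
    """Write TER series to the tidy CSV schema."""
    rows = []
    for s in series_list:
        for t, r in zip(s.time, s.resistance):
            rows.append(
                {
                    "well_id": s.well_id,
                    "condition": s.condition,
                    "time_min": t,
                    "resistance_ohm": r,
                    "blank_resistance_ohm": s.blank_resistance,
                    "membrane_area_cm2": s.membrane_area,
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=TER_COLUMNS).to_csv(path, index=False)
    return path


def read_ter_csv(path) -> list:
    """Read TER series from CSV; validates the schema before constructing."""
    df = pd.read_csv(path)
    missing = set(TER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TER CSV missing columns: {sorted(missing)}")
    out = []
    for well_id, g in df.groupby("well_id", sort=False):
        g = g.sort_values("time_min")
        out.append(
            TERTimeSeries(
                well_id=str(well_id),
                condition=str(g["condition"].iloc[0]),
                time=g["time_min"].to_numpy(float),
                resistance=g["resistance_ohm"].to_numpy(float),
                blank_resistance=float(g["blank_resistance_ohm"].iloc[0]),
                membrane_area=float(g["membrane_area_cm2"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------- masks


def write_mask_png(roi: ROIMask, path) -> Path:
    """Export the ROI mask as an 8-bit 0/255 PNG (lines as rows)."""
    path = Path(path)
    img = Image.fromarray((roi.mask.astype(np.uint8)) * 255, mode="L")
    img.save(path, format="PNG")
    return path


def mask_to_rle_frame(roi: ROIMask) -> pd.DataFrame:
    """Run-length encoding, one row per (line, start_sample, run_length)."""
    rows = []
    for j in range(roi.mask.shape[0]):
        m = roi.mask[j]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            rows.append({"line": j, "start_sample": int(start), "run_length": int(stop - start)})
    return pd.DataFrame(rows, columns=["line", "start_sample", "run_length"])


def write_mask_rle_csv(roi: ROIMask, path) -> Path:
    path = Path(path)
    mask_to_rle_frame(roi).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------- estimates


def estimate_to_frame(estimate, value_name: str) -> pd.DataFrame:
    """Per-line estimate values plus a summary row."""
    per_line = np.asarray(estimate.per_line, dtype=float)
    df = pd.DataFrame({"line": np.arange(per_line.size), value_name: per_line})
    summary = pd.DataFrame(
        {"line": ["mean", "std"], value_name: [estimate.mean, estimate.std]}
    )
    return pd.concat([df, summary], ignore_index=True)


def thickness_sweep_to_frame(thicknesses, estimates) -> pd.DataFrame:
    """Tidy (thickness, mean, std) table for impedance-vs-thickness curves."""
    return pd.DataFrame(
        {
            "thickness_mm": list(thicknesses),
            "impedance_mean_mrayl": [e.mean for e in estimates],
            "impedance_std_mrayl": [e.std for e in estimates],
        }
    )
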