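"""Readers and writers for the package's plain-text interchange formats.

CSV dialects (UTF-8, '.' decimal, header required):

* sweep:       ``frequency_hz, g_prime_pa, g_double_prime_pa``
* relaxation:  ``time_s, modulus_pa`` (or ``stress_pa`` plus a declared
  step-strain amplitude, which converts stress to modulus on read)
* cine:        ``frame_index, time_s, point_index, x_mm, y_mm`` with an
  optional ``surface`` column in {endo, epi}
* zone labels: ``segment_index, zone`` with zone in {infarct, border, remote}

Heart specifications travel as JSON with keys ``species``, ``g_myo_pa``,
``h_myo_mm``, ``h_graft_mm``, ``rate_band_hz``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .formulation import DesignResult, Formulation, HeartSpec
from .rheology import FrequencySweep, GelPoint, MaxwellSpectrum, RelaxationCurve
from .strain import CineSequence, ContourFrame, StrainMap, ZoneLabels

__all__ = [
    "read_sweep_csv",
    "write_sweep_csv",
    "read_relaxation_csv",
    "write_relaxation_csv",
    "read_cine_csv",
    "write_cine_csv",
    "read_zone_labels_csv",
    "read_heart_spec_json",
    "read_formulation_json",
    "design_result_to_dict",
    "gel_point_to_dict",
    "spectrum_to_dict",
    "strain_map_to_dict",
    "strain_map_to_frame",
]


def _require_columns(df: pd.DataFrame, required: set[str], path: Any) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing required columns {sorted(missing)}")


def read_sweep_csv(path: str | Path) -> FrequencySweep:
    df = pd.read_csv(path)
    _require_columns(df, {"frequency_hz", "g_prime_pa", "g_double_prime_pa"}, path)
    return FrequencySweep(
        df["frequency_hz"].to_numpy(float),
        df["g_prime_pa"].to_numpy(float),
        df["g_double_prime_pa"].to_numpy(float),
    )


def write_sweep_csv(sweep: FrequencySweep, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_hz": sweep.frequencies,
            "g_prime_pa": sweep.storage_moduli,
            "g_double_prime_pa": sweep.loss_moduli,
        }
    ).to_csv(path, index=False)


def read_relaxation_csv(path: str | Path, step_strain: float | None = None) -> RelaxationCurve:
    """Read a relaxation record; ``stress_pa`` columns need ``step_strain``."""
    df = pd.read_csv(path)
    _require_columns(df, {"time_s"}, path)
    if "modulus_pa" in df.columns:
        values = df["modulus_pa"].to_numpy(float)
    elif "stress_pa" in df.columns:
        if step_strain is None or step_strain <= 0:
            raise ConfigError(
                f"{path}: stress_pa column requires a positive declared step strain"
            )
        values = df["stress_pa"].to_numpy(float) / step_strain
    else:
        raise ConfigError(f"{path}: need a modulus_pa or stress_pa column")
    return RelaxationCurve(df["time_s"].to_numpy(float), values)


def write_relaxation_csv(curve: RelaxationCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": curve.times, "modulus_pa": curve.values}).to_csv(
        path, index=False
    )


def _frames_from_table(df: pd.DataFrame) -> tuple[ContourFrame, ...]:
    frames = []
    for idx, grp in df.groupby("frame_index", sort=True):
        grp = grp.sort_values("point_index")
        times = grp["time_s"].unique()
        if len(times) != 1:
            raise DataError(f"frame {idx}: inconsistent time_s values")
        frames.append(
            ContourFrame(float(times[0]), grp[["x_mm", "y_mm"]].to_numpy(float))
        )
    return tuple(frames)


def read_cine_csv(path: str | Path) -> CineSequence:
    df = pd.read_csv(path)
    _require_columns(df, {"frame_index", "time_s", "point_index", "x_mm", "y_mm"}, path)
    if "surface" in df.columns:
        surfaces = set(df["surface"].unique())
        if not surfaces <= {"endo", "epi"}:
            raise ConfigError(f"{path}: surface values must be 'endo' or 'epi'")
        endo = _frames_from_table(df[df["surface"] == "endo"])
        epi = _frames_from_table(df[df["surface"] == "epi"]) if "epi" in surfaces else None
        return CineSequence(endo, epicardial_frames=epi)
    return CineSequence(_frames_from_table(df))


def write_cine_csv(seq: CineSequence, path: str | Path) -> None:
    rows = []

    def emit(frames, surface):
        for i, frame in enumerate(frames):
            for j, (x, y) in enumerate(frame.points):
                row = {
                    "frame_index": i,
                    "time_s": frame.time,
                    "point_index": j,
                    "x_mm": x,
                    "y_mm": y,
                }
                if surface is not None:
                    row["surface"] = surface
                rows.append(row)

    if seq.epicardial_frames is not None:
        emit(seq.frames, "endo")
        emit(seq.epicardial_frames, "epi")
    else:
        emit(seq.frames, None)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_zone_labels_csv(path: str | Path, n_segments: int = 24) -> ZoneLabels:
    df = pd.read_csv(path)
    _require_columns(df, {"segment_index", "zone"}, path)
    idx = df["segment_index"].to_numpy(int)
    if sorted(idx) != list(range(n_segments)):
        raise ConfigError(
            f"{path}: segment_index must cover 0..{n_segments - 1} exactly once"
        )
    ordered = df.set_index("segment_index")["zone"]
    return ZoneLabels(tuple(str(ordered[k]) for k in range(n_segments)))


def read_heart_spec_json(path: str | Path) -> HeartSpec:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    try:
        band = doc["rate_band_hz"]
        return HeartSpec(
            myocardial_modulus=float(doc["g_myo_pa"]),
            wall_thickness=float(doc["h_myo_mm"]),
            graft_thickness=float(doc["h_graft_mm"]),
            heart_rate_band=(float(band[0]), float(band[1])),
            species=str(doc.get("species", "")),
        )
    except (KeyError, TypeError, IndexError, ValueError) as exc:
        raise ConfigError(f"{path}: malformed heart spec ({exc})") from exc


def read_formulation_json(path: str | Path) -> Formulation:
    try:
        doc = json.loads(Path(path).read_text())
        return Formulation(
            gtn_wt_percent=float(doc["gtn_wt_percent"]),
            fpba_fraction=float(doc["fpba_fraction"]),
            egcg_mM=float(doc.get("egcg_mM", 0.0)),
        )
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: malformed formulation ({exc})") from exc


def gel_point_to_dict(gp: GelPoint) -> dict:
    return {"f_gp_hz": gp.frequency, "g_gp_pa": gp.modulus}


def spectrum_to_dict(spectrum: MaxwellSpectrum) -> dict:
    return {
        "modes": [
            {"modulus_pa": m.modulus_weight, "relaxation_time_s": m.relaxation_time}
            for m in spectrum.modes
        ],
        "characteristic_time_s": spectrum.characteristic_time,
    }


def design_result_to_dict(result: DesignResult) -> dict:
    return {
        "formulation": {
            "gtn_wt_percent": result.formulation.gtn_wt_percent,
            "fpba_fraction": result.formulation.fpba_fraction,
            "egcg_mM": result.formulation.egcg_mM,
        },
        "predicted_gel_point": gel_point_to_dict(result.predicted_gel_point),
        "within_band": result.within_band,
        "target_modulus_pa": result.target_modulus,
    }


def strain_map_to_dict(strain_map: StrainMap) -> dict:
    return {
        "reference_frame_index": strain_map.reference_frame_index,
        "end_systole_frame_index": strain_map.end_systole_frame_index,
        "times_s": strain_map.times.tolist(),
        "strain_percent": strain_map.strains.tolist(),
        "strain_differential_percent": strain_map.differentials.tolist(),
    }


def strain_map_to_frame(strain_map: StrainMap) -> pd.DataFrame:
    """Tidy per-frame, per-segment table of strain and differentials."""
    n_frames, n_seg = strain_map.strains.shape
    frame_idx, seg_idx = np.meshgrid(np.arange(n_frames), np.arange(n_seg), indexing="ij")
    return pd.DataFrame(
        {
            "frame_index": frame_idx.ravel(),
            "time_s": np.repeat(strain_map.times, n_seg),
            "segment_index": seg_idx.ravel(),
            "strain_percent": strain_map.strains.ravel(),
            "strain_differential_percent": strain_map.differentials.ravel(),
        }
    )
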