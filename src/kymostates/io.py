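"""Readers and writers for the package's plain formats.

Kymographs travel as single-channel 32-bit float TIFF (row 0 = first
scan line) with a JSON sidecar carrying acquisition metadata, or as
delimited text with one scan line per row.  Traces, tracks and dwell
tables are CSV; fits and kinetic schemes are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .containers import HeightTrace, Kymograph, TopographyImage
from .dwells import DwellRecord
from .errors import ConfigurationError
from .states import IdealizedTrace


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_kymograph(kymo: Kymograph, path) -> None:
    """Write a kymograph as float32 TIFF (or ``.csv`` text) + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, kymo.heights.astype(np.float32))
    elif path.suffix.lower() in (".csv", ".txt"):
        np.savetxt(path, kymo.heights, delimiter=",", fmt="%.6g")
    else:
        raise ConfigurationError(f"unsupported kymograph format: {path.suffix}")
    meta = {
        "line_period_s": kymo.line_period,
        "pixel_size_nm": kymo.pixel_size,
        **{k: v for k, v in kymo.meta.items() if _jsonable(v)},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_kymograph(path, line_period: Optional[float] = None,
                   pixel_size: Optional[float] = None) -> Kymograph:
    """Read a TIFF or delimited-text kymograph; metadata comes from the
    JSON sidecar unless given explicitly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = np.asarray(tifffile.imread(path), dtype=float)
    else:
        heights = np.loadtxt(path, delimiter=",", dtype=float)
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    lp = line_period if line_period is not None else meta.get("line_period_s")
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_nm")
    if lp is None or px is None:
        raise ConfigurationError(
            "line_period and pixel_size must come from the sidecar or arguments"
        )
    return Kymograph(heights=heights, line_period=float(lp), pixel_size=float(px),
                     meta=meta)


def write_topography(img: TopographyImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.heights.astype(np.float32))
    _sidecar(path).write_text(json.dumps({"pixel_size_nm": img.pixel_size}))


def read_topography(path, pixel_size: Optional[float] = None) -> TopographyImage:
    path = Path(path)
    heights = np.asarray(tifffile.imread(path), dtype=float)
    if pixel_size is None:
        sidecar = _sidecar(path)
        if sidecar.exists():
            pixel_size = json.loads(sidecar.read_text()).get("pixel_size_nm")
    return TopographyImage(heights=heights, pixel_size=float(pixel_size or 1.0))


def write_trace(trace: HeightTrace, path) -> None:
    """CSV with header ``time_s,height_nm``."""
    df = pd.DataFrame({"time_s": trace.times, "height_nm": trace.heights})
    df.to_csv(path, index=False)


def read_trace(path) -> HeightTrace:
    df = pd.read_csv(path)
    return HeightTrace(times=df["time_s"].to_numpy(),
                       heights=df["height_nm"].to_numpy())


def write_truth(truth, path) -> None:
    """CSV with header ``t_change_s,state``: segment start times and labels."""
    starts = np.concatenate([[0.0], truth.change_times])
    df = pd.DataFrame({"t_change_s": starts, "state": truth.state_labels})
    df.to_csv(path, index=False)


def write_tracks(tracks: list, path) -> None:
    """CSV with one row per tracked line: track_id,line,position_px,gap_flag."""
    rows = []
    for t in tracks:
        for i, (pos, gap) in enumerate(zip(t.positions, t.gap_mask)):
            rows.append((t.track_id, t.first_line + i, pos, int(gap)))
    pd.DataFrame(rows, columns=["track_id", "line", "position_px", "gap_flag"]).to_csv(
        path, index=False
    )


def write_idealization(trace: HeightTrace, ideal: IdealizedTrace, path) -> None:
    """CSV with ``time_s,height_nm,fit_nm,state`` per sample."""
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "height_nm": trace.heights,
            "fit_nm": ideal.fitted(),
            "state": ideal.labels_per_sample(),
        }
    )
    df.to_csv(path, index=False)


def idealization_summary(ideal: IdealizedTrace) -> dict:
    from .states import classify_activity, compute_snr

    snr = compute_snr(ideal)
    return {
        "n_states": ideal.n_states,
        "state_heights_nm": ideal.state_heights.tolist(),
        "noise_sigma_nm": ideal.noise_sigma,
        "residual_std_nm": ideal.residual_std,
        "snr": None if np.isnan(snr) else snr,
        "active": classify_activity(ideal),
        "n_transitions": int(ideal.change_points.size),
    }


def write_dwell_table(records: list, path) -> None:
    """CSV dwell table: one row per :class:`DwellRecord`."""
    df = pd.DataFrame(
        [
            {
                "trace_id": r.trace_id,
                "state": r.state,
                "duration_s": r.duration,
                "height_nm": r.height,
                "prev": r.prev,
                "next": r.next,
                "left_cens": int(r.left_censored),
                "right_cens": int(r.right_censored),
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_dwell_table(path) -> list:
    df = pd.read_csv(path)

    def _opt(v):
        return None if pd.isna(v) else v

    records = []
    t = 0.0
    for row in df.itertuples(index=False):
        records.append(
            DwellRecord(
                state=row.state,
                duration=float(row.duration_s),
                t_start=t,
                t_end=t + float(row.duration_s),
                height=float(row.height_nm),
                prev=_opt(row.prev),
                next=_opt(row.next),
                left_censored=bool(row.left_cens),
                right_censored=bool(row.right_cens),
                trace_id=_opt(row.trace_id),
            )
        )
        t += float(row.duration_s)
    return records


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
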