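"""Two-channel compound-action-potential (CAP) analysis.

A recording holds time-aligned proximal and distal voltage traces from two
electrodes a known distance apart (3 cm in the reference setup).  The
pipeline is: locate the CAP peak on each channel (global maximum after an
artifact-blank window, refined to sub-sample precision by a three-point
quadratic fit), take the peak-to-peak latency, convert to conduction
velocity as distance/latency, and — given a healthy-control amplitude
ratio — compute a channel-block index from the distal/proximal amplitude
ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateLatencyError,
    DomainError,
    FormatError,
    NoPeakError,
)

__all__ = [
    "CapRecording",
    "CapMeasurement",
    "BlockIndex",
    "read_recording",
    "write_recording",
    "detect_peaks",
    "latency",
    "ncv_from_latency",
    "block_index",
    "analyze",
]

_COLUMNS = ("time_ms", "proximal_mV", "distal_mV")
_SIDECAR_KEYS = ("sampling_rate_khz", "electrode_distance_cm")


@dataclass(frozen=True)
class CapRecording:
    """Two-channel CAP recording with acquisition metadata.

    ``time_ms`` must be uniformly sampled at ``sampling_rate_khz`` (checked
    to 1e-6 relative); electrode distance in cm (3 cm default in the
    reference setup).
    """

    time_ms: np.ndarray
    proximal_mv: np.ndarray
    distal_mv: np.ndarray
    sampling_rate_khz: float
    electrode_distance_cm: float = 3.0
    stimulus_onset_ms: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        p = np.asarray(self.proximal_mv, dtype=float)
        d = np.asarray(self.distal_mv, dtype=float)
        if not (t.shape == p.shape == d.shape) or t.ndim != 1 or t.size < 2:
            raise FormatError(
                "time and both channels must be equal-length 1-D with "
                ">= 2 samples")
        if self.sampling_rate_khz <= 0:
            raise FormatError("sampling_rate_khz must be > 0")
        if self.electrode_distance_cm <= 0:
            raise FormatError("electrode_distance_cm must be > 0")
        dt = 1.0 / self.sampling_rate_khz
        steps = np.diff(t)
        if np.any(np.abs(steps - dt) > 1e-6 * max(dt, 1.0)):
            raise FormatError(
                "time_ms is not uniformly sampled at sampling_rate_khz "
                f"({self.sampling_rate_khz} kHz)")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "proximal_mv", p)
        object.__setattr__(self, "distal_mv", d)

    @property
    def n_samples(self) -> int:
        return self.time_ms.size

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_rate_khz


class BlockIndex(NamedTuple):
    value: float
    clamped: bool


@dataclass(frozen=True)
class CapMeasurement:
    """Derived quantities of one recording."""

    t_peak_proximal_ms: float
    t_peak_distal_ms: float
    latency_ms: float
    ncv_mps: float
    amplitude_proximal_mv: float
    amplitude_distal_mv: float
    block_index: float | None = None
    block_clamped: bool | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path,
                   sidecar: str | Path | None = None) -> CapRecording:
    """Read a recording CSV plus its metadata sidecar JSON.

    The CSV must carry the header ``time_ms, proximal_mV, distal_mV``; the
    sidecar (default: same stem with ``.json`` suffix) must define
    ``sampling_rate_khz`` and ``electrode_distance_cm`` and may define
    ``stimulus_onset_ms``.  Schema violations raise :class:`FormatError`
    naming the offending field.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else \
        path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar file {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar} is not valid JSON") from exc
    for key in _SIDECAR_KEYS:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing key {key!r}")
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(
            f"recording {path} missing column(s) {sorted(missing)}")
    return CapRecording(
        time_ms=df["time_ms"].to_numpy(),
        proximal_mv=df["proximal_mV"].to_numpy(),
        distal_mv=df["distal_mV"].to_numpy(),
        sampling_rate_khz=float(meta["sampling_rate_khz"]),
        electrode_distance_cm=float(meta["electrode_distance_cm"]),
        stimulus_onset_ms=(float(meta["stimulus_onset_ms"])
                           if "stimulus_onset_ms" in meta else None))


def write_recording(rec: CapRecording, path: str | Path,
                    sidecar: str | Path | None = None) -> None:
    """Write a recording to CSV + JSON sidecar in the reader's schema."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else \
        path.with_suffix(".json")
    pd.DataFrame({
        "time_ms": rec.time_ms,
        "proximal_mV": rec.proximal_mv,
        "distal_mV": rec.distal_mv,
    }).to_csv(path, index=False, float_format="%.9g")
    meta = {"sampling_rate_khz": rec.sampling_rate_khz,
            "electrode_distance_cm": rec.electrode_distance_cm}
    if rec.stimulus_onset_ms is not None:
        meta["stimulus_onset_ms"] = rec.stimulus_onset_ms
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")


# ---------------------------------------------------------------------------
# measurement primitives
# ---------------------------------------------------------------------------

def _channel_peak(t: np.ndarray, v: np.ndarray, blank_ms: float,
                  noise_floor_mv: float, label: str) -> tuple[float, float]:
    mask = t >= (t[0] + blank_ms)
    if not np.any(mask):
        raise NoPeakError(
            f"{label}: artifact-blank window {blank_ms} ms covers the "
            "whole recording")
    idx0 = np.argmax(mask)                 # first index after the blank
    seg = v[idx0:]
    i = int(np.argmax(seg)) + idx0
    amp = float(v[i])
    if amp <= noise_floor_mv:
        raise NoPeakError(
            f"{label}: maximum amplitude {amp:.4g} mV is at or below the "
            f"noise floor {noise_floor_mv} mV")
    if i == idx0 or i == v.size - 1:
        raise NoPeakError(
            f"{label}: maximum sits on the search-window boundary "
            "(no interior peak)")
    # three-point quadratic refinement around the maximum sample
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i]), amp
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    dt = t[1] - t[0]
    t_peak = float(t[i] + shift * dt)
    a_peak = float(y1 - 0.25 * (y0 - y2) * shift)
    return t_peak, a_peak


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="same")


def detect_peaks(rec: CapRecording, artifact_blank_ms: float = 0.3,
                 noise_floor_mv: float = 0.0,
                 smooth_window: int | None = None
                 ) -> tuple[float, float, float, float]:
    """Peak time and amplitude of each channel.

    The peak is the global maximum after the artifact-blank window
    (stimulus-onset time, if recorded, extends the blank), refined to
    sub-sample precision with a three-point quadratic fit.  Returns
    ``(t_prox, t_dist, a_prox, a_dist)``; flat or sub-noise-floor channels
    raise :class:`NoPeakError`.
    """
    if artifact_blank_ms < 0:
        raise DomainError("artifact_blank_ms must be >= 0")
    blank = artifact_blank_ms
    if rec.stimulus_onset_ms is not None:
        blank = max(blank, rec.stimulus_onset_ms - rec.time_ms[0]
                    + artifact_blank_ms)
    p = rec.proximal_mv
    d = rec.distal_mv
    if smooth_window:
        p = _smooth(p, smooth_window)
        d = _smooth(d, smooth_window)
    t_p, a_p = _channel_peak(rec.time_ms, p, blank, noise_floor_mv,
                             "proximal channel")
    t_d, a_d = _channel_peak(rec.time_ms, d, blank, noise_floor_mv,
                             "distal channel")
    return t_p, t_d, a_p, a_d


def latency(t_prox: float, t_dist: float) -> float:
    """Peak-to-peak latency ``t_dist - t_prox`` in ms; must be positive."""
    if not (np.isfinite(t_prox) and np.isfinite(t_dist)):
        raise DomainError("peak times must be finite")
    lat = t_dist - t_prox
    if lat <= 0:
        raise DegenerateLatencyError(
            f"non-positive latency {lat:.6g} ms "
            f"(t_prox={t_prox}, t_dist={t_dist})")
    return lat


def ncv_from_latency(lat_ms: float, distance_cm: float) -> float:
    """Conduction velocity in m/s: electrode distance over latency."""
    if lat_ms <= 0:
        raise DegenerateLatencyError(
            f"latency must be > 0 ms, got {lat_ms}")
    if distance_cm <= 0:
        raise DomainError(f"distance must be > 0 cm, got {distance_cm}")
    return (distance_cm / 100.0) / (lat_ms / 1000.0)


def block_index(a_prox: float, a_dist: float,
                baseline_ratio: float = 1.0) -> BlockIndex:
    """Channel-block index from the distal/proximal amplitude ratio.

    ``1 - (a_dist/a_prox)/baseline_ratio`` where ``baseline_ratio`` is the
    distal/proximal ratio of an untreated control; 0 means no block, 1 a
    complete block of the distal response.  The result is clamped to
    [0, 1]; the flag reports whether clamping occurred.  Invariant under a
    common gain on both channels.
    """
    if a_prox <= 0:
        raise DomainError(f"proximal amplitude must be > 0, got {a_prox}")
    if a_dist < 0:
        raise DomainError(f"distal amplitude must be >= 0, got {a_dist}")
    if baseline_ratio <= 0:
        raise DomainError(
            f"baseline ratio must be > 0, got {baseline_ratio}")
    raw = 1.0 - (a_dist / a_prox) / baseline_ratio
    clamped = float(np.clip(raw, 0.0, 1.0))
    return BlockIndex(value=clamped, clamped=clamped != raw)


def analyze(rec: CapRecording, artifact_blank_ms: float = 0.3,
            noise_floor_mv: float = 0.0, smooth_window: int | None = None,
            baseline_ratio: float | None = None) -> CapMeasurement:
    """Full deterministic measurement of one recording.

    Composes peak detection, latency, distance/latency NCV and — if a
    control amplitude ratio is supplied — the block index.
    """
    t_p, t_d, a_p, a_d = detect_peaks(
        rec, artifact_blank_ms=artifact_blank_ms,
        noise_floor_mv=noise_floor_mv, smooth_window=smooth_window)
    lat = latency(t_p, t_d)
    ncv = ncv_from_latency(lat, rec.electrode_distance_cm)
    bi = bc = None
    if baseline_ratio is not None:
        res = block_index(a_p, a_d, baseline_ratio)
        bi, bc = res.value, res.clamped
    return CapMeasurement(
        t_peak_proximal_ms=t_p, t_peak_distal_ms=t_d, latency_ms=lat,
        ncv_mps=ncv, amplitude_proximal_mv=a_p, amplitude_distal_mv=a_d,
        block_index=bi, block_clamped=bc)
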