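"""Seeded generators for testable surrogate data.

No public repository carries the recordings or SEM thickness tables this
toolkit analyzes, so these generators produce inputs with the same
statistical structure: two-channel CAP recordings as a biphasic
raised-cosine template with a programmed peak-to-peak latency plus Gaussian
noise, thickness-replicate tables with a programmed true demyelination
factor and multiplicative measurement scatter, and saturating
dose-response series of thickness loss versus venom concentration.  All
generators are deterministic given their seed and emit objects (or files)
that round-trip losslessly through the analysis readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cap_signals import CapRecording
from .exceptions import DomainError
from .quantification import ThicknessTable

__all__ = [
    "CapSpec",
    "ThicknessSpec",
    "gen_cap_recording",
    "gen_thickness_table",
    "gen_dose_series",
    "noise_sd_for_snr",
    "write_thickness_csv",
    "read_thickness_csv",
]


def noise_sd_for_snr(amplitude_mv: float, snr_db: float) -> float:
    """Noise SD giving the requested peak-amplitude-to-noise ratio in dB."""
    if amplitude_mv <= 0:
        raise DomainError("amplitude must be > 0")
    return amplitude_mv / 10.0 ** (snr_db / 20.0)


@dataclass(frozen=True)
class CapSpec:
    """Parameters of a synthetic two-channel CAP recording.

    The distal channel is the proximal template delayed by ``latency_ms``
    and scaled to ``amp_distal_mv``.  ``width_ms`` is the half-width of
    each raised-cosine lobe.  The recording must be long enough to contain
    both waveforms with margin: ``duration > t0 + latency + 3 * width``.
    """

    latency_ms: float
    amp_proximal_mv: float = 1.0
    amp_distal_mv: float = 0.9
    width_ms: float = 0.4
    sampling_rate_khz: float = 100.0
    duration_ms: float = 8.0
    noise_sd_mv: float = 0.0
    t0_ms: float = 1.0
    electrode_distance_cm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latency_ms <= 0:
            raise DomainError("latency must be > 0")
        if self.width_ms <= 0:
            raise DomainError("width must be > 0")
        if self.amp_proximal_mv <= 0 or self.amp_distal_mv <= 0:
            raise DomainError("amplitudes must be > 0")
        if self.noise_sd_mv < 0:
            raise DomainError("noise SD must be >= 0")
        if self.sampling_rate_khz <= 0:
            raise DomainError("sampling rate must be > 0")
        if self.duration_ms <= self.t0_ms + self.latency_ms + \
                3.0 * self.width_ms:
            raise DomainError(
                "duration must exceed t0 + latency + 3*width "
                f"(got {self.duration_ms} ms)")

    @property
    def programmed_ncv_mps(self) -> float:
        """The conduction velocity implied by latency and distance."""
        return (self.electrode_distance_cm / 100.0) / \
            (self.latency_ms / 1000.0)


def _biphasic(t: np.ndarray, center: float, amp: float,
              width: float) -> np.ndarray:
    """Raised-cosine biphasic waveform: positive main lobe at ``center``
    (half-width ``width``), then a 0.35-amplitude negative after-lobe.
    The after-lobe vanishes in a neighbourhood of ``center``, so the global
    maximum sits exactly at ``center``."""
    def lobe(c: float) -> np.ndarray:
        x = (t - c) / width
        out = np.where(np.abs(x) <= 1.0,
                       np.cos(0.5 * math.pi * x) ** 2, 0.0)
        return out
    return amp * lobe(center) - 0.35 * amp * lobe(center + 1.2 * width)


def gen_cap_recording(spec: CapSpec) -> CapRecording:
    """Generate a seeded synthetic recording per ``spec``.

    Channel templates are centered at ``t0`` (proximal) and
    ``t0 + latency`` (distal) with independent zero-mean Gaussian noise of
    SD ``noise_sd_mv`` on each channel.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_ms * spec.sampling_rate_khz))
    t = np.arange(n) / spec.sampling_rate_khz
    prox = _biphasic(t, spec.t0_ms, spec.amp_proximal_mv, spec.width_ms)
    dist = _biphasic(t, spec.t0_ms + spec.latency_ms, spec.amp_distal_mv,
                     spec.width_ms)
    if spec.noise_sd_mv > 0:
        prox = prox + rng.normal(0.0, spec.noise_sd_mv, size=n)
        dist = dist + rng.normal(0.0, spec.noise_sd_mv, size=n)
    return CapRecording(
        time_ms=t, proximal_mv=prox, distal_mv=dist,
        sampling_rate_khz=spec.sampling_rate_khz,
        electrode_distance_cm=spec.electrode_distance_cm)


@dataclass(frozen=True)
class ThicknessSpec:
    """Parameters of a synthetic myelin-thickness replicate table.

    Replicates are drawn as ``d0 * (1 - true_gamma) * (1 + cv * z)`` with
    standard-normal ``z`` — multiplicative measurement scatter of relative
    SD ``cv`` around the true demyelinated thickness.  Non-positive draws
    are resampled so the replicate count stays exact.
    """

    d0_um: float = 1.79
    true_gamma: float = 0.0
    cv: float = 0.1
    n: int = 6
    treatment: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d0_um <= 0:
            raise DomainError("d0 must be > 0")
        if not 0.0 <= self.true_gamma < 1.0:
            raise DomainError("true_gamma must be in [0, 1)")
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        if self.n < 2:
            raise DomainError("need n >= 2 replicates")


def gen_thickness_table(spec: ThicknessSpec) -> ThicknessTable:
    """Generate a seeded replicate table per ``spec``."""
    rng = np.random.default_rng(spec.seed)
    center = spec.d0_um * (1.0 - spec.true_gamma)
    draws: list[float] = []
    while len(draws) < spec.n:
        d = center * (1.0 + spec.cv * rng.standard_normal())
        if d > 0:
            draws.append(float(d))
    return ThicknessTable(treatment=spec.treatment,
                          thicknesses=tuple(draws))


def gen_dose_series(concentrations_ug_ml, delta_max_um: float,
                    half_sat_ug_ml: float, noise_sd_um: float = 0.0,
                    seed: int = 0) -> pd.DataFrame:
    """Saturating thickness-loss-versus-dose series.

    Expected loss follows the hyperbolic saturation law
    ``delta_d(c) = delta_max * c / (half_sat + c)`` — fast initial rise,
    plateau at ``delta_max`` — plus additive Gaussian noise.  Returns a
    DataFrame with columns ``concentration_ug_ml`` and ``delta_d_um``.
    """
    conc = np.asarray(list(concentrations_ug_ml), dtype=float)
    if np.any(conc < 0):
        raise DomainError("concentrations must be >= 0")
    if delta_max_um <= 0:
        raise DomainError("delta_max must be > 0")
    if half_sat_ug_ml <= 0:
        raise DomainError("half_sat must be > 0")
    if noise_sd_um < 0:
        raise DomainError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    dd = delta_max_um * conc / (half_sat_ug_ml + conc)
    if noise_sd_um > 0:
        dd = dd + rng.normal(0.0, noise_sd_um, size=conc.size)
    return pd.DataFrame({"concentration_ug_ml": conc, "delta_d_um": dd})


# ---------------------------------------------------------------------------
# thickness-table file schema shared with the CLI
# ---------------------------------------------------------------------------

def write_thickness_csv(tables, path: str | Path) -> None:
    """Write tables as tidy CSV: treatment, replicate, thickness_um."""
    rows = [
        {"treatment": t.treatment, "replicate": i + 1, "thickness_um": x}
        for t in tables for i, x in enumerate(t.thicknesses)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_thickness_csv(path: str | Path) -> list[ThicknessTable]:
    """Read the tidy thickness schema back into per-treatment tables."""
    df = pd.read_csv(path)
    missing = {"treatment", "thickness_um"} - set(df.columns)
    if missing:
        raise DomainError(
            f"thickness table {path} missing column(s) {sorted(missing)}")
    return [
        ThicknessTable(treatment=str(label),
                       thicknesses=tuple(sub["thickness_um"].tolist()))
        for label, sub in df.groupby("treatment", sort=False)]
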