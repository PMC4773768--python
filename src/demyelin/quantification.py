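"""Demyelination quantification.

Three routes to the demyelination factor gamma:

* anatomically, from myelin thickness: ``gamma = (D0 - D)/D0`` where ``D0``
  is the healthy (baseline) thickness and ``D`` the treated thickness, both
  in um — with ``delta_d = D0 - D`` the absolute thickness loss;
* electrophysiologically, by simulating the NCV-versus-gamma curve for a
  calibrated model and inverting a measured conduction velocity through it
  (the curve is strictly decreasing, so the inverse is well defined);
* statistically, replicate summaries (mean, sample SD) matching the
  six-replicate design of the underlying experiments.

``calibrate_baseline`` anchors a surrogate parameterization to a measured
healthy-nerve velocity by bisecting on the internodal length — the single
knob to which velocity responds monotonically — so gamma estimates inherit
the measured baseline rather than the surrogate defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    DomainError,
    ExtrapolationError,
    NegativeDemyelinationError,
    PropagationFailureError,
)
from . import bundle_simulator as sim
from .model_core import ModelConfig

__all__ = [
    "gamma_from_thickness",
    "delta_d",
    "replicate_stats",
    "ThicknessTable",
    "summarize_thickness",
    "NcvCurve",
    "ncv_curve",
    "gamma_from_ncv",
    "CalibrationResult",
    "calibrate_baseline",
    "simulate_ncv",
]

#: Default gamma grid: 13 points on [0, 0.6], spacing 0.05.
DEFAULT_GAMMA_GRID = np.round(np.linspace(0.0, 0.6, 13), 10)


# ---------------------------------------------------------------------------
# thickness-based quantification
# ---------------------------------------------------------------------------

def gamma_from_thickness(d0: float, d: float, clamp: bool = False) -> float:
    """Demyelination factor ``(d0 - d)/d0`` from myelin thicknesses (um).

    ``d0`` is the baseline (healthy) thickness, ``d`` the measured treated
    thickness.  A thickness above baseline raises
    :class:`NegativeDemyelinationError` unless ``clamp`` is set, in which
    case 0 is returned.  Summaries report two decimals; this returns the
    raw value.
    """
    if d0 <= 0:
        raise DomainError(f"baseline thickness must be > 0, got {d0}")
    if d <= 0:
        raise DomainError(f"thickness must be > 0, got {d}")
    if d > d0:
        if clamp:
            return 0.0
        raise NegativeDemyelinationError(
            f"thickness {d} um exceeds baseline {d0} um "
            "(pass clamp=True to clip at 0)")
    return (d0 - d) / d0


def delta_d(d0: float, d: float) -> float:
    """Absolute myelin-thickness loss ``d0 - d`` in um.

    Identically ``gamma_from_thickness(d0, d) * d0``.
    """
    if d0 <= 0:
        raise DomainError(f"baseline thickness must be > 0, got {d0}")
    if d <= 0:
        raise DomainError(f"thickness must be > 0, got {d}")
    if d > d0:
        raise NegativeDemyelinationError(
            f"thickness {d} um exceeds baseline {d0} um")
    return d0 - d


def replicate_stats(values: Iterable[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of replicates."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise DomainError(
            f"need at least 2 replicates, got {arr.size}")
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass(frozen=True)
class ThicknessTable:
    """Replicate myelin thicknesses (um) for one treatment."""

    treatment: str
    thicknesses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thicknesses) < 2:
            raise DomainError("need at least 2 replicate thicknesses")
        if any(t <= 0 for t in self.thicknesses):
            raise DomainError("thicknesses must be > 0")

    @property
    def n(self) -> int:
        return len(self.thicknesses)

    @property
    def mean(self) -> float:
        return replicate_stats(self.thicknesses)[0]

    @property
    def sd(self) -> float:
        return replicate_stats(self.thicknesses)[1]

    def gamma(self, d0: float, clamp: bool = False) -> float:
        """Demyelination factor of the replicate mean against ``d0``."""
        return gamma_from_thickness(d0, self.mean, clamp=clamp)

    def delta_d(self, d0: float) -> float:
        return delta_d(d0, self.mean)


def summarize_thickness(tables: Sequence[ThicknessTable],
                        baseline_label: str) -> pd.DataFrame:
    """Per-treatment report: n, mean, SD, delta_d and gamma (2-dp rounded).

    The baseline thickness ``D0`` is the replicate mean of the table whose
    treatment equals ``baseline_label``.  Gamma is clamped at 0 for
    treatments measuring thicker than baseline (scatter in controls).
    """
    by_label = {t.treatment: t for t in tables}
    if baseline_label not in by_label:
        raise DomainError(
            f"baseline label {baseline_label!r} not among "
            f"{sorted(by_label)}")
    d0 = by_label[baseline_label].mean
    rows = []
    for t in tables:
        g = t.gamma(d0, clamp=True)
        rows.append({
            "treatment": t.treatment,
            "n": t.n,
            "mean_um": t.mean,
            "sd_um": t.sd,
            "delta_d_um": max(d0 - t.mean, 0.0),
            "gamma": g,
            "gamma_2dp": round(g, 2),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NCV curve and inversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NcvCurve:
    """Tabulated strictly-decreasing NCV-versus-gamma curve.

    Construction fails if the gammas are not strictly increasing or the
    velocities not strictly decreasing, so inversion is always well posed.
    ``provenance`` records how the table was produced (config digest, dt,
    grid, truncation).
    """

    gammas: np.ndarray
    ncvs: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.gammas, dtype=float)
        v = np.asarray(self.ncvs, dtype=float)
        if g.ndim != 1 or g.shape != v.shape or g.size < 1:
            raise DomainError("gammas and ncvs must be equal-length 1-D")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise DomainError("gammas must be strictly increasing")
        if g.size > 1 and not np.all(np.diff(v) < 0):
            raise DomainError(
                "NCV must be strictly decreasing along the gamma grid")
        object.__setattr__(self, "gammas", g)
        object.__setattr__(self, "ncvs", v)

    def __len__(self) -> int:
        return self.gammas.size

    def ncv_at(self, gamma: float) -> float:
        """Piecewise-linear interpolation of NCV at ``gamma``."""
        if not self.gammas[0] <= gamma <= self.gammas[-1]:
            raise ExtrapolationError(
                f"gamma {gamma} outside tabulated range "
                f"[{self.gammas[0]}, {self.gammas[-1]}]")
        return float(np.interp(gamma, self.gammas, self.ncvs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gamma": self.gammas, "ncv_mps": self.ncvs})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NcvCurve":
        df = pd.read_csv(path, sep="\t")
        missing = {"gamma", "ncv_mps"} - set(df.columns)
        if missing:
            raise DomainError(
                f"curve file {path} missing column(s) {sorted(missing)}")
        return cls(gammas=df["gamma"].to_numpy(),
                   ncvs=df["ncv_mps"].to_numpy(),
                   provenance={"source": str(path)})


def simulate_ncv(config: ModelConfig, gamma: float | None = None,
                 dt: float = 0.005, t_end: float = 6.0,
                 protocol: sim.StimulusProtocol | None = None) -> float:
    """Central-axon conduction velocity (m/s) for one configuration."""
    if gamma is not None:
        config = config.with_state(gamma=gamma)
    model = sim.build_bundle(config)
    result = sim.simulate(model, protocol=protocol, t_end=t_end, dt=dt)
    return float(result.velocities[0])


def ncv_curve(config: ModelConfig,
              gamma_grid: Sequence[float] | None = None,
              dt: float = 0.005, t_end: float = 6.0,
              protocol: sim.StimulusProtocol | None = None) -> NcvCurve:
    """Simulate the NCV-versus-gamma curve over a grid (default [0, 0.6]).

    One bundle simulation per grid point, reporting the central axon's
    velocity.  If propagation fails at some gamma the curve is truncated
    there with a warning (recorded in provenance); construction fails if
    the resulting table is not strictly decreasing.
    """
    grid = DEFAULT_GAMMA_GRID if gamma_grid is None else \
        np.asarray(gamma_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise DomainError("gamma grid must be a non-empty 1-D sequence")
    gammas, ncvs = [], []
    truncated_at = None
    for g in grid:
        try:
            v = simulate_ncv(config, gamma=float(g), dt=dt, t_end=t_end,
                             protocol=protocol)
        except PropagationFailureError:
            truncated_at = float(g)
            warnings.warn(
                f"propagation failed at gamma={g:.3f}; curve truncated",
                stacklevel=2)
            break
        gammas.append(float(g))
        ncvs.append(v)
    provenance = {
        "config_digest": config.digest(),
        "dt_ms": dt,
        "t_end_ms": t_end,
        "grid": [float(g) for g in grid],
        "truncated_at": truncated_at,
    }
    return NcvCurve(gammas=np.asarray(gammas), ncvs=np.asarray(ncvs),
                    provenance=provenance)


def gamma_from_ncv(curve: NcvCurve, v: float) -> float:
    """Invert a measured conduction velocity to a demyelination factor.

    Monotone piecewise-linear inversion of the tabulated curve; exact at
    the knots.  Velocities outside the tabulated range raise
    :class:`ExtrapolationError` naming the valid interval.
    """
    v_min, v_max = float(curve.ncvs[-1]), float(curve.ncvs[0])
    if not v_min <= v <= v_max:
        raise ExtrapolationError(
            f"NCV {v} m/s outside the curve's range "
            f"[{v_min:.4g}, {v_max:.4g}] m/s")
    # np.interp needs ascending x: reverse the decreasing NCV table
    return float(np.interp(v, curve.ncvs[::-1], curve.gammas[::-1]))


# ---------------------------------------------------------------------------
# baseline calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Adjusted configuration plus calibration provenance."""

    config: ModelConfig
    achieved_ncv: float
    target_ncv: float
    tolerance: float
    length_scale: float
    iterations: int


def calibrate_baseline(config: ModelConfig, v_target: float,
                       tolerance: float = 0.5,
                       scale_bounds: tuple[float, float] = (0.05, 10.0),
                       dt: float = 0.005, t_end: float = 6.0,
                       max_iter: int = 60) -> CalibrationResult:
    """Scale the internodal length until baseline NCV matches ``v_target``.

    Bisection on a multiplicative length scale: velocity grows monotonically
    with internodal length (same nodal delay over a longer hop), so a single
    bracketing search suffices and no other surrogate parameter is touched.
    Calibration is run at gamma = 0 (healthy nerve).  Raises
    :class:`CalibrationError` if the target is outside the reachable range.
    """
    if v_target <= 0:
        raise DomainError("target velocity must be > 0")
    if tolerance <= 0:
        raise DomainError("tolerance must be > 0")
    base = config.with_state(gamma=0.0, block_fraction=0.0)
    l0 = base.geometry.internodal_length

    def ncv_at_scale(s: float) -> float:
        import dataclasses as dc
        geo = dc.replace(base.geometry, internodal_length=s * l0)
        return simulate_ncv(base.replace(geometry=geo), dt=dt, t_end=t_end)

    lo, hi = scale_bounds
    try:
        v_lo = ncv_at_scale(lo)
    except PropagationFailureError as exc:
        raise CalibrationError(
            f"propagation fails at the lower length bound "
            f"(scale {lo})") from exc
    v_hi = ncv_at_scale(hi)
    if not v_lo <= v_target <= v_hi:
        raise CalibrationError(
            f"target {v_target} m/s outside reachable range "
            f"[{v_lo:.3g}, {v_hi:.3g}] m/s for length scales {scale_bounds}")

    s_mid, v_mid = lo, v_lo
    iterations = 0
    for iterations in range(1, max_iter + 1):
        s_mid = 0.5 * (lo + hi)
        v_mid = ncv_at_scale(s_mid)
        if abs(v_mid - v_target) <= tolerance:
            break
        if v_mid < v_target:
            lo = s_mid
        else:
            hi = s_mid
    else:
        raise CalibrationError(
            f"bisection did not reach |NCV - {v_target}| <= {tolerance} "
            f"within {max_iter} iterations (last {v_mid:.4g} m/s)")

    import dataclasses as dc
    geo = dc.replace(base.geometry, internodal_length=s_mid * l0)
    calibrated = config.replace(geometry=geo)
    return CalibrationResult(config=calibrated, achieved_ncv=v_mid,
                             target_ncv=v_target, tolerance=tolerance,
                             length_scale=s_mid, iterations=iterations)
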