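"""Domain types and scaling laws of the nerve-bundle circuit model.

The model represents a myelinated peripheral nerve as a bundle of axons, each
a chain of nodes of Ranvier joined by passive internodal resistances.  Each
node carries four threshold-gated ionic branches (Na, fast K, slow K, leak),
a nodal capacitance, and — within a bundle — an ephaptic coupling to
neighbouring axons through the shared extracellular resistance.

Demyelination is captured by a single dimensionless factor ``gamma`` in
``[0, 1)``: the fractional loss of myelin thickness ``(D0 - D)/D0``.  Thinner
myelin makes the membrane leakier and raises its effective capacitance, so
every passive element scales multiplicatively with ``(1 + gamma)``:
conductances as ``g*(1 + gamma)`` (equivalently, ionic resistances
``1/(g*(1 + gamma))``) and the nodal capacitance as ``c*(1 + gamma)**p``
with exponent ``p = 1`` by default.

Channel blockade by neurotoxin is phenomenological: a block fraction
``beta`` in ``[0, 1]`` multiplies the three gated conductances by
``(1 - beta)``, leaving the leak and all voltages untouched.

Units used throughout the package: mV, ms, mS, pF, kOhm, mm.  With these,
``mS * mV = uA`` and ``mV / kOhm = uA``; capacitances are converted to uF
inside the simulator so that ``uA / uF = mV/ms``.  Node positions in mm and
crossing times in ms make ``mm/ms`` numerically equal to m/s.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ConfigError, DomainError

__all__ = [
    "BRANCHES",
    "IonChannelParams",
    "AxonGeometry",
    "BundleLayout",
    "AxonState",
    "GatingPolicy",
    "ModelConfig",
    "scale_conductance",
    "scale_capacitance",
    "node_offset",
    "apply_block",
    "default_config",
]

#: Ionic branch order used by every array in the simulator.
BRANCHES = ("na", "kf", "ks", "leak")


# ---------------------------------------------------------------------------
# scaling laws
# ---------------------------------------------------------------------------

def scale_conductance(g: float, gamma: float) -> float:
    """Demyelinated ionic conductance ``g * (1 + gamma)``.

    Equivalently the ionic resistance becomes ``1/(g*(1 + gamma))``: loss of
    myelin exposes more membrane, so every ionic pathway conducts more.
    """
    if g <= 0:
        raise DomainError(f"conductance must be > 0, got {g}")
    _check_gamma(gamma)
    return g * (1.0 + gamma)


def scale_capacitance(c: float, gamma: float, exponent: float = 1.0) -> float:
    """Effective nodal capacitance ``c * (1 + gamma)**exponent``.

    Thinner myelin brings the conducting media closer together and raises the
    effective capacitance; the default exponent of 1 applies the same uniform
    ``(1 + gamma)`` scaling as the conductances.
    """
    if c <= 0:
        raise DomainError(f"capacitance must be > 0, got {c}")
    _check_gamma(gamma)
    return c * (1.0 + gamma) ** exponent


def node_offset(alignment: float, internodal_length: float) -> float:
    """Longitudinal stagger between nodes of neighbouring axons, in mm.

    ``alignment = 1`` means the nodes of Ranvier of the two axons are exactly
    registered (offset 0); ``alignment = 0.5`` means they are evenly
    staggered (offset of half an internode).  Linear in between:
    ``(1 - alignment) * internodal_length``.
    """
    if not 0.5 <= alignment <= 1.0:
        raise DomainError(f"alignment must be in [0.5, 1], got {alignment}")
    if internodal_length <= 0:
        raise DomainError(
            f"internodal length must be > 0, got {internodal_length}")
    return (1.0 - alignment) * internodal_length


def apply_block(params: "IonChannelParams", beta: float) -> "IonChannelParams":
    """Scale the three gated conductances by ``(1 - beta)``.

    Represents neurotoxin blockade of the voltage-gated Na+/K+ channels; the
    leak conductance and all voltages are unchanged.  ``beta = 0`` is the
    identity, ``beta = 1`` a complete block.
    """
    if not 0.0 <= beta <= 1.0:
        raise DomainError(f"block fraction must be in [0, 1], got {beta}")
    f = 1.0 - beta
    return dataclasses.replace(
        params, g_na=params.g_na * f, g_kf=params.g_kf * f,
        g_ks=params.g_ks * f)


def _check_gamma(gamma: float) -> None:
    if not 0.0 <= gamma < 1.0:
        raise DomainError(
            f"demyelination factor must be in [0, 1), got {gamma}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonChannelParams:
    """Baseline nodal ionic-branch parameters.

    Conductances in mS per node, all potentials in mV.  ``e_*`` are the
    Nernst (reversal) potentials at which each current vanishes; ``vth_*``
    the threshold voltages at which each branch starts to conduct.
    """

    g_na: float
    g_kf: float
    g_ks: float
    g_leak: float
    e_na: float
    e_kf: float
    e_ks: float
    e_leak: float
    vth_na: float
    vth_kf: float
    vth_ks: float
    vth_leak: float

    def __post_init__(self) -> None:
        # zero is allowed so a complete channel block is representable
        for name in ("g_na", "g_kf", "g_ks", "g_leak"):
            if getattr(self, name) < 0:
                raise DomainError(
                    f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.e_na > self.e_kf:
            warnings.warn(
                "unphysiological ordering: expected e_na > e_kf "
                f"(got e_na={self.e_na}, e_kf={self.e_kf})",
                stacklevel=2)

    def conductances(self) -> tuple[float, float, float, float]:
        """(g_na, g_kf, g_ks, g_leak) in branch order."""
        return (self.g_na, self.g_kf, self.g_ks, self.g_leak)

    def nernst(self) -> tuple[float, float, float, float]:
        return (self.e_na, self.e_kf, self.e_ks, self.e_leak)

    def thresholds(self) -> tuple[float, float, float, float]:
        return (self.vth_na, self.vth_kf, self.vth_ks, self.vth_leak)


@dataclass(frozen=True)
class AxonGeometry:
    """Single-axon geometry and passive circuit constants.

    internodal_length in mm, axial_resistance (per internode) in kOhm,
    nodal_capacitance in pF, baseline_myelin_thickness in um.
    """

    internodal_length: float
    n_nodes: int
    axial_resistance: float
    nodal_capacitance: float
    baseline_myelin_thickness: float = 1.79

    def __post_init__(self) -> None:
        if self.internodal_length <= 0:
            raise DomainError("internodal_length must be > 0")
        if self.n_nodes < 3:
            raise DomainError(f"n_nodes must be >= 3, got {self.n_nodes}")
        if self.axial_resistance <= 0:
            raise DomainError("axial_resistance must be > 0")
        if self.nodal_capacitance <= 0:
            raise DomainError("nodal_capacitance must be > 0")
        if self.baseline_myelin_thickness <= 0:
            raise DomainError("baseline_myelin_thickness must be > 0")


@dataclass(frozen=True)
class BundleLayout:
    """Bundle topology and ephaptic-coupling constants.

    One central axon surrounded by ``n_neighbors`` axons of equal geometry,
    their nodes staggered by ``node_offset(alignment, L)``.  The ephaptic
    interaction injects ``alpha * (V_neighbor - V_self) / external_resistance``
    into each coupled node pair.
    """

    n_neighbors: int = 6
    alignment: float = 1.0
    ephaptic_coupling: float = 0.05
    external_resistance: float = 5000.0

    def __post_init__(self) -> None:
        if self.n_neighbors < 0:
            raise DomainError("n_neighbors must be >= 0")
        if not 0.5 <= self.alignment <= 1.0:
            raise DomainError(
                f"alignment must be in [0.5, 1], got {self.alignment}")
        if self.ephaptic_coupling < 0:
            raise DomainError("ephaptic_coupling must be >= 0")
        if self.external_resistance <= 0:
            raise DomainError("external_resistance must be > 0")


@dataclass(frozen=True)
class AxonState:
    """Pathological state of one axon: demyelination and channel block."""

    gamma: float = 0.0
    block_fraction: float = 0.0

    def __post_init__(self) -> None:
        _check_gamma(self.gamma)
        if not 0.0 <= self.block_fraction <= 1.0:
            raise DomainError(
                f"block_fraction must be in [0, 1], "
                f"got {self.block_fraction}")


@dataclass(frozen=True)
class GatingPolicy:
    """Threshold-switch semantics of the gated branches (durations in ms).

    A gated branch opens when the nodal voltage first crosses its threshold
    upward, stays open for its configured duration, then closes and is held
    refractory.  A branch whose threshold lies at or below the resting
    potential is statically open (the leak branch by default).
    """

    open_duration_na: float = 0.3
    open_duration_kf: float = 1.0
    open_duration_ks: float = 2.0
    open_duration_leak: float = math.inf
    refractory: float = 3.0

    def __post_init__(self) -> None:
        for name in ("open_duration_na", "open_duration_kf",
                     "open_duration_ks", "open_duration_leak"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.refractory < 0:
            raise DomainError("refractory must be >= 0")

    def durations(self) -> tuple[float, float, float, float]:
        return (self.open_duration_na, self.open_duration_kf,
                self.open_duration_ks, self.open_duration_leak)


# ---------------------------------------------------------------------------
# configuration container and file I/O
# ---------------------------------------------------------------------------

_SECTIONS: dict[str, type] = {
    "channels": IonChannelParams,
    "geometry": AxonGeometry,
    "layout": BundleLayout,
    "state": AxonState,
    "gating": GatingPolicy,
}
_SCALARS = ("resting_potential", "capacitance_gamma_exponent")


@dataclass(frozen=True)
class ModelConfig:
    """Complete, validated model configuration.

    Mirrors the on-disk YAML/JSON layout: one section per domain type plus
    the scalar keys ``resting_potential`` (mV) and
    ``capacitance_gamma_exponent``.
    """

    channels: IonChannelParams
    geometry: AxonGeometry
    layout: BundleLayout
    state: AxonState = field(default_factory=AxonState)
    gating: GatingPolicy = field(default_factory=GatingPolicy)
    resting_potential: float = -70.0
    capacitance_gamma_exponent: float = 1.0

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelConfig":
        """Build from a nested mapping, rejecting unknown keys by name."""
        unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
        if unknown:
            raise ConfigError(
                f"unknown top-level key(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for section, typ in _SECTIONS.items():
            if section not in data:
                if section in ("channels", "geometry"):
                    raise ConfigError(f"missing required section {section!r}")
                continue
            sub = data[section]
            if not isinstance(sub, Mapping):
                raise ConfigError(f"section {section!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(typ)}
            bad = set(sub) - valid
            if bad:
                raise ConfigError(
                    f"unknown key(s) in section {section!r}: {sorted(bad)}")
            try:
                kwargs[section] = typ(**sub)
            except TypeError as exc:  # missing required field
                raise ConfigError(f"section {section!r}: {exc}") from None
        for key in _SCALARS:
            if key in data:
                kwargs[key] = float(data[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Load a YAML (``.yaml``/``.yml``) or JSON (``.json``) config."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for section in _SECTIONS:
            out[section] = dataclasses.asdict(getattr(self, section))
        for key in _SCALARS:
            out[key] = getattr(self, key)
        return out

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))

    def replace(self, **kwargs: Any) -> "ModelConfig":
        """Return a copy with the given top-level fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def with_state(self, gamma: float | None = None,
                   block_fraction: float | None = None) -> "ModelConfig":
        """Return a copy with a modified pathological state."""
        state = AxonState(
            gamma=self.state.gamma if gamma is None else gamma,
            block_fraction=(self.state.block_fraction
                            if block_fraction is None else block_fraction))
        return dataclasses.replace(self, state=state)

    def digest(self) -> str:
        """Short content hash, used as provenance for derived curves."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_config() -> ModelConfig:
    """The packaged default configuration (surrogate amphibian-node values).

    The defaults are order-of-magnitude realistic for an amphibian node of
    Ranvier and are tuned so the uncalibrated bundle conducts at roughly the
    normal toad sciatic-nerve velocity; quantitative work should calibrate
    the baseline explicitly (see ``quantification.calibrate_baseline``) and
    cite the config digest.
    """
    text = (resources.files(__package__) / "defaults.yaml").read_text()
    return ModelConfig.from_dict(yaml.safe_load(text))
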