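"""Parameter records shared by the model, simulator and estimators.

Units used throughout the package: nm, s, pN, mM.  Thermal energy kT is
carried in pN nm (4.07 pN nm at 22 degC).  Viscosity is in pN s nm^-2
(water at 22 degC is about 9.55e-10 pN s nm^-2).
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from typing import Mapping

import yaml

#: thermal energy k_B * 295.15 K in pN nm (22 degC assay temperature)
KT_DEFAULT = 4.07

#: dynamic viscosity of water at 22 degC, pN s nm^-2
WATER_VISCOSITY = 9.55e-10


class ParameterError(ValueError):
    """Raised when a parameter record violates its invariants."""


@dataclasses.dataclass(frozen=True)
class CycleRates:
    """Zero-load kinetic constants of one motor variant.

    Attributes
    ----------
    k1_0 : float
        ADP-release rate at zero load (s^-1).
    k2_0 : float
        Second-order ATP-binding constant at zero load (mM^-1 s^-1).
    d1, d2 : float
        Load-sensitivity distances (nm) of the two exit rates; a rate
        under load F is ``k0 * exp(-F * d / kT)``.
    k_att : float
        Effective attachment rate from the detached state (s^-1).
    """

    k1_0: float
    k2_0: float
    d1: float = 0.0
    d2: float = 0.0
    k_att: float = 0.5

    def __post_init__(self) -> None:
        if self.k1_0 <= 0 or self.k2_0 <= 0 or self.k_att <= 0:
            raise ParameterError("rates must be positive")
        if self.d1 < 0 or self.d2 < 0:
            raise ParameterError("distance parameters must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class MechanicalParams:
    """Working-stroke geometry, stiffnesses and bead hydrodynamics.

    The working stroke is split into two substeps, ``ws1`` completed on
    entering the ADP state and ``ws2`` on entering the nucleotide-free
    (rigor) state; ``ws1 + ws2`` must equal ``ws_total``.
    """

    ws_total: float = 18.0
    ws1: float = 15.0
    ws2: float = 3.0
    kappa_pre: float = 0.25    # crossbridge stiffness before rigor, pN/nm
    kappa_rigor: float = 0.35  # crossbridge stiffness nucleotide-free, pN/nm
    kappa_trap: float = 0.02   # per-trap stiffness, pN/nm
    kappa_link: float = 1.3    # actin-bead connection stiffness, pN/nm
    bead_radius: float = 500.0  # nm
    viscosity: float = WATER_VISCOSITY
    drag_rod: float | None = None  # pN s/nm; default: same as one bead

    def __post_init__(self) -> None:
        if not math.isclose(self.ws1 + self.ws2, self.ws_total,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ParameterError(
                f"ws1 + ws2 = {self.ws1 + self.ws2} != ws_total = {self.ws_total}")
        for name in ("kappa_pre", "kappa_rigor", "kappa_trap", "kappa_link"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.kappa_link < 1.0:
            raise ParameterError("kappa_link must be >= 1.0 pN/nm")
        if self.bead_radius <= 0 or self.viscosity <= 0:
            raise ParameterError("bead_radius and viscosity must be > 0")

    @property
    def drag_bead(self) -> float:
        """Stokes drag of one bead, 6*pi*eta*r (pN s/nm)."""
        return 6.0 * math.pi * self.viscosity * self.bead_radius

    @property
    def drag_actin(self) -> float:
        """Drag of the actin dumbbell rod coordinate (pN s/nm).

        A few-micron filament has slender-body drag comparable to a
        500-nm bead, which is what the default reproduces.
        """
        return self.drag_bead if self.drag_rod is None else self.drag_rod

    @property
    def kappa_series(self) -> float:
        """Series stiffness of one trap + its actin link, pN/nm."""
        return (self.kappa_trap * self.kappa_link
                / (self.kappa_trap + self.kappa_link))

    def kappa_state(self, state: str) -> float:
        """Crossbridge stiffness for an attached-cycle state label."""
        if state == "detached":
            return 0.0
        if state == "post1_ADP":
            return self.kappa_pre
        if state == "rigor":
            return self.kappa_rigor
        raise ParameterError(f"unknown state {state!r}")

    def stroke_offset(self, state: str) -> float:
        """Motor anchor offset (nm) imposed on the actin rod per state."""
        if state == "detached":
            return 0.0
        if state == "post1_ADP":
            return self.ws1
        if state == "rigor":
            return self.ws1 + self.ws2
        raise ParameterError(f"unknown state {state!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class Conditions:
    """Solution and load conditions for rate evaluation.

    ``load`` is the signed force on the crossbridge in pN, with
    resisting load positive (opposing the working-stroke direction).
    """

    atp: float          # mM
    load: float = 0.0   # pN
    kT: float = KT_DEFAULT

    def __post_init__(self) -> None:
        if self.atp < 0:
            raise ParameterError("atp must be >= 0")
        if self.kT <= 0:
            raise ParameterError("kT must be > 0")

    def with_load(self, load: float) -> "Conditions":
        return dataclasses.replace(self, load=load)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class Variant:
    """One motor variant: kinetics, mechanics and solution anchors."""

    name: str
    rates: CycleRates
    mech: MechanicalParams
    stopped_flow: Mapping[str, float] = dataclasses.field(default_factory=dict)


def _load_registry() -> dict[str, Variant]:
    text = (resources.files("actotrap") / "data" / "variants.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, entry in raw.items():
        out[name] = Variant(
            name=name,
            rates=CycleRates(**entry["rates"]),
            mech=MechanicalParams(**entry["mech"]),
            stopped_flow=dict(entry.get("stopped_flow", {})),
        )
    return out


_REGISTRY: dict[str, Variant] | None = None


def variant(name: str) -> Variant:
    """Look up a shipped variant parameter set (``WT``, ``S267A``, ``S267E``)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ParameterError(
            f"unknown variant {name!r}; known: {sorted(_REGISTRY)}") from None


def variant_names() -> list[str]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return sorted(_REGISTRY)
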