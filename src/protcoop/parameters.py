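"""Model parameters and the state-vector convention.

The model tracks eight nondimensional densities describing a well-mixed
liquid coculture of a protease-producing *Bacillus subtilis* strain (the
wild type) and an isogenic non-producer (the Δ8 mutant lacking all eight
extracellular protease genes):

======  ==========================================================
name    meaning
======  ==========================================================
W       producer (wild-type) vegetative cell density
C       non-producer (Δ8) vegetative cell density
Ws      producer spore density
Cs      non-producer spore density
B       polymeric nutrient (BSA analogue), unusable until degraded
Bd      degraded/intermediate nutrient released from B
A       accessible nutrient (glutamic acid/glycerol analogue)
E       extracellular protease abundance
======  ==========================================================

Any flat array representation of the state uses exactly this ordering;
all serializations use these names.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

#: Fixed ordering of the state components in every flat representation.
STATE_VARS: tuple[str, ...] = ("W", "C", "Ws", "Cs", "B", "Bd", "A", "E")

#: Number of state components.
N_STATE: int = len(STATE_VARS)


@dataclass(frozen=True)
class ModelParameters:
    """The twelve rate/yield/cost constants of the coculture model.

    All values are nondimensional.  Defaults are the values used for all
    headline simulations.

    Attributes
    ----------
    gamma_A:
        Yield coefficient (biomass per nutrient) for the accessible
        nutrient ``A``.  Must exceed ``gamma_Bd``: degraded polymer
        supports growth at a lower yield.
    gamma_Bd:
        Yield coefficient for the degraded nutrient ``Bd``.
    chi:
        Absolute cost of protease production — the growth penalty per
        unit protease produced per unit producer (``chi >= 0``).
    k1:
        Maximum nutrient consumption rate (per unit cell density).
    k2:
        Nutrient-uptake half-saturation constant.
    k3:
        Maximum sporulation rate.
    k4:
        Sporulation half-saturation constant.
    k5:
        Maximum protease production rate per unit producer.
    k6:
        Protease carrying capacity (production is self-limiting and
        stops once ``E`` reaches ``k6``).
    k7:
        Maximum enzymatic conversion rate of ``B`` to ``Bd``.
    k8:
        Michaelis constant of the enzymatic conversion.
    """

    gamma_A: float = 4.0
    gamma_Bd: float = 1.0
    chi: float = 1.0
    k1: float = 3.0
    k2: float = 0.02
    k3: float = 0.4
    k4: float = 0.003
    k5: float = 0.03
    k6: float = 0.2
    k7: float = 0.5
    k8: float = 0.45

    def __post_init__(self) -> None:
        if not self.gamma_A > self.gamma_Bd > 0:
            raise ValueError(
                "yield coefficients must satisfy gamma_A > gamma_Bd > 0; "
                f"got gamma_A={self.gamma_A}, gamma_Bd={self.gamma_Bd}"
            )
        if self.chi < 0:
            raise ValueError(f"chi must be >= 0; got {self.chi}")
        for name in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0; got {value}")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def with_chi(self, chi: float) -> "ModelParameters":
        """Return a copy with a different absolute cost ``chi``."""
        return replace(self, chi=chi)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())
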