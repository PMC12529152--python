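"""Process-intermediate stream state shared by all downstream-unit models."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass
class StreamState:
    """A process intermediate flowing between unit operations.

    Attributes
    ----------
    volume_ml : float
        Stream volume in mL.
    particles_per_ml : float
        Total particle concentration (NTA/MALS scale).
    protein_ug_ml : float
        Total protein concentration in µg/mL.
    dna_ng_ml : float
        dsDNA concentration in ng/mL.
    modifier_mM : float
        Salt (modifier) concentration in mM.
    """

    volume_ml: float
    particles_per_ml: float = 0.0
    protein_ug_ml: float = 0.0
    dna_ng_ml: float = 0.0
    modifier_mM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("volume_ml", "particles_per_ml", "protein_ug_ml",
                     "dna_ng_ml", "modifier_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # masses are the quantities conserved across volume changes
    @property
    def particle_mass(self) -> float:
        """Total particles in the stream."""
        return self.particles_per_ml * self.volume_ml

    @property
    def protein_mass_ug(self) -> float:
        return self.protein_ug_ml * self.volume_ml

    @property
    def dna_mass_ng(self) -> float:
        return self.dna_ng_ml * self.volume_ml

    def with_volume(self, volume_ml: float, conserve_mass: bool = True) -> "StreamState":
        """Return a copy at a new volume, rescaling concentrations if requested."""
        if volume_ml <= 0:
            raise ValueError("volume must be positive")
        if not conserve_mass:
            return replace(self, volume_ml=volume_ml)
        f = self.volume_ml / volume_ml
        return StreamState(
            volume_ml=volume_ml,
            particles_per_ml=self.particles_per_ml * f,
            protein_ug_ml=self.protein_ug_ml * f,
            dna_ng_ml=self.dna_ng_ml * f,
            modifier_mM=self.modifier_mM,
        )
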