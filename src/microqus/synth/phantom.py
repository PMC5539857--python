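"""Layered-tissue phantom descriptions.

A phantom is an ordered stack of plane-parallel tissue layers resting on a
substrate (agar over absorber in the bench setup being emulated), imaged
through a lossless coupling medium (degassed PBS). Each layer carries the
acoustic ground truth used to validate every downstream estimator: impedance,
one-way attenuation, backscatter energy scale and scatterer density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class TissueLayerSpec:
    """One homogeneous tissue layer.

    Attributes
    ----------
    name : str
        Anatomical label (mucosa, submucosa, muscularis, ...).
    thickness : float
        mm, > 0.
    impedance : float
        Characteristic acoustic impedance, MRayl.
    attenuation : float
        One-way amplitude attenuation coefficient alpha, dB/mm.
    backscatter_strength : float
        Variance scale of single-scatterer echo amplitude (dimensionless
        energy units relative to the incident amplitude squared).
    scatterer_density : float
        Point scatterers per mm^2 of the imaging plane.
    sound_speed : float
        m/s.
    """

    name: str
    thickness: float
    impedance: float
    attenuation: float = 0.0
    backscatter_strength: float = 0.0
    scatterer_density: float = 0.0
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if self.impedance <= 0:
            raise ValueError(f"layer {self.name!r}: impedance must be > 0")
        if self.attenuation < 0:
            raise ValueError(f"layer {self.name!r}: attenuation must be >= 0")
        if self.backscatter_strength < 0 or self.scatterer_density < 0:
            raise ValueError(f"layer {self.name!r}: backscatter fields must be >= 0")
        if self.sound_speed <= 0:
            raise ValueError(f"layer {self.name!r}: sound_speed must be > 0")


@dataclass(frozen=True)
class LayeredPhantom:
    """An ordered layer stack, superficial layer first.

    Attributes
    ----------
    layers : tuple of TissueLayerSpec
    coupling_impedance : float
        Z_w of the imaging medium, MRayl.
    coupling_sound_speed : float
        m/s.
    standoff : float
        Coupling path between transducer face and the first layer, mm.
    substrate_impedance : float
        Impedance of the backing below the last layer (agar), MRayl.
    """

    layers: tuple
    coupling_impedance: float = 1.48
    coupling_sound_speed: float = 1480.0
    standoff: float = 1.0
    substrate_impedance: float = 1.54

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 1:
            raise ValueError("phantom needs at least one layer")
        if self.standoff < 0:
            raise ValueError("standoff must be >= 0")
        if self.coupling_impedance <= 0 or self.substrate_impedance <= 0:
            raise ValueError("impedances must be > 0")
        for r in self.interface_reflection_coefficients():
            if not -1.0 < r < 1.0:
                raise ValueError("interface reflection coefficients must lie in (-1, 1)")

    @property
    def total_thickness(self) -> float:
        """Stack thickness, mm."""
        return sum(layer.thickness for layer in self.layers)

    def impedance_profile(self) -> list:
        """Impedances from coupling medium through layers to substrate."""
        return (
            [self.coupling_impedance]
            + [layer.impedance for layer in self.layers]
            + [self.substrate_impedance]
        )

    def interface_reflection_coefficients(self) -> list:
        """Pressure reflection coefficients at each of the len(layers)+1 interfaces."""
        z = self.impedance_profile()
        return [(z[i + 1] - z[i]) / (z[i + 1] + z[i]) for i in range(len(z) - 1)]

    def interface_depths(self) -> list:
        """Depths (mm, from the transducer face) of each interface."""
        depths = [self.standoff]
        for layer in self.layers:
            depths.append(depths[-1] + layer.thickness)
        return depths

    def to_dict(self) -> dict:
        """JSON-serializable ground-truth record."""
        d = asdict(self)
        d["layers"] = [asdict(layer) for layer in self.layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LayeredPhantom":
        layers = tuple(TissueLayerSpec(**ld) for ld in d["layers"])
        rest = {k: v for k, v in d.items() if k != "layers"}
        return cls(layers=layers, **rest)


def default_phantom() -> LayeredPhantom:
    """Two-layer esophageal-wall phantom used as the stock simulation target.

    A bright mucosa/submucosa band (the region the segmentation isolates)
    over a quieter muscularis, on an agar substrate under dPBS coupling.
    The band's attenuation is set to the ex vivo mucosa/submucosa average
    of 1.86 dB/mm that the estimators are expected to recover.
    """
    return LayeredPhantom(
        layers=(
            TissueLayerSpec(
                name="mucosa_submucosa",
                thickness=2.0,
                impedance=1.60,
                attenuation=1.86,
                backscatter_strength=1.6e-4,
                scatterer_density=200.0,
                sound_speed=1540.0,
            ),
            TissueLayerSpec(
                name="muscularis",
                thickness=1.5,
                impedance=1.63,
                attenuation=1.0,
                backscatter_strength=1.6e-7,
                scatterer_density=200.0,
                sound_speed=1540.0,
            ),
        ),
        coupling_impedance=1.48,
        coupling_sound_speed=1480.0,
        standoff=1.0,
        substrate_impedance=1.54,
    )
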