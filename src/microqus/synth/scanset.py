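"""One bundled in silico experiment: sample scan + calibration echoes.

A ScanSet holds everything a single bench acquisition would produce — the
B-scan of the layered sample, the quartz-flat reference with and without an
overlying tissue slab (for the substitution attenuation measurement), the
bare quartz scan used to calibrate the incident amplitude — together with
the generating phantom as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .bscan import BScan, ReferenceEcho, simulate_bscan, simulate_reference_pair
from .phantom import LayeredPhantom, default_phantom
from .pulse import AcousticPulse, make_pulse


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry and pulse settings for one simulated experiment."""

    phantom: LayeredPhantom = field(default_factory=default_phantom)
    center_frequency: float = 48e6
    fractional_bandwidth: float = 0.5
    sampling_rate: float = 400e6
    n_lines: int = 61
    line_pitch: float = 0.5
    noise_sd: float = 0.0
    incident_amplitude: float = 1.0
    include_transmission: bool = True
    quartz_impedance: float = 13.1
    attenuation_slab_index: int = 0  # which layer is measured as the separated slab
    sound_speed_assumed: float = 1540.0
    tail_mm: float = 1.0

    def make_pulse(self) -> AcousticPulse:
        return make_pulse(
            self.center_frequency,
            self.fractional_bandwidth,
            self.sampling_rate,
            amplitude=self.incident_amplitude,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"] = self.phantom.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        d = dict(d)
        d["phantom"] = LayeredPhantom.from_dict(d["phantom"])
        return cls(**d)


@dataclass(frozen=True)
class ScanSet:
    """A complete simulated experiment with exported ground truth."""

    sample_scan: BScan
    reference_no_tissue: ReferenceEcho
    reference_with_tissue: ReferenceEcho
    quartz_scan_for_incident: ReferenceEcho
    ground_truth: LayeredPhantom
    config: ScanConfig
    seed: int

    def __post_init__(self) -> None:
        rates = {
            self.sample_scan.sampling_rate,
            self.reference_no_tissue.sampling_rate,
            self.reference_with_tissue.sampling_rate,
            self.quartz_scan_for_incident.sampling_rate,
        }
        if len(rates) != 1:
            raise ValueError("all ScanSet members must share one sampling rate")


def generate_scan_set(config: ScanConfig | None = None, seed: int = 0) -> ScanSet:
    """Run one complete simulated acquisition.

    The sample B-scan, the substitution reference pair for the configured
    slab layer, and the bare-quartz calibration scan are all generated from
    one seed; the ground-truth phantom suffices to predict every downstream
    estimate.
    """
    if config is None:
        config = ScanConfig()
    pulse = config.make_pulse()
    phantom = config.phantom

    scan = simulate_bscan(
        phantom,
        pulse,
        n_lines=config.n_lines,
        line_pitch=config.line_pitch,
        noise_sd=config.noise_sd,
        seed=seed,
        incident_amplitude=config.incident_amplitude,
        include_transmission=config.include_transmission,
        tail_mm=config.tail_mm,
        sound_speed_assumed=config.sound_speed_assumed,
    )

    slab = phantom.layers[config.attenuation_slab_index]
    under, bare = simulate_reference_pair(
        slab,
        config.quartz_impedance,
        pulse,
        seed=seed + 1,
        coupling_impedance=phantom.coupling_impedance,
        coupling_sound_speed=phantom.coupling_sound_speed,
        standoff=phantom.standoff,
        incident_amplitude=config.incident_amplitude,
        include_transmission=config.include_transmission,
        noise_sd=config.noise_sd,
    )

    return ScanSet(
        sample_scan=scan,
        reference_no_tissue=bare,
        reference_with_tissue=under,
        quartz_scan_for_incident=bare,
        ground_truth=phantom,
        config=config,
        seed=seed,
    )
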