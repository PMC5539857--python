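"""Pulse-echo RF simulation of layered phantoms.

Each A-line is an impulse train convolved with the transmit pulse:

* specular echoes at every impedance interface, with round-trip delay
  ``2 * sum(path_i / c_i)``, amplitude = incident x reflection coefficient
  x two-way transmission products of the shallower interfaces
  x ``10**(-2 * alpha_i * d_i / 20)`` per traversed layer;
* diffuse speckle from Poisson-count point scatterers with zero-mean
  Gaussian amplitudes of variance ``backscatter_strength``, subject to the
  same transmission/attenuation law down to the scatterer depth;
* optional additive white Gaussian noise on the RF.

This is a ray (straight-path) model: no diffraction, focusing, multiple
scattering or nonlinearity. It is sufficient to make every downstream
estimator testable against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, hilbert

from .phantom import LayeredPhantom, TissueLayerSpec
from .pulse import AcousticPulse


@dataclass(frozen=True)
class BScan:
    """A rectangular grid of RF A-lines.

    Attributes
    ----------
    rf : numpy.ndarray
        Shape (n_lines, n_samples), linear amplitude.
    sampling_rate : float
        Hz.
    line_pitch : float
        Lateral spacing between A-lines, mm.
    sound_speed_assumed : float
        m/s, used for all depth conversions downstream.
    depth_origin : float
        Depth (mm) of sample 0; 0 at the transducer face.
    """

    rf: np.ndarray = field(repr=False)
    sampling_rate: float
    line_pitch: float
    sound_speed_assumed: float = 1540.0
    depth_origin: float = 0.0

    def __post_init__(self) -> None:
        rf = np.asarray(self.rf, dtype=float)
        if rf.ndim != 2 or rf.shape[0] < 1 or rf.shape[1] < 1:
            raise ValueError("rf must be a 2-D (n_lines, n_samples) array")
        if not np.all(np.isfinite(rf)):
            raise ValueError("rf must be finite")
        object.__setattr__(self, "rf", rf)

    @property
    def n_lines(self) -> int:
        return self.rf.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rf.shape[1]

    @property
    def scan_length(self) -> float:
        """Lateral extent, mm."""
        return (self.n_lines - 1) * self.line_pitch

    def sample_depths_mm(self) -> np.ndarray:
        """Depth (mm) of every sample along an A-line."""
        dz = self.sound_speed_assumed / (2.0 * self.sampling_rate) * 1e3
        return self.depth_origin + np.arange(self.n_samples) * dz


@dataclass(frozen=True)
class ReferenceEcho:
    """A single calibration A-line from a flat reflector of known impedance.

    Roles: the bare-reflector echo gives the incident amplitude (V_q / V_a);
    the same reflector under a tissue slab gives the through-tissue amplitude
    (V_r) for the substitution attenuation measurement.
    """

    waveform: np.ndarray = field(repr=False)
    sampling_rate: float
    reflector_impedance: float
    reflection_coefficient: float
    with_tissue: bool = False
    tissue_thickness: float = 0.0
    echo_time: float = 0.0  # expected arrival time (s) of the reflector echo

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        if w.ndim != 1:
            raise ValueError("waveform must be 1-D")
        object.__setattr__(self, "waveform", w)
        if abs(self.reflection_coefficient) > 1:
            raise ValueError("|reflection_coefficient| must be <= 1")
        if self.with_tissue and self.tissue_thickness <= 0:
            raise ValueError("tissue_thickness must be > 0 when with_tissue")
        if not self.with_tissue and self.tissue_thickness != 0:
            raise ValueError("tissue_thickness must be 0 without tissue")

    def envelope(self) -> np.ndarray:
        return np.abs(hilbert(self.waveform))

    def peak_amplitude(self, window_s: float | None = None) -> float:
        """Envelope peak, optionally restricted to echo_time +/- window_s."""
        env = self.envelope()
        if window_s is None:
            return float(env.max())
        n0 = int(round((self.echo_time - window_s) * self.sampling_rate))
        n1 = int(round((self.echo_time + window_s) * self.sampling_rate))
        n0, n1 = max(n0, 0), min(n1, env.size)
        if n1 <= n0:
            raise ValueError("measurement window lies outside the recording")
        return float(env[n0:n1].max())

    def energy(self) -> float:
        """Integral of |waveform|^2 dt over the full record (V^2 s)."""
        return float(np.sum(self.waveform**2) / self.sampling_rate)


def _two_way_transmission(r: float) -> float:
    # Down- and up-going pressure transmission product through one interface.
    return 1.0 - r * r


def _layer_events(
    phantom: LayeredPhantom,
    include_transmission: bool,
) -> list:
    """Per-interface (time s, amplitude factor) of specular echoes, plus the
    per-layer context needed to place scatterers: cumulative delay, cumulative
    amplitude (transmission x attenuation) at layer entry."""
    refl = phantom.interface_reflection_coefficients()
    events = []
    t_cum = 2.0 * (phantom.standoff * 1e-3) / phantom.coupling_sound_speed
    amp_cum = 1.0  # cumulative two-way transmission x attenuation factor
    layer_ctx = []
    for i, r in enumerate(refl):
        events.append((t_cum, amp_cum * r))
        if i < len(phantom.layers):
            layer = phantom.layers[i]
            if include_transmission:
                amp_cum *= _two_way_transmission(r)
            layer_ctx.append((layer, t_cum, amp_cum))
            t_cum += 2.0 * (layer.thickness * 1e-3) / layer.sound_speed
            amp_cum *= 10.0 ** (-2.0 * layer.attenuation * layer.thickness / 20.0)
    return events, layer_ctx


def simulate_bscan(
    phantom: LayeredPhantom,
    pulse: AcousticPulse,
    n_lines: int = 61,
    line_pitch: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    incident_amplitude: float = 1.0,
    include_transmission: bool = True,
    tail_mm: float = 1.0,
    sound_speed_assumed: float = 1540.0,
) -> BScan:
    """Simulate a B-scan of a layered phantom.

    Parameters
    ----------
    phantom, pulse
        Scene and transmit waveform.
    n_lines, line_pitch
        Lateral geometry; 61 lines at 0.5 mm pitch span a 30 mm scan.
    noise_sd : float
        Additive white Gaussian RF noise, linear units.
    seed : int
        Seeds scatterer placement, amplitudes and noise; identical
        (inputs, seed) gives bit-identical output.
    incident_amplitude : float
        Amplitude of the incident wave at every interface depth (the ray
        model carries no diffraction, so this is a single scale).
    include_transmission : bool
        Include two-way interface transmission losses in echo amplitudes.
        Turned off for exact-recovery tests, since the substitution
        attenuation relation ignores them.
    tail_mm : float
        Extra quiet depth recorded below the substrate interface.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if line_pitch <= 0:
        raise ValueError("line_pitch must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    fs = pulse.sampling_rate
    events, layer_ctx = _layer_events(phantom, include_transmission)
    t_bottom = events[-1][0]
    t_end = t_bottom + 2.0 * (tail_mm * 1e-3) / sound_speed_assumed
    n_samples = int(np.ceil(t_end * fs)) + 2 * pulse.half_length + 1

    rng = np.random.default_rng(seed)
    impulses = np.zeros((n_lines, n_samples))

    # Specular interface echoes, identical on every line.
    for t_ev, a_ev in events:
        idx = int(round(t_ev * fs))
        if 0 <= idx < n_samples and a_ev != 0.0:
            impulses[:, idx] += incident_amplitude * a_ev

    # Diffuse scatterers, drawn per line then per layer in fixed order.
    for j in range(n_lines):
        for layer, t_entry, amp_entry in layer_ctx:
            mean_count = layer.scatterer_density * layer.thickness * line_pitch
            n_scat = rng.poisson(mean_count) if mean_count > 0 else 0
            if n_scat == 0:
                continue
            z_local = rng.uniform(0.0, layer.thickness, n_scat)  # mm into layer
            amps = rng.normal(0.0, np.sqrt(layer.backscatter_strength), n_scat)
            t_scat = t_entry + 2.0 * (z_local * 1e-3) / layer.sound_speed
            att = 10.0 ** (-2.0 * layer.attenuation * z_local / 20.0)
            idx = np.round(t_scat * fs).astype(int)
            ok = (idx >= 0) & (idx < n_samples)
            np.add.at(
                impulses[j],
                idx[ok],
                incident_amplitude * amp_entry * amps[ok] * att[ok],
            )

    rf = fftconvolve(impulses, pulse.samples[None, :] / pulse.amplitude, mode="same")
    rf *= pulse.amplitude
    if noise_sd > 0:
        rf = rf + rng.normal(0.0, noise_sd, rf.shape)

    return BScan(
        rf=rf,
        sampling_rate=fs,
        line_pitch=line_pitch,
        sound_speed_assumed=sound_speed_assumed,
        depth_origin=0.0,
    )


def simulate_reference_pair(
    phantom_slab: TissueLayerSpec,
    quartz_impedance: float,
    pulse: AcousticPulse,
    seed: int = 0,
    coupling_impedance: float = 1.48,
    coupling_sound_speed: float = 1480.0,
    standoff: float = 1.0,
    incident_amplitude: float = 1.0,
    include_transmission: bool = True,
    noise_sd: float = 0.0,
    tail_mm: float = 0.5,
) -> tuple:
    """Simulate the substitution-method calibration pair on a quartz flat.

    Returns ``(with_tissue, without_tissue)`` reference echoes. The bare
    echo has amplitude ``V_a = A0 * R_q``; under a slab of one-way
    attenuation alpha (dB/mm) and thickness d (mm) the reflector echo is
    ``V_r = V_a * T^2 * 10**(-2 alpha d / 20)`` with the slab's two-way
    surface transmission T^2 included only when ``include_transmission``.
    The slab's own surface echo is present in the with-tissue record; use
    ``peak_amplitude`` with a window about ``echo_time`` to read the
    reflector echo.
    """
    if phantom_slab.thickness <= 0:
        raise ValueError("slab thickness must be > 0")
    fs = pulse.sampling_rate
    r_q = (quartz_impedance - coupling_impedance) / (quartz_impedance + coupling_impedance)
    rng = np.random.default_rng(seed)

    t_surface = 2.0 * (standoff * 1e-3) / coupling_sound_speed
    t_quartz_bare = t_surface
    d = phantom_slab.thickness
    t_quartz_tissue = t_surface + 2.0 * (d * 1e-3) / phantom_slab.sound_speed
    t_end = max(t_quartz_bare, t_quartz_tissue) + 2.0 * (tail_mm * 1e-3) / 1540.0
    n_samples = int(np.ceil(t_end * fs)) + 2 * pulse.half_length + 1

    def _build(event_list) -> np.ndarray:
        imp = np.zeros(n_samples)
        for t_ev, a_ev in event_list:
            imp[int(round(t_ev * fs))] += a_ev
        w = fftconvolve(imp, pulse.samples / pulse.amplitude, mode="same") * pulse.amplitude
        if noise_sd > 0:
            w = w + rng.normal(0.0, noise_sd, n_samples)
        return w

    # Bare reflector.
    v_a = incident_amplitude * r_q
    bare = _build([(t_quartz_bare, v_a)])

    # Reflector beneath the slab: surface echo + attenuated reflector echo.
    r_surf = (phantom_slab.impedance - coupling_impedance) / (
        phantom_slab.impedance + coupling_impedance
    )
    trans = _two_way_transmission(r_surf) if include_transmission else 1.0
    attn = 10.0 ** (-2.0 * phantom_slab.attenuation * d / 20.0)
    v_r = v_a * trans * attn
    with_tissue = _build([(t_surface, incident_amplitude * r_surf), (t_quartz_tissue, v_r)])

    without = ReferenceEcho(
        waveform=bare,
        sampling_rate=fs,
        reflector_impedance=quartz_impedance,
        reflection_coefficient=r_q,
        with_tissue=False,
        echo_time=t_quartz_bare,
    )
    under = ReferenceEcho(
        waveform=with_tissue,
        sampling_rate=fs,
        reflector_impedance=quartz_impedance,
        reflection_coefficient=r_q,
        with_tissue=True,
        tissue_thickness=d,
        echo_time=t_quartz_tissue,
    )
    return under, without
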