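"""Quantitative ultrasound estimators: impedance, attenuation, backscatter.

Three tissue parameters are estimated per A-line from calibrated pulse-echo
data and then aggregated across the scan (mean and standard deviation):

* acoustic impedance ``Z_t = Z_w (V_i + V_r) / (V_i - V_r)`` from the
  surface-echo amplitude ``V_r`` and the incident amplitude ``V_i``
  calibrated off a quartz flat;
* attenuation ``alpha = -20 / (2 d) * log10(V_r / V_a)`` (dB/mm) from the
  substitution pair (reference reflector with / without an overlying slab
  of thickness d), converted to nepers as ``a' = alpha / 8.686``;
* backscatter coefficient
  ``mu_B = [R_q^2 / (2 pi (1 - cos theta_T))]
          * [int_{t1}^{t2} |V_s|^2 dt / int |V_q|^2 dt]
          * [4 a' / (exp(-4 a' d1) - exp(-4 a' d2))]``,
  the product of a transducer geometry factor, a gated energy ratio against
  the quartz reference, and an attenuation compensation whose a' -> 0 limit
  is ``1 / (d2 - d1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .segmentation import SegmentedScan, sub_segment_by_thickness
from .synth.bscan import ReferenceEcho

#: dB per neper (20 / ln 10), printed to the conventional 4 digits.
DB_PER_NEPER = 8.686

#: Half-angle subtended by a 5 mm aperture focused bowl of 15 mm radius
#: of curvature at its focus: arcsin(2.5 / 15).
DEFAULT_HALF_ANGLE = float(np.arcsin(2.5 / 15.0))


@dataclass(frozen=True)
class CalibrationSet:
    """Constants and reference echo required by the estimators.

    Attributes
    ----------
    coupling_impedance : float
        Z_w of the imaging medium, MRayl (1.48 for water/dPBS).
    quartz_impedance : float
        MRayl (13.1 for fused quartz).
    incident_amplitude : float
        V_i, linear units, from ``calibrate_incident``.
    reference_echo : ReferenceEcho
        Bare quartz-flat record; houses V_q and R_q.
    transducer_half_angle : float
        theta_T, rad.
    """

    coupling_impedance: float
    quartz_impedance: float
    incident_amplitude: float
    reference_echo: ReferenceEcho
    transducer_half_angle: float = DEFAULT_HALF_ANGLE

    def __post_init__(self) -> None:
        if self.coupling_impedance <= 0:
            raise ValueError("coupling_impedance must be > 0")
        if not 0 < self.transducer_half_angle < np.pi / 2:
            raise ValueError("transducer_half_angle must lie in (0, pi/2)")
        if self.incident_amplitude <= 0:
            raise ValueError("incident_amplitude must be > 0")


@dataclass(frozen=True)
class GatedSignal:
    """One A-line restricted to its ROI time gate [t1, t2]."""

    samples: np.ndarray = field(repr=False)
    sampling_rate: float
    t1: float
    t2: float
    line_index: int = 0

    def __post_init__(self) -> None:
        if self.t1 >= self.t2:
            raise ValueError("gate requires t1 < t2")

    def energy(self) -> float:
        """Integral of |samples|^2 dt over the gate (discrete sum x dt)."""
        return float(np.sum(np.asarray(self.samples) ** 2) / self.sampling_rate)


def _aggregate(values: np.ndarray, population: bool = True) -> tuple:
    values = np.asarray(values, dtype=float)
    ddof = 0 if population else 1
    std = float(values.std(ddof=ddof)) if values.size > ddof else 0.0
    return float(values.mean()), std


@dataclass(frozen=True)
class ImpedanceEstimate:
    per_line: np.ndarray = field(repr=False)
    mean: float = 0.0
    std: float = 0.0
    segmentation_thickness: float | None = None

    @classmethod
    def from_per_line(cls, values, segmentation_thickness=None, population=True):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("no per-line impedance values")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("per-line impedances must be positive and finite")
        mean, std = _aggregate(values, population)
        return cls(per_line=values, mean=mean, std=std,
                   segmentation_thickness=segmentation_thickness)


@dataclass(frozen=True)
class AttenuationEstimate:
    """Attenuation on both scales; the neper value is derived, never stored
    independently, so ``alpha_neper_per_mm == alpha_db_per_mm / 8.686``
    holds to machine precision."""

    alpha_db_per_mm: float
    per_line: np.ndarray = field(default=None, repr=False)
    mean: float = None
    std: float = None

    def __post_init__(self) -> None:
        if self.mean is None:
            object.__setattr__(self, "mean", float(self.alpha_db_per_mm))
        if self.std is None:
            object.__setattr__(self, "std", 0.0)
        if self.per_line is None:
            object.__setattr__(self, "per_line", np.array([self.alpha_db_per_mm]))

    @property
    def alpha_neper_per_mm(self) -> float:
        return self.alpha_db_per_mm / DB_PER_NEPER

    @classmethod
    def from_per_line(cls, values, population=True):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("no per-line attenuation values")
        mean, std = _aggregate(values, population)
        return cls(alpha_db_per_mm=mean, per_line=values, mean=mean, std=std)


@dataclass(frozen=True)
class BSCEstimate:
    per_line: np.ndarray = field(repr=False)
    mean: float
    std: float
    d1: float
    d2: float
    attenuation_used: float  # Np/mm


def signed_envelope_peak(
    waveform: np.ndarray,
    sampling_rate: float,
    center_time: float | None = None,
    window_s: float | None = None,
) -> float:
    """Envelope peak with the sign of the underlying RF at the peak sample.

    The analytic-signal magnitude is positive by construction; the polarity
    of the echo (soft vs hard reflector) is recovered from the RF sample at
    the envelope maximum.
    """
    w = np.asarray(waveform, dtype=float)
    env = np.abs(hilbert(w))
    if center_time is not None and window_s is not None:
        n0 = max(int(round((center_time - window_s) * sampling_rate)), 0)
        n1 = min(int(round((center_time + window_s) * sampling_rate)), w.size)
        if n1 <= n0:
            raise ValueError("measurement window lies outside the recording")
    else:
        n0, n1 = 0, w.size
    k = n0 + int(np.argmax(env[n0:n1]))
    sign = 1.0 if w[k] >= 0 else -1.0
    return sign * float(env[k])


def calibrate_incident(
    quartz_echo: ReferenceEcho,
    coupling_impedance: float,
    quartz_impedance: float | None = None,
    window_s: float | None = None,
) -> float:
    """Incident amplitude V_i from a bare quartz-flat echo.

    Inverts the impedance relation with Z_t set to the known quartz
    impedance: ``V_i = V_r,quartz * (Z_q + Z_w) / (Z_q - Z_w)``.
    """
    z_q = quartz_impedance if quartz_impedance is not None else quartz_echo.reflector_impedance
    z_w = coupling_impedance
    if z_q == z_w:
        raise ValueError("quartz impedance equals coupling impedance: no echo, "
                         "calibration impossible")
    center = quartz_echo.echo_time if window_s is not None else None
    v_r = signed_envelope_peak(
        quartz_echo.waveform, quartz_echo.sampling_rate, center, window_s
    )
    return v_r * (z_q + z_w) / (z_q - z_w)


def estimate_impedance(v_i: float, v_r: float, coupling_impedance: float) -> float:
    """Tissue impedance from incident and surface-reflected amplitudes."""
    if v_r == v_i:
        raise ValueError("V_r equals V_i: rigid-boundary singularity")
    if abs(v_r) > abs(v_i):
        raise ValueError("|V_r| exceeds |V_i|: unphysical reflection")
    return coupling_impedance * (v_i + v_r) / (v_i - v_r)


def estimate_impedance_scan(
    segmented: SegmentedScan,
    cal: CalibrationSet,
    surface_gate_mm: float = 0.2,
    population_std: bool = True,
    segmentation_thickness: float | None = None,
) -> ImpedanceEstimate:
    """Per-line impedance from the ROI top-surface echo, aggregated.

    V_r on each line is the signed envelope peak within the first
    ``surface_gate_mm`` of that line's ROI. Lines without ROI are skipped.
    """
    roi = segmented.mask
    scan = segmented.source
    dz = roi.sound_speed_assumed / (2.0 * roi.sampling_rate) * 1e3
    gate = max(int(round(surface_gate_mm / dz)), 1)

    env = np.abs(hilbert(segmented.rf_masked, axis=1))
    values = []
    for j in range(roi.mask.shape[0]):
        cols = np.nonzero(roi.mask[j])[0]
        if cols.size == 0:
            continue
        top = cols.min()
        sl = slice(top, min(top + gate, segmented.rf_masked.shape[1]))
        k = sl.start + int(np.argmax(env[j, sl]))
        v_r = (1.0 if segmented.rf_masked[j, k] >= 0 else -1.0) * env[j, k]
        values.append(estimate_impedance(cal.incident_amplitude, v_r, cal.coupling_impedance))
    if not values:
        raise ValueError("mask is empty on all lines")
    return ImpedanceEstimate.from_per_line(
        values, segmentation_thickness=segmentation_thickness, population=population_std
    )


def estimate_attenuation(v_r: float, v_a: float, d: float) -> float:
    """Substitution attenuation, dB/mm: ``-20/(2d) * log10(V_r / V_a)``.

    ``v_r`` is the reference-reflector amplitude beneath the tissue slab,
    ``v_a`` without tissue, ``d`` the slab thickness in mm (the factor 2d
    is the round trip). Positive when the slab attenuates.
    """
    if v_r <= 0 or v_a <= 0:
        raise ValueError("amplitudes must be positive")
    if d <= 0:
        raise ValueError("thickness must be positive")
    return -20.0 / (2.0 * d) * np.log10(v_r / v_a)


def estimate_attenuation_pair(
    under: ReferenceEcho,
    bare: ReferenceEcho,
    window_s: float | None = None,
) -> AttenuationEstimate:
    """Attenuation from a simulated/recorded substitution pair.

    Amplitudes are envelope peaks, windowed about each record's expected
    reflector echo time when ``window_s`` is given.
    """
    if not under.with_tissue or bare.with_tissue:
        raise ValueError("expected (with-tissue, without-tissue) reference pair")
    v_r = under.peak_amplitude(window_s)
    v_a = bare.peak_amplitude(window_s)
    alpha = estimate_attenuation(v_r, v_a, under.tissue_thickness)
    return AttenuationEstimate(alpha_db_per_mm=float(alpha))


def db_to_neper(alpha_db_per_mm: float) -> float:
    """Convert dB/mm to Np/mm (divide by 8.686)."""
    return alpha_db_per_mm / DB_PER_NEPER


def attenuation_compensation(a_prime: float, d1: float, d2: float) -> float:
    """Gate attenuation-compensation factor ``4a' / (e^{-4a'd1} - e^{-4a'd2})``.

    Evaluated through ``expm1`` for numerical continuity; the a' -> 0 limit
    is ``1 / (d2 - d1)``.
    """
    if d1 >= d2:
        raise ValueError("requires d1 < d2")
    if a_prime < 0:
        raise ValueError("a_prime must be >= 0")
    if a_prime == 0:
        return 1.0 / (d2 - d1)
    # 4a' / (e^{-4a'd1} - e^{-4a'd2}) = 4a' e^{4a'd1} / -expm1(-4a'(d2-d1))
    x = 4.0 * a_prime
    return x * np.exp(x * d1) / (-np.expm1(-x * (d2 - d1)))


def estimate_bsc_line(
    gated: GatedSignal,
    cal: CalibrationSet,
    a_prime: float,
    d1: float,
    d2: float,
) -> float:
    """Backscatter coefficient for one gated A-line."""
    ref_energy = cal.reference_echo.energy()
    if ref_energy <= 0:
        raise ValueError("reference energy must be > 0")
    geometry = cal.reference_echo.reflection_coefficient**2 / (
        2.0 * np.pi * (1.0 - np.cos(cal.transducer_half_angle))
    )
    return geometry * (gated.energy() / ref_energy) * attenuation_compensation(
        a_prime, d1, d2
    )


def estimate_bsc_scan(
    segmented: SegmentedScan,
    cal: CalibrationSet,
    attenuation: AttenuationEstimate,
    population_std: bool = True,
) -> BSCEstimate:
    """Per-line backscatter coefficients over the ROI gates, aggregated.

    Gates [t1, t2] come from each line's ROI extent; d1/d2 are the
    whole-mask depth extremes. Lines without ROI are skipped.
    """
    roi = segmented.mask
    fs = roi.sampling_rate
    a_prime = attenuation.alpha_neper_per_mm
    d1, d2 = roi.d1, roi.d2
    values = []
    for j in range(roi.mask.shape[0]):
        cols = np.nonzero(roi.mask[j])[0]
        if cols.size == 0:
            continue
        gated = GatedSignal(
            samples=segmented.rf_masked[j, cols.min() : cols.max() + 1],
            sampling_rate=fs,
            t1=cols.min() / fs,
            t2=(cols.max() + 1) / fs,
            line_index=j,
        )
        values.append(estimate_bsc_line(gated, cal, a_prime, d1, d2))
    if not values:
        raise ValueError("mask is empty on all lines")
    values = np.asarray(values)
    mean, std = _aggregate(values, population_std)
    return BSCEstimate(
        per_line=values, mean=mean, std=std, d1=d1, d2=d2, attenuation_used=a_prime
    )


def impedance_vs_thickness(
    segmented: SegmentedScan,
    cal: CalibrationSet,
    thicknesses,
    **kwargs,
) -> list:
    """Impedance estimates for a sweep of segmentation thicknesses (mm)."""
    thicknesses = list(thicknesses)
    if any(t <= 0 for t in thicknesses):
        raise ValueError("thicknesses must be positive")
    if thicknesses != sorted(thicknesses):
        raise ValueError("thicknesses must be ascending")
    out = []
    for t in thicknesses:
        sub = sub_segment_by_thickness(segmented, t)
        out.append(
            estimate_impedance_scan(sub, cal, segmentation_thickness=t, **kwargs)
        )
    return out
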