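"""Transmit-pulse model.

A pulse-echo system is emulated by a Gaussian-enveloped sinusoid: the
band-limited impulse response of a single-element piezocomposite transducer.
The -6 dB fractional bandwidth is the standard spec quoted for imaging
transducers, so the envelope width is parameterized from it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Full -6 dB width of a Gaussian amplitude spectrum in units of its sigma:
# |P(f0 + df)| = 0.5 |P(f0)|  =>  df = sigma_f * sqrt(2 ln 2).
_SIX_DB_WIDTH_SIGMAS = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class AcousticPulse:
    """A sampled transmit pulse.

    Attributes
    ----------
    center_frequency : float
        Carrier frequency in Hz (48 MHz for imaging, 4 MHz for therapy).
    fractional_bandwidth : float
        -6 dB spectral full width divided by the center frequency.
    sampling_rate : float
        Sample rate of ``samples`` in Hz.
    amplitude : float
        Peak envelope amplitude, linear units.
    samples : numpy.ndarray
        The waveform, odd length, envelope peak at the central sample.
    """

    center_frequency: float
    fractional_bandwidth: float
    sampling_rate: float
    amplitude: float
    samples: np.ndarray = field(repr=False)

    @property
    def duration(self) -> float:
        """Pulse support in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def half_length(self) -> int:
        """Samples from the envelope peak to either end."""
        return self.samples.size // 2

    @property
    def sigma_t(self) -> float:
        """Gaussian envelope time constant in seconds."""
        sigma_f = self.fractional_bandwidth * self.center_frequency / _SIX_DB_WIDTH_SIGMAS
        return 1.0 / (2.0 * np.pi * sigma_f)


def make_pulse(
    center_frequency: float,
    fractional_bandwidth: float,
    sampling_rate: float,
    amplitude: float = 1.0,
    n_sigma: float = 4.5,
) -> AcousticPulse:
    """Build a Gaussian-enveloped sinusoidal pulse.

    Parameters
    ----------
    center_frequency : float
        Carrier frequency, Hz. Must satisfy ``sampling_rate >= 4 * center_frequency``.
    fractional_bandwidth : float
        -6 dB bandwidth / center frequency, in (0, 2).
    sampling_rate : float
        Hz.
    amplitude : float
        Peak envelope amplitude, linear units.
    n_sigma : float
        Envelope support half-width in units of the Gaussian sigma.

    Returns
    -------
    AcousticPulse

    Raises
    ------
    ValueError
        If any argument is non-positive or the pulse would be undersampled.
    """
    if center_frequency <= 0 or sampling_rate <= 0:
        raise ValueError("center_frequency and sampling_rate must be positive")
    if not 0 < fractional_bandwidth < 2:
        raise ValueError("fractional_bandwidth must lie in (0, 2)")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if sampling_rate < 4.0 * center_frequency:
        raise ValueError(
            f"sampling_rate {sampling_rate:g} Hz violates the Nyquist safety margin: "
            f"need at least 4 x center_frequency = {4.0 * center_frequency:g} Hz"
        )

    sigma_f = fractional_bandwidth * center_frequency / _SIX_DB_WIDTH_SIGMAS
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(n_sigma * sigma_t * sampling_rate))
    n = np.arange(-half, half + 1)
    t = n / sampling_rate
    waveform = amplitude * np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(
        2.0 * np.pi * center_frequency * t
    )
    return AcousticPulse(
        center_frequency=float(center_frequency),
        fractional_bandwidth=float(fractional_bandwidth),
        sampling_rate=float(sampling_rate),
        amplitude=float(amplitude),
        samples=waveform,
    )
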