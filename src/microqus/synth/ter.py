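"""Synthetic transepithelial-resistance (TER) time series.

Emulates barrier-function monitoring of Caco-2 monolayers on porous
membrane inserts during insonation. Three arms are modelled: microbubbles
without ultrasound (MB_only), ultrasound without microbubbles (US_only),
and ultrasound with microbubbles (US_plus_MB). Each well holds a noisy
baseline, an abrupt fractional dip at the insonation time, and an
exponential return that re-attains baseline (within 1%) by the configured
recovery time.

The generator is stochastic at two levels: per-well response magnitude
(biological variability around the condition mean) and per-sample
measurement noise on the TER readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONDITIONS = ("MB_only", "US_only", "US_plus_MB")

#: Fraction of baseline within which the series counts as recovered.
RECOVERY_TOLERANCE = 0.01


@dataclass(frozen=True)
class TERTimeSeries:
    """Timestamped resistance readings for one well.

    ``resistance`` is the direct meter reading (ohm); the barrier metric is
    ``(resistance - blank_resistance) * membrane_area`` in ohm cm^2.
    """

    well_id: str
    condition: str
    time: np.ndarray = field(repr=False)  # minutes, strictly ascending
    resistance: np.ndarray = field(repr=False)  # ohm
    blank_resistance: float = 100.0
    membrane_area: float = 1.13  # cm^2, 12-well insert

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.resistance, dtype=float)
        if t.ndim != 1 or t.size != r.size:
            raise ValueError("time and resistance must be 1-D and equally long")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly ascending")
        if self.membrane_area <= 0:
            raise ValueError("membrane_area must be > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "resistance", r)

    def ter(self) -> np.ndarray:
        """TER in ohm cm^2 at every time point."""
        return (self.resistance - self.blank_resistance) * self.membrane_area


@dataclass(frozen=True)
class TERConditionSpec:
    """Ground-truth description of one insonation arm.

    ``drop_fraction`` is the mean fractional TER drop at insonation across
    wells; per-well responses are drawn with relative spread
    ``drop_rel_sd`` (biological variability). ``noise_sd`` is iid Gaussian
    measurement noise on the TER readout in ohm cm^2.
    """

    condition: str
    baseline_ter: float = 750.0  # ohm cm^2, mid acceptable window
    drop_fraction: float = 0.0
    recovery_time: float = 5.5  # min to re-attain baseline within 1%
    noise_sd: float = 1.0  # ohm cm^2
    n_wells: int = 3
    drop_rel_sd: float = 0.2
    blank_resistance: float = 100.0
    membrane_area: float = 1.13

    def __post_init__(self) -> None:
        if not 0 <= self.drop_fraction < 1:
            raise ValueError("drop_fraction must lie in [0, 1)")
        if self.baseline_ter <= 0 or self.recovery_time <= 0:
            raise ValueError("baseline_ter and recovery_time must be > 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")


def default_condition_specs(n_wells: int = 3, noise_sd: float = 1.0) -> list:
    """The three-arm design with its reported mean responses as truth:
    MBs alone leave TER unaffected, ultrasound alone drops it 2.94%, and
    ultrasound with microbubbles drops it 5.52%, all recovering in 5-6 min.
    """
    drops = {"MB_only": 0.0, "US_only": 0.0294, "US_plus_MB": 0.0552}
    return [
        TERConditionSpec(
            condition=c, drop_fraction=drops[c], n_wells=n_wells, noise_sd=noise_sd
        )
        for c in CONDITIONS
    ]


def generate_ter_series(
    spec: TERConditionSpec,
    duration: float = 20.0,
    sampling_interval: float = 0.25,
    insonation_start: float = 5.0,
    seed: int = 0,
) -> list:
    """Generate ``spec.n_wells`` TER series for one condition.

    The dip begins at ``insonation_start`` (min) and decays exponentially
    with the time constant chosen so the series re-attains baseline within
    ``RECOVERY_TOLERANCE`` exactly at ``insonation_start + recovery_time``.
    """
    if not duration > insonation_start >= 0:
        raise ValueError("need duration > insonation_start >= 0")
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be > 0")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * sampling_interval, sampling_interval)
    series = []
    for w in range(spec.n_wells):
        drop = spec.drop_fraction
        if drop > 0 and spec.drop_rel_sd > 0:
            drop = rng.normal(drop, spec.drop_rel_sd * drop)
            drop = float(np.clip(drop, 0.0, 0.99))
        ter = np.full_like(t, spec.baseline_ter)
        if drop > 0:
            after = t >= insonation_start
            if drop > RECOVERY_TOLERANCE:
                tau = spec.recovery_time / np.log(drop / RECOVERY_TOLERANCE)
            else:
                tau = spec.recovery_time / 3.0
            dip = drop * np.exp(-(t[after] - insonation_start) / tau)
            ter[after] = spec.baseline_ter * (1.0 - dip)
        if spec.noise_sd > 0:
            ter = ter + rng.normal(0.0, spec.noise_sd, ter.shape)
        resistance = spec.blank_resistance + ter / spec.membrane_area
        series.append(
            TERTimeSeries(
                well_id=f"{spec.condition}_w{w + 1}",
                condition=spec.condition,
                time=t.copy(),
                resistance=resistance,
                blank_resistance=spec.blank_resistance,
                membrane_area=spec.membrane_area,
            )
        )
    return series
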