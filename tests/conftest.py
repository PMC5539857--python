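import numpy as np
import pytest

import microqus as mq


@pytest.fixture(scope="session")
def pulse48():
    return mq.make_pulse(48e6, 0.5, 400e6)


@pytest.fixture(scope="session")
def default_scan_set():
    """Stock two-layer phantom experiment, fixed seed."""
    return mq.generate_scan_set(mq.ScanConfig(), seed=7)


@pytest.fixture(scope="session")
def weak_speckle_scan_set():
    """Homogeneous weak-scattering slab: surface echo dominates speckle by
    ~20 dB, the regime where the surface-echo amplitude picker is unbiased.
    Noiseless, interface transmission off (exact-recovery conditions)."""
    phantom = mq.LayeredPhantom(
        layers=(
            mq.TissueLayerSpec(
                name="mucosa",
                thickness=2.0,
                impedance=1.60,
                attenuation=1.86,
                backscatter_strength=1.6e-5,
                scatterer_density=200.0,
            ),
        )
    )
    cfg = mq.ScanConfig(phantom=phantom, include_transmission=False)
    return mq.generate_scan_set(cfg, seed=11)


def calibration_for(scan_set) -> mq.CalibrationSet:
    v_i = mq.calibrate_incident(
        scan_set.quartz_scan_for_incident,
        scan_set.ground_truth.coupling_impedance,
    )
    return mq.CalibrationSet(
        coupling_impedance=scan_set.ground_truth.coupling_impedance,
        quartz_impedance=scan_set.quartz_scan_for_incident.reflector_impedance,
        incident_amplitude=v_i,
        reference_echo=scan_set.quartz_scan_for_incident,
    )


def tissue_extent_mask(scan_set, n_layers: int | None = None) -> np.ndarray:
    """Ground-truth pixel extent of the first n_layers (default: the layers
    with appreciable backscatter) in the sample scan's sample grid."""
    ph = scan_set.ground_truth
    fs = scan_set.sample_scan.sampling_rate
    if n_layers is None:
        n_layers = 1
    t_top = 2.0 * (ph.standoff * 1e-3) / ph.coupling_sound_speed
    t = t_top
    for layer in ph.layers[:n_layers]:
        t += 2.0 * (layer.thickness * 1e-3) / layer.sound_speed
    i_top, i_bot = int(round(t_top * fs)), int(round(t * fs))
    truth = np.zeros_like(scan_set.sample_scan.rf, dtype=bool)
    truth[:, i_top : i_bot + 1] = True
    return truth
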