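import pytest

from cardiolum import SimConfig, simulate_ca_trace, simulate_luminescence


def make_config(**overrides) -> SimConfig:
    """A short, photon-rich recording with visible consumption dynamics.

    Ca²⁺ rises to ~2.1 µM per beat against Kd = 2 µM, so the Hill-saturating
    consumption rate spans roughly 0.001–0.55 s⁻¹ within each transient —
    enough dynamic range to exercise the budget estimators.
    """
    defaults = dict(
        duration=20.0, acq_freq=25.0, atrial_rate=180.0, conduction_ratio=1,
        ca_diastolic=0.1, ca_amplitude=2.0, tau_rise=0.03, tau_decay=0.15,
        hill_n=3.0, kd=2.0, lambda_max=1.0, pool0=1.0e6, detect_eff=1.0,
        bg_rate=50.0, read_noise_sd=0.0, triton_time=None, seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def config():
    return make_config()


def simulate_recording(**overrides):
    """Config -> (ground truth, luminescence sim) in one call."""
    cfg = make_config(**overrides)
    gt = simulate_ca_trace(cfg)
    lum = simulate_luminescence(gt, cfg)
    return cfg, gt, lum
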