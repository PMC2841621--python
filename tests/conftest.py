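import numpy as np
import pytest

from chronocycle import CellCyclePreset, Schedule, load_preset


@pytest.fixture(scope="session")
def host():
    return load_preset("host")


@pytest.fixture(scope="session")
def tumor_fast():
    return load_preset("tumor_fast")


@pytest.fixture(scope="session")
def tumor_slow():
    return load_preset("tumor_slow")


@pytest.fixture(scope="session")
def plain_preset():
    """Clock-off kinetics: no modulation, mild loss and death rates."""
    return CellCyclePreset(kappa_mean=0.05, g1_loss_rate=0.01, ts=9.0,
                           tg2_mean=3.0, tm=1.0, label="plain")


@pytest.fixture(scope="session")
def clocked_preset():
    """Generic clocked kinetics for property tests."""
    return CellCyclePreset(kappa_mean=0.05, g1_loss_rate=0.01, ts=8.0,
                           tg2_mean=3.0, tm=1.0, kappa_mod_amp=0.3,
                           kappa_mod_phase=9.0, g2_mod_amp=0.1,
                           g2_mod_phase=21.0, label="clocked")


@pytest.fixture(scope="session")
def s_schedule():
    return Schedule(target_phase="S", start_time=4.0, interval=24.0,
                    n_admin=5, k_max=0.06)


def random_clocked_preset(rng: np.random.Generator) -> CellCyclePreset:
    """Seeded draw of a valid clocked preset (shared by property tests)."""
    return CellCyclePreset(
        kappa_mean=float(rng.uniform(0.03, 0.09)),
        g1_loss_rate=float(rng.uniform(0.0, 0.02)),
        ts=float(rng.uniform(6.0, 21.0)),
        tg2_mean=float(rng.uniform(2.0, 4.0)),
        tm=1.0,
        death_s=float(rng.uniform(0.0, 0.002)),
        death_g2=float(rng.uniform(0.0, 0.002)),
        death_m=float(rng.uniform(0.0, 0.002)),
        kappa_mod_amp=float(rng.uniform(0.1, 0.3)),
        kappa_mod_phase=float(rng.uniform(0.0, 24.0)),
        g2_mod_amp=float(rng.uniform(0.0, 0.1)),
        g2_mod_phase=float(rng.uniform(0.0, 24.0)),
        label="random",
    )
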