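import numpy as np
import pandas as pd
import pytest

from hegrid import load_grid
from hegrid.pairing import PairedSet


@pytest.fixture(scope="session")
def heg():
    return load_grid("heg")


@pytest.fixture(scope="session")
def clarke():
    return load_grid("clarke")


@pytest.fixture(scope="session")
def parkes():
    return load_grid("parkes")


def make_pairs(smbg, cgm, dt_s=None) -> PairedSet:
    """Build a PairedSet directly from value arrays (dt defaults to 0)."""
    smbg = np.asarray(smbg, dtype=float)
    cgm = np.asarray(cgm, dtype=float)
    dt = np.zeros_like(smbg) if dt_s is None else np.asarray(dt_s, dtype=float)
    base = pd.Timestamp("2022-01-03")
    df = pd.DataFrame(
        {
            "patient_id": "P01",
            "t_smbg": base + pd.to_timedelta(np.arange(smbg.size), unit="h"),
            "t_cgm": base + pd.to_timedelta(np.arange(smbg.size) * 3600 + dt, unit="s"),
            "delta_t_s": dt,
            "smbg_mmol": smbg,
            "cgm_mmol": cgm,
            "diff": cgm - smbg,
            "ard": np.abs(cgm - smbg) / smbg * 100.0,
        }
    )
    return PairedSet(pairs=df, n_smbg=smbg.size, n_cgm=smbg.size, n_unpaired=0)


@pytest.fixture(scope="session")
def paper_like_run():
    """One paper-like simulated cohort, paired; shared across tests.

    Seed 1 is the suite's fixed simulation seed.
    """
    from hegrid.pairing import pair_readings
    from hegrid.simulate import paper_like_preset, simulate_cohort

    params = paper_like_preset(seed=1)
    cgm, smbg, truth = simulate_cohort(params)
    paired = pair_readings(smbg, cgm)
    return {"params": params, "cgm": cgm, "smbg": smbg, "truth": truth, "paired": paired}
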