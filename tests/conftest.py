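import numpy as np
import pandas as pd
import pytest

import cdwheat as cw


@pytest.fixture(scope="session")
def default_dataset() -> cw.Dataset:
    """One default synthetic dataset (311 records, study conditions)."""
    return cw.generate_dataset(cw.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_dataset() -> cw.Dataset:
    """Synthetic dataset whose grain Cd follows the M2 equation exactly."""
    cfg = cw.SyntheticConfig(seed=7, wheat=cw.WheatResponse(noise_sd=0.0))
    return cw.generate_dataset(cfg)


def make_frame(n: int, *, ph=6.0, cec=10.0, clay=20.0, som=15.0,
               fe_dcb=10.0, fe_ox=2.0, cd_total=1.0, cd_wheat=0.25,
               **overrides) -> pd.DataFrame:
    """Hand-built record table with broadcastable column overrides."""
    base = {"ph": ph, "cec": cec, "clay": clay, "som": som,
            "fe_dcb": fe_dcb, "fe_ox": fe_ox, "cd_total": cd_total,
            "cd_wheat": cd_wheat}
    base.update(overrides)
    cols = {k: np.broadcast_to(np.asarray(v, dtype=float), n).copy()
            for k, v in base.items()}
    return pd.DataFrame(cols)
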