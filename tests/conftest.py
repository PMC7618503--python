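import numpy as np
import pandas as pd
import pytest

import tempmort as tm


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_series(rng):
    """40-day temperature series around 20 C."""
    dates = pd.date_range("2010-01-01", periods=40, freq="D")
    return tm.TemperatureSeries("m000", dates, rng.normal(20.0, 5.0, size=40))


@pytest.fixture
def small_crossbasis_spec():
    expo = tm.SplineSpec((18.0,), (0.0, 40.0))
    lag = tm.SplineSpec((), (0.0, float(np.log(6.0))), intercept=True, transform="log")
    return tm.CrossBasisSpec(expo, lag, max_lag=5)


@pytest.fixture(scope="session")
def fitted_small_run():
    """One small end-to-end synthetic fit shared across reduction/pipeline tests."""
    surf = tm.TrueSurface()
    cfg = tm.SimConfig(n_municipalities=4, n_years=3, seed=11)
    temps = tm.simulate_temperature(cfg)
    gen = np.random.default_rng(99)
    counts = [tm.simulate_deaths(s, surf, cfg, gen) for s in temps]
    tdict = {s.municipality_id: s for s in temps}
    rcfg = tm.RunConfig(knot_candidates=((0.10, 0.75, 0.90),))
    res = tm.run_region("toy", tdict, counts, rcfg)
    return surf, cfg, tdict, counts, rcfg, res
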