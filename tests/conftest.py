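import numpy as np
import pandas as pd
import pytest

import ecoregions as er


def toy_field(values, lat0=35.0, lon0=10.0, cell_deg=0.5, mask=None,
              start="2000-01-01", units=""):
    """Build a GriddedField from a (T, nlat, nlon) array; all-ocean by default."""
    values = np.asarray(values, dtype=float)
    T, nlat, nlon = values.shape
    if mask is None:
        mask = np.ones((nlat, nlon), dtype=bool)
    return er.GriddedField(
        values=values,
        time=pd.date_range(start, periods=T, freq="MS"),
        lat=lat0 + np.arange(nlat) * cell_deg,
        lon=lon0 + np.arange(nlon) * cell_deg,
        mask=mask,
        units=units,
    )


@pytest.fixture(scope="session")
def make_field():
    return toy_field


@pytest.fixture(scope="session")
def small_cfg():
    """A quick 2-region world used by several module tests."""
    return er.SynthConfig(nlat=16, nlon=16, n_years=10, n_regions=2, seed=11)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    truth = er.generate_truth(small_cfg)
    sst = er.generate_sst(truth, small_cfg)
    return truth, sst


@pytest.fixture(scope="session")
def default_world():
    """One full-size realization of the default study conditions."""
    cfg = er.SynthConfig(seed=7)
    truth = er.generate_truth(cfg)
    sst = er.generate_sst(truth, cfg)
    anoms = er.anomalies(sst)
    return cfg, truth, sst, anoms


@pytest.fixture(scope="session")
def default_domains(default_world):
    _, _, _, anoms = default_world
    return er.identify_domains(anoms)


def best_jaccard(cells, domain_set):
    """(best Jaccard, matching domain id) of a planted cell set."""
    s = set(cells)
    best, bid = 0.0, None
    for d in domain_set.domains:
        o = set(d.cells)
        j = len(s & o) / len(s | o)
        if j > best:
            best, bid = j, d.id
    return best, bid


@pytest.fixture(scope="session")
def jaccard_matcher():
    return best_jaccard
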