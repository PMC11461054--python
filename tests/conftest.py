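"""Shared fixtures: small synthetic deployments reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from psatkit import (
    REGIMES,
    ArchivalSeries,
    BehaviourRegime,
    TagScenario,
    correct_depth,
    fit_pressure_drift,
    generate_archival_series,
    load_regions,
)


@pytest.fixture(scope="session")
def regions():
    return load_regions()


@pytest.fixture(scope="session")
def nor_scenario():
    """20-day single-regime deployment with Nordic-waters dive statistics,
    cubic pressure drift and low sensor noise."""
    return TagScenario(
        duration_days=20,
        regimes=(REGIMES["NOR"],),
        seed=7,
        drift_coeffs=(0.02, -1e-4, 0.0),
        depth_noise_sd=0.05,
        temp_noise_sd=0.02,
    )


@pytest.fixture(scope="session")
def nor_series(nor_scenario):
    series, truth = generate_archival_series(nor_scenario)
    return series, truth


@pytest.fixture(scope="session")
def nor_corrected(nor_series):
    series, truth = nor_series
    model = fit_pressure_drift(series)
    return correct_depth(series, model), truth, model


@pytest.fixture(scope="session")
def sharp_thermocline_series():
    """30-day two-layer column with a sharp (20 m scale) thermocline at
    40 m: the scenario where threshold-MLD recovery against the injected
    mixed-layer base is well posed."""
    regime = BehaviourRegime(
        dive_rate=12,
        dive_depth_dist=(90.0, 30.0),
        dive_duration_dist=(0.3, 0.15),
        mld_true=40.0,
        t_ml=14.0,
        t_deep=6.0,
        thermocline_scale=20.0,
    )
    scen = TagScenario(
        duration_days=30,
        regimes=(regime,),
        seed=5,
        drift_coeffs=(0.02, -1e-4, 0.0),
    )
    series, truth = generate_archival_series(scen)
    series = correct_depth(series, fit_pressure_drift(series))
    return series, truth


def make_series(
    depth,
    temp=None,
    *,
    interval_s=60.0,
    tag_id="T01",
    start="2022-09-01",
):
    """Hand-built uniform series for constructed-case tests."""
    depth = np.asarray(depth, dtype=float)
    if temp is None:
        temp = np.full_like(depth, 12.0)
    time = pd.date_range(start, periods=len(depth), freq=f"{int(interval_s)}s")
    return ArchivalSeries(tag_id=tag_id, time=time, depth_raw=depth, temp=np.asarray(temp, float))
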