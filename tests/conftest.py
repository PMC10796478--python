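import numpy as np
import pytest

from grazerates.timeseries_io import CountSeries, Experiment


def make_series(
    days,
    prey,
    predator=None,
    flask_id="f1",
    prey_strain="HL3E12",
    predator_strain=None,
    treatment=None,
):
    days = np.asarray(days, dtype=float)
    prey = np.asarray(prey, dtype=float)
    if predator is None:
        predator = np.zeros_like(prey)
    predator = np.asarray(predator, dtype=float)
    if treatment is None:
        treatment = "grazed" if predator.any() else "control"
    if treatment == "grazed" and predator_strain is None:
        predator_strain = "F8"
    return CountSeries(
        flask_id=flask_id,
        prey_strain=prey_strain,
        predator_strain=predator_strain,
        treatment=treatment,
        days=days,
        prey_conc=prey,
        predator_conc=predator,
    )


@pytest.fixture
def toy_pair_experiment():
    """One control and one grazed flask over a single 2-day interval."""
    ctrl = make_series([0, 2], [1000, 1160], flask_id="c1")
    gz = make_series([0, 2], [1000, 700], [200, 200], flask_id="g1")
    return Experiment(series=(ctrl, gz))
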