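import pytest

from walkerstep import ContactModel, TrackGeometry, default_config, default_walker_design


@pytest.fixture(scope="session")
def design():
    return default_walker_design()


@pytest.fixture(scope="session")
def flat_track():
    return TrackGeometry(kind="flat")


@pytest.fixture(scope="session")
def flat_model(design, flat_track):
    """Shared flat-track contact model; modest n keeps the suite fast."""
    return ContactModel(design, flat_track, n=20_000, seed=424242)


@pytest.fixture()
def tiny_config():
    """Down-scaled run config for pipeline tests."""
    cfg = default_config()
    cfg["fret"]["n_bursts"] = 400
    cfg["fret"]["n_bootstrap"] = 30
    cfg["fret"]["true_stepping_rates"] = {10: 1.0, 20: 1.0, 30: 1.0}
    cfg["kinetics"]["fuel_concentrations"] = ["1 uM", "4 uM", "10 uM"]
    cfg["sampling"]["n_conformations"] = 6000
    cfg["sampling"]["step_grid_nm"] = [10, 20, 30]
    cfg["sampling"]["n_bootstrap"] = 24
    return cfg
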