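"""Shared fixtures: the expensive integrations run once per session."""

import numpy as np
import pytest

import nephroflow as nf


@pytest.fixture(scope="session")
def params():
    return nf.load_parameters()


@pytest.fixture(scope="session")
def topo(params):
    return nf.build_topology(params)


@pytest.fixture(scope="session")
def library(params):
    return nf.load_substance_library(params.eta_water)


@pytest.fixture(scope="session")
def steady(params):
    """Drug-free physiological steady state (Tables 1-4 defaults)."""
    return nf.find_steady_state(params)


@pytest.fixture(scope="session")
def steady_obs(params, steady):
    return nf.KidneyModel(params).observables(steady)


@pytest.fixture(scope="session")
def contrast_panel(params, steady, library):
    """1.5-ml bolus scenarios over 3 h for the five packaged contrast agents."""
    panel = {}
    for name in ("iopromide_300", "iomeprol_400", "iodixanol_320",
                 "iothalamate_400", "perfect_dimer"):
        spec = library[name]
        panel[name] = nf.run_scenario(
            steady, spec, [nf.DoseEvent("bolus", spec.dose_ml_to_umol(1.5))],
            horizon=180.0, params=params)
    return panel


@pytest.fixture(scope="session")
def mannitol_run(params, steady, library):
    """The printed mannitol protocol: 0.15 g prime + 6.75 g over 450 min."""
    man = library["mannitol"]
    doses = [nf.DoseEvent("bolus", man.dose_g_to_umol(0.15)),
             nf.DoseEvent("infusion", man.dose_g_to_umol(6.75),
                          start=1.0, duration=450.0)]
    return nf.run_scenario(steady, man, doses, horizon=451.0, params=params,
                           output_dt=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
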