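import logging

import pytest

from snpmeth import CohortDesign, crosstalk_scenario, generate_bundle


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("snpmeth").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def strong_bundle(tmp_path_factory):
    """A strong-signal fixture bundle: 5 planted cross-talk genes on a
    modest cohort, shared across tests that only read it."""
    outdir = tmp_path_factory.mktemp("bundle")
    params = crosstalk_scenario(
        seed=11, n_planted=5, n_genes=60, n_probes=600, n_case=120, n_control=80
    )
    truth = generate_bundle(params, outdir)
    return params, truth, outdir


@pytest.fixture()
def two_group_design():
    def _make(n_case, n_control, prefix=("C", "K")):
        samples = [f"{prefix[0]}{i}" for i in range(n_case)] + [
            f"{prefix[1]}{i}" for i in range(n_control)
        ]
        return CohortDesign(samples, ["case"] * n_case + ["control"] * n_control)

    return _make
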