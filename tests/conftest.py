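import pytest

from ssb_burden import argentina_inputs, table3_observed


@pytest.fixture(scope="session")
def argentina():
    """Packaged country inputs (validated once per session)."""
    return argentina_inputs()


@pytest.fixture(scope="session")
def table3():
    """Published per-condition, per-sex attributable/total burden rows."""
    return table3_observed()


@pytest.fixture(scope="session")
def argentina_run(argentina):
    """One deterministic full-pipeline run on the packaged inputs."""
    from ssb_burden import run_point

    return run_point(argentina, seed=0)
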