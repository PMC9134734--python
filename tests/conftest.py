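import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))

from plastosynapo.synthetic_data import ancestral_spec, build_ancestral_genome


@pytest.fixture(scope="session")
def ancestral_record():
    """One scaled ancestral plastome shared by read-only tests."""
    return build_ancestral_genome(ancestral_spec("scaled"), seed=11)


@pytest.fixture(scope="session")
def figure2_run():
    """The packaged scenario plus a full pipeline run (built once; the
    heavyweight shared fixture behind the end-to-end tests)."""
    from plastosynapo.pipeline import RunConfig, run_pipeline
    from plastosynapo.synthetic_data import figure2_scenario

    tree, leaves, ledger, events = figure2_scenario(seed=1, sub_rate=0.01)
    bundle = run_pipeline(leaves, tree, RunConfig(reference="Osmundaceae_1", seed=1))
    return tree, leaves, ledger, events, bundle
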