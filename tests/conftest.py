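import numpy as np
import pytest

from trfkit.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic preset, shared by the
    end-to-end assertions (recovery, class mix, determinism baseline)."""
    out = tmp_path_factory.mktemp("pipeline") / "run_a"
    config = RunConfig(out_dir=str(out), seed=11)
    result = run_pipeline(config)
    return config, result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
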