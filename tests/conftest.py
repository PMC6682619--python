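import logging

import pytest

from thromboquant import run_pipeline, write_demo_inputs


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One demo dataset generated and analysed once per session."""
    logging.disable(logging.INFO)
    root = tmp_path_factory.mktemp("demo")
    config = write_demo_inputs(root, seed=1)
    manifest = run_pipeline(config)
    logging.disable(logging.NOTSET)
    return {"root": root, "config": config, "manifest": manifest}
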