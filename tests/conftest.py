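import json
from pathlib import Path

import pytest

from acnekit.pipeline import RunConfig, run
from acnekit.simulate import ScenarioConfig, generate_scenario

BUNDLE_SEED = 2018  # fixed reference seed for the default noise-free scenario


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> Path:
    """Default noise-free synthetic scenario, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    generate_scenario(ScenarioConfig(seed=BUNDLE_SEED), outdir)
    return outdir


@pytest.fixture(scope="session")
def manifest(bundle) -> dict:
    with open(bundle / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def pipeline_out(bundle, tmp_path_factory):
    """Full pipeline run over the session bundle."""
    outdir = tmp_path_factory.mktemp("run")
    report = run(RunConfig(bundle_dir=str(bundle), outdir=str(outdir),
                           seed=BUNDLE_SEED))
    return outdir, report
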