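import pytest

from agenrich import SimConfig, write_corpus
from agenrich.cli import _write_default_run_config


@pytest.fixture(scope="session")
def planted_corpus(tmp_path_factory):
    """One seeded synthetic corpus with the default planted effects,
    written to disk with a matching run configuration."""
    outdir = tmp_path_factory.mktemp("corpus")
    cfg = SimConfig(seed=7)
    manifest = write_corpus(cfg, outdir)
    _write_default_run_config(outdir)
    return outdir, cfg, manifest
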