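import numpy as np
import pytest

from regwas.synthetic import SimConfig, simulate_workspace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(seed=7, **overrides):
    """A deliberately small simulated study for fast unit tests."""
    kwargs = dict(
        seed=seed,
        n_samples=600,
        n_genes=20,
        n_res=30,
        snps_per_block=5,
        fraction_unsupported=0.2,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_workspace(tmp_path_factory):
    """A small on-disk workspace with one implanted causal element."""
    outdir = tmp_path_factory.mktemp("ws")
    config = SimConfig(
        seed=11,
        n_samples=600,
        n_genes=20,
        n_res=30,
        snps_per_block=5,
        causal_spec=[(3, 7.0)],
    )
    manifest = simulate_workspace(config, outdir)
    return outdir, config, manifest
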