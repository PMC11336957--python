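import numpy as np
import pytest

from ccan import (AlignedPair, DomainDataset, RunConfig, SimConfig,
                  generate_multiomics, preprocess, pretrain)


def small_run_config(**kw):
    """Network sized for fast tests; science-relevant defaults unchanged."""
    base = dict(encoder_dims=[64, 32], classifier_dims=[8], latent_dim=16,
                batch_size=32, epochs=40, seed=0)
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def tiny_domain():
    rng = np.random.default_rng(0)
    return DomainDataset(
        matrix=rng.normal(size=(6, 4)),
        cell_ids=[f"c{i}" for i in range(6)],
        gene_ids=["gA", "gB", "gC", "gD"],
        labels=np.array(["x", "y", "x", "y", "x", "y"]),
        modality="rna", role="source",
    )


@pytest.fixture(scope="session")
def small_pair():
    """Scaled unpaired two-modality pair, 210 cells/domain, 60 genes, 3 types."""
    cfg = SimConfig(n_cells=210, n_genes=60, n_types=3, n_cycle_genes=12,
                    type_effect_size=5.0, seed=0)
    pair, truth = generate_multiomics(cfg, paired=False)
    pair = AlignedPair(preprocess(pair.source, scale=True),
                       preprocess(pair.target, scale=True))
    return pair, truth


@pytest.fixture(scope="session")
def small_trained(small_pair):
    """A briefly pretrained model reused by downstream tests."""
    pair, _ = small_pair
    return pretrain(pair, small_run_config(), epochs=40), pair
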