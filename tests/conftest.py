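import networkx as nx
import numpy as np
import pytest

from drugnet.features import fit_scaler
from drugnet.model import DTIModel, ModelConfig
from drugnet.synthetic import SyntheticConfig, generate_study
from drugnet.training import PairData, TrainConfig, split_dataset, train

#: desk-scale model widths used throughout the suite (4 cross heads x 16 = 64)
DESK_MODEL = dict(
    d_m=64, d_g=64, gat_heads=4, transformer_heads=4,
    cross_heads=4, cross_head_dim=16, k_clusters=5, gene_head_hidden=32,
)


def desk_model_config(study, seed=0, **overrides):
    kwargs = DESK_MODEL | overrides
    return ModelConfig(n_fp=study.config.n_fp_bits, n_desc=study.config.n_desc,
                       seed=seed, **kwargs)


def build_pair_data(study, seed=0):
    scaler = fit_scaler(study.drugs.descriptors)
    dataset = split_dataset(study.interactions, seed=seed)
    return PairData(dataset, study.drugs.ids, study.drugs.fingerprints,
                    scaler.transform(study.drugs.descriptors), study.gene_labels), scaler


@pytest.fixture()
def path3():
    return nx.path_graph(["a", "b", "c"])


@pytest.fixture()
def bridged_cliques():
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(0, 4)
    return g


@pytest.fixture(scope="session")
def benchmark_study():
    """The desk-scale synthetic benchmark (fixed seed)."""
    return generate_study(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_study():
    """A small, fast synthetic study for model-contract tests."""
    cfg = SyntheticConfig(n_genes=30, k_clusters=3, n_drugs=20, n_pairs=200,
                          latent_dim=6, p_in=0.5, p_out=0.05, seed=1)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_study):
    cfg = ModelConfig(n_fp=tiny_study.config.n_fp_bits, n_desc=tiny_study.config.n_desc,
                      d_m=32, d_g=32, gat_heads=4, transformer_heads=4,
                      cross_heads=4, cross_head_dim=8, k_clusters=3,
                      gene_head_hidden=16, seed=3)
    return DTIModel(cfg, tiny_study.graph, tiny_study.partition)


@pytest.fixture(scope="session")
def trained_benchmark(benchmark_study):
    """Model trained on the benchmark at the reference optimizer settings
    (Adam, lr 1e-4, batch 64, patience 10, reconstruction warm-up).

    Session-scoped: this is the expensive fixture the learning-sanity and
    acceptance checks share.
    """
    model = DTIModel(desk_model_config(benchmark_study, seed=0),
                     benchmark_study.graph, benchmark_study.partition)
    data, scaler = build_pair_data(benchmark_study, seed=0)
    cfg = TrainConfig(learning_rate=1e-4, batch_size=64, patience=10,
                      max_epochs=250, pretrain_epochs=5, seed=0)
    result = train(model, data, cfg)
    return {"model": model, "data": data, "result": result,
            "study": benchmark_study, "scaler": scaler}
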