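import pytest

from comorbid_rank.io_model import (
    AssociativeNetwork,
    InteractionType,
    NodeClass,
)
from comorbid_rank.pipeline import RunConfig
from comorbid_rank.synthetic_data import SyntheticConfig, generate_study, write_study


def net_from_pairs(pairs, itype=InteractionType.ASSOCIATIVE, node_class=NodeClass.GENE):
    """Tiny undirected test network from (u, v) symbol pairs, one edge type."""
    net = AssociativeNetwork(name="test")
    for u, v in pairs:
        net.add_edge(u, node_class, v, node_class, itype)
    return net


def run_config_from_paths(paths, out_dir, **overrides) -> RunConfig:
    """RunConfig pointing at a written synthetic study bundle."""
    kwargs = dict(
        network_path=str(paths["network"]),
        disease_genes_path=str(paths["disease_genes"]),
        go_annotations_path=str(paths["go_annotations"]),
        disease_process_links_path=str(paths["disease_process_links"]),
        snp_catalog_path=str(paths["snp_catalog"]),
        comorbid_diseases_path=str(paths["comorbid_diseases"]),
        external_score_paths={
            cid: str(paths[f"external_scores_{cid}"]) for cid in (1, 2, 3)
        },
        output_dir=str(out_dir),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One synthetic study bundle, generated once and shared read-only."""
    config = SyntheticConfig(seed=11)
    bundle, truth = generate_study(config)
    out = tmp_path_factory.mktemp("study")
    paths = write_study(bundle, truth, out)
    return bundle, truth, paths
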