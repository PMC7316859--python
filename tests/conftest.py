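import pytest

from domainhood import pipeline
from domainhood.search import parse_domtblout
from domainhood.synthetic import default_family_specs, generate_hit_table


@pytest.fixture(scope="session")
def two_family_dataset(tmp_path_factory):
    """2 planted families x 10 genomes, no dropout, no decoys."""
    out = tmp_path_factory.mktemp("synth")
    specs = default_family_specs(n_families=2, n_domains=5, seed=7)
    return generate_hit_table(specs, n_genomes=10, out_dir=out)


@pytest.fixture(scope="session")
def curated_two_family(two_family_dataset):
    ds = two_family_dataset
    hits = parse_domtblout(ds.domtblout)
    return pipeline.curate(hits, ds.genomes, profile_meta=ds.profile_meta)
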