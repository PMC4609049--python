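import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured simulated dataset shared across tests."""
    from kleptotx.simulate import SimConfig, simulate

    return simulate(SimConfig(seed=11, n_genes=1500, decoy_factor=1.0, effects={"pw007": 2.0}))


@pytest.fixture(scope="session")
def toy_taxa():
    from kleptotx.io import TaxonMap

    return TaxonMap(
        subject_to_taxon={
            "c1": "Geminigera cryophila",
            "c2": "Guillardia theta",
            "t1": "Tetrahymena thermophila",
            "o1": "Arabidopsis thaliana",
        },
        cryptophyte_labels=frozenset({"Geminigera cryophila", "Guillardia theta"}),
        ciliate_labels=frozenset({"Tetrahymena thermophila"}),
    )


def make_hit(query, subject, evalue, bitscore=200.0):
    from kleptotx.io import HitRecord

    return HitRecord(
        query_id=query, subject_id=subject, pct_identity=90.0, aln_len=100,
        mismatches=5, gap_opens=1, qstart=1, qend=100, sstart=1, send=100,
        evalue=evalue, bitscore=bitscore,
    )
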