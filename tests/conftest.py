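import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from modycalib import score_conversion, synthetic_data
from modycalib.data_model import (
    Dataset,
    Label,
    MutationClass,
    MutationRecord,
    Phenotype,
)


@pytest.fixture(scope="session")
def registry():
    return score_conversion.default_registry()


@pytest.fixture(scope="session")
def registry_by_name(registry):
    return {s.name: s for s in registry}


def make_record(gene="GCK", vid="v1", label=Label.DISEASE,
                mclass=MutationClass.MISSENSE, phenotype=None, scores=None,
                aux=None):
    if phenotype is None:
        phenotype = Phenotype.MODY if label is Label.DISEASE else Phenotype.NONE
    return MutationRecord(
        gene=gene, variant_id=vid, label=label, mutation_class=mclass,
        phenotype=phenotype, raw_scores=scores or {}, aux=aux or {},
    )


def make_dataset(records, genes=None):
    if genes is None:
        genes = tuple(dict.fromkeys(r.gene for r in records))
    return Dataset(tuple(records), tuple(genes))


@pytest.fixture(scope="session")
def small_panel():
    """Two genes, one identity-converted method, fully deterministic."""
    recs = []
    for i, s in enumerate([0.9, 0.8, 0.7]):
        recs.append(make_record("GCK", f"c{i}", Label.DISEASE,
                                scores={"PhyloP": s}))
    for i, s in enumerate([0.3, 0.2, 0.1]):
        recs.append(make_record("GCK", f"k{i}", Label.CONTROL,
                                scores={"PhyloP": s}))
    return make_dataset(recs)


@pytest.fixture(scope="session")
def generated_panel():
    """Default synthetic seven-gene panel (seed 7), shared across tests."""
    return synthetic_data.generate(synthetic_data.per_gene_default_config(seed=7))
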