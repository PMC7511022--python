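import pytest

from placeboprot.config import SimConfig
from placeboprot import matrix as mx
from placeboprot.behavior import das_table
from placeboprot.synth import simulate_cohort


@pytest.fixture(scope="session")
def study():
    """Default synthetic study used across test modules."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def protein_data(study):
    """Protein dataset built from the default study (filled, filtered)."""
    qv = mx.aggregate_to_proteins(study.peptides_qvalue)
    qvs = mx.aggregate_to_proteins(study.peptides_qvalue_sparse)
    prot = mx.fill_and_filter(qv, qvs)
    return {
        "protein": prot,
        "log": mx.normalize_and_log(prot),
        "fc": mx.fold_changes(mx.normalized_scale(prot)),
    }


@pytest.fixture(scope="session")
def peptide_fc(study):
    pep = mx.filter_peptides(study.peptides_qvalue_sparse)
    return mx.fold_changes(mx.normalized_scale(pep), mapping=pep.mapping)


@pytest.fixture(scope="session")
def das_by_subject(study):
    return das_table(study.behavior).set_index("subject")


@pytest.fixture(scope="session")
def arm(study):
    return study.design.subjects["arm"]


@pytest.fixture(scope="session")
def sex(study):
    return study.design.subjects["sex"]
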