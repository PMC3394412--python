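"""Shared fixtures: the worked-example cohort and small text-format fixtures.

All fixture data is generated programmatically at test time.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from domainscape import examples, preprocess
from domainscape.landscape_stats import cumulative_domain_lengths, domain_counts, gene_counts
from domainscape.preprocess import assign_mutations_to_domains

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def excerpt_inputs():
    return examples.colon_domain_excerpt()


@pytest.fixture(scope="session")
def excerpt_cohort(excerpt_inputs):
    records, proteins, domains = excerpt_inputs
    cohort, _report = preprocess.build_cohort("excerpt", records, proteins, domains)
    return cohort


@pytest.fixture(scope="session")
def excerpt_domain_stats(excerpt_cohort):
    assignments, fraction = assign_mutations_to_domains(excerpt_cohort)
    counts, breakdown = domain_counts(assignments, excerpt_cohort)
    lengths = cumulative_domain_lengths(excerpt_cohort.domains)
    return {
        "assignments": assignments,
        "fraction_in_domain": fraction,
        "counts": counts,
        "breakdown": breakdown,
        "lengths": lengths,
        "gene_counts": gene_counts(excerpt_cohort),
    }


TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: biological_process_root
namespace: biological_process

[Term]
id: GO:0000002
name: signaling
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: kinase_signaling
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: map_kinase_signaling
namespace: biological_process
is_a: GO:0000003

[Term]
id: GO:0000005
name: retired_process
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0000006
name: dual_parent_activity
namespace: molecular_function
is_a: GO:0000002
relationship: part_of GO:0000003
"""

CYCLIC_OBO = """\
format-version: 1.2

[Term]
id: GO:0000010
name: chicken
namespace: biological_process
is_a: GO:0000011

[Term]
id: GO:0000011
name: egg
namespace: biological_process
is_a: GO:0000010
"""


@pytest.fixture
def toy_obo_path(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def cyclic_obo_path(tmp_path):
    path = tmp_path / "cyclic.obo"
    path.write_text(CYCLIC_OBO)
    return path
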