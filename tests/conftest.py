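import pytest

import cpnet as cp


@pytest.fixture(scope="session")
def study_matrix():
    return cp.load_haplotype_matrix()


@pytest.fixture(scope="session")
def populations():
    return cp.load_populations()


@pytest.fixture(scope="session")
def study_samples(study_matrix, populations):
    """Per-sample events, ordered sample ids, sample -> population map."""
    return cp.sample_events(study_matrix, populations)


@pytest.fixture(scope="session")
def collapsed(study_matrix, study_samples):
    """The 86 study samples collapsed and relabelled to published letters."""
    events, samples, _ = study_samples
    matrix = cp.collapse_haplotypes(events, samples)
    return cp.relabel(matrix, cp.match_labels_to_reference(matrix, study_matrix))


@pytest.fixture(scope="session")
def study_alignments(study_matrix):
    """Six-region alignments synthesized from the variant-state fixture."""
    return cp.synthesize_alignments(study_matrix, seed=11)


def make_alignment(name, rows, **kw):
    """Small helper: RegionAlignment from {sample: sequence}."""
    seqs = tuple(rows.items())
    length = len(next(iter(rows.values()))) if rows else 0
    return cp.RegionAlignment(name, seqs, kw.get("length", length))
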