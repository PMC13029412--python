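import pytest

import fam111kit as fk


@pytest.fixture(scope="session")
def family17():
    """The default synthetic family (seed 17): records, taxonomy, truth."""
    spec = fk.default_family_spec(seed=17)
    records, taxonomy, truth = fk.evolve_family(spec)
    return spec, records, taxonomy, truth


@pytest.fixture(scope="session")
def pipeline17(family17):
    """Distances, guide tree, MSA, profile and called motifs for seed 17,
    computed once and shared."""
    _, records, taxonomy, truth = family17
    params = fk.AlignmentParams()
    D = fk.distance_matrix(records, params)
    guide = fk.build_guide_tree(D)
    msa = fk.progressive_msa(records, guide, params)
    profile = fk.build_profile(msa)
    called = fk.call_motifs(profile)
    return {
        "params": params,
        "D": D,
        "guide": guide,
        "msa": msa,
        "profile": profile,
        "called": called,
    }


@pytest.fixture(scope="session")
def reference_sequence():
    return fk.load_reference_sequence()


@pytest.fixture(scope="session")
def reference_variants():
    return fk.load_reference_variants()


@pytest.fixture(scope="session")
def reference_motif_patterns():
    return fk.reference_motifs()
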