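import numpy as np
import pytest

from citmotif import array_analysis as aa
from citmotif import array_design as ad
from citmotif import synthetic_data as sd
from citmotif.immunogen_design import PositionWeightSpec, immunization_pool_spec
from citmotif.residues import STANDARD_AA


@pytest.fixture(scope="session")
def pool_spec():
    return immunization_pool_spec()


@pytest.fixture()
def toy_spec():
    return PositionWeightSpec(
        {-1: (("A", 60), ("G", 40)), 1: (("D", 50), ("S", 30), ("Y", 20))}
    )


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    manifest = sd.make_fixture_bundle(out, scale="tiny", seed=1)
    return out, manifest


@pytest.fixture(scope="session")
def array_library(pool_spec):
    """Motif set plus a 10k non-motif set and a triplicate layout."""
    motif = ad.build_motif_set(pool_spec)
    nonmotif = ad.build_non_motif_set(
        ad.nonmotif_complements(pool_spec), 10000, seed=7
    )
    design = ad.layout_array(
        motif, nonmotif, replicates=3, n_controls=100, n_blanks=100, seed=7
    )
    return motif, nonmotif, design


def _analyze(design, weights, sim_seed=13):
    model = sd.AntibodyModel(weights=weights, noise_sigma=0.3)
    spots = sd.simulate_array(design, model, seed=sim_seed)
    joined = spots.merge(
        design.mapping()[["spot_index", "group", "core"]], on="spot_index"
    )
    summaries = aa.summarize_replicates(joined)
    selection = aa.select_strong_binders(summaries)
    return summaries, selection, aa.binder_enrichment(selection, summaries)


@pytest.fixture(scope="session")
def motif_preference_sim(pool_spec, array_library):
    """Simulated antibody preferring motif-set residues with distinct weights
    per offset, so every offset has an unambiguous planted favorite."""
    _, _, design = array_library
    rng = np.random.default_rng(11)
    weights = {}
    for o in ad.CORE_OFFSETS:
        residues = list(STANDARD_AA) if o == 1 else list(pool_spec.residues(o))
        vals = 0.5 + rng.permutation(np.linspace(0, 1.2, len(residues)))
        for r, v in zip(residues, vals):
            weights[(o, r)] = float(v)
    summaries, selection, table = _analyze(design, weights)
    return weights, summaries, selection, table


@pytest.fixture(scope="session")
def full_preference_sim(array_library):
    """Simulated antibody with a distinct weight for every residue at every
    core offset (a full planted preference ranking)."""
    _, _, design = array_library
    rng = np.random.default_rng(11)
    weights = {}
    for o in ad.CORE_OFFSETS:
        vals = rng.permutation(np.linspace(0.0, 1.5, 20))
        for r, v in zip(STANDARD_AA, vals):
            weights[(o, r)] = float(v)
    summaries, selection, table = _analyze(design, weights)
    return weights, summaries, selection, table
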