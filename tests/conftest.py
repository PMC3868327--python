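import numpy as np
import pytest

from ptmsurf.datamodel import Atom, PTMRecord, PTMTable, ResidueRecord, StructureModel, VariantSite
from ptmsurf.synthetic import generate_globule, plant_variants, sample_ptms


@pytest.fixture(scope="session")
def globule64():
    return generate_globule(64, seed=1)


@pytest.fixture(scope="session")
def globule150():
    return generate_globule(150, seed=1)


@pytest.fixture(scope="session")
def bundle150():
    """A full synthetic analysis bundle: model, truth, variants, PTM table."""
    model, truth = generate_globule(150, seed=1)
    variants = plant_variants(model, truth, n_clusters=2, cluster_size=6, seed=2)
    table, ptm_truth = sample_ptms(
        model, variants, sorted(truth.shell_positions), p_near=0.5, p_far=0.25, seed=3
    )
    return model, truth, variants, table, ptm_truth


def single_atom_model(element="C", name="CA", aa="G"):
    return StructureModel([ResidueRecord(1, aa, [Atom(name, element, 0.0, 0.0, 0.0)])])


def two_atom_model(separation, element="C"):
    return StructureModel(
        [
            ResidueRecord(1, "G", [Atom("CA", element, 0.0, 0.0, 0.0)]),
            ResidueRecord(2, "G", [Atom("CA", element, separation, 0.0, 0.0)]),
        ]
    )


def brute_force_pairs(model, queries, targets, radius):
    """Reference all-pairs residue proximity scan (no spatial indexing)."""
    pairs = set()
    dists = {}
    for q in queries:
        cq = model[q].coord_array()
        for t in targets:
            if q == t:
                continue
            ct = model[t].coord_array()
            d = np.sqrt(((cq[:, None, :] - ct[None, :, :]) ** 2).sum(axis=2)).min()
            if d <= radius:
                pairs.add((q, t))
                dists[(q, t)] = float(d)
    return pairs, dists


@pytest.fixture
def small_table():
    recs = [
        PTMRecord("eEF1A1", 300, "S", "phosphorylation", 12, True, ("human",)),
        PTMRecord("eEF1A1", 273, "K", "acetylation", 7, False, ("human", "mouse")),
        PTMRecord("eEF1A1", 273, "K", "ubiquitination", 9, False, ("human",)),
        PTMRecord("eEF1A1", 273, "K", "methylation", 2, False, ("rat",)),
        PTMRecord("eEF1A1", 176, "T", "phosphorylation", 3, False, ("human",)),
        PTMRecord("eEF1A1", 234, "C", "S-nitrosylation", 1, False, ("mouse",)),
        PTMRecord("eEF1A2", 234, "C", "S-nitrosylation", 1, False, ("mouse",)),
        PTMRecord("eEF1A1", 53, "S", "O-glucosylation", 1, True, ("rabbit",)),
        PTMRecord("eEF1A1", 301, "E", "ethanolamination", 6, True, ("human",)),
    ]
    return PTMTable(records=recs, provenance="unit fixture")
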