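"""Exposure classes, proximity sets, face partitioning, charge environments."""

import numpy as np
import pytest

from ptmsurf.datamodel import Atom, ResidueRecord, StructureModel, VariantSite
from ptmsurf.geometry import (
    MAX_ASA,
    assign_faces,
    charge_environment,
    classify_exposure,
    proximity_to_targets,
    side_chain_centroid,
)
from ptmsurf.sasa import compute_sasa
from ptmsurf.synthetic import generate_globule, plant_variants

from conftest import brute_force_pairs


class TestClassifyExposure:
    def test_zero_sasa_is_buried(self, globule64):
        model, _ = globule64
        sasa = {p: 0.0 for p in model.positions}
        profile = classify_exposure(model, sasa)
        assert all(profile.is_buried(p) for p in model.positions)

    def test_isolated_residue_fully_exposed_rel_capped(self):
        model = StructureModel([ResidueRecord(1, "A", [Atom("CA", "C", 0, 0, 0)])])
        _, residue_sasa = compute_sasa(model)
        profile = classify_exposure(model, residue_sasa, max_asa={"A": residue_sasa[1] * 0.9})
        rec = profile.records[1]
        assert rec.exposure_class == "exposed"
        assert rec.sasa_rel == 1.0  # capped at 1 for reporting

    def test_missing_reference_is_error(self, globule64):
        model, _ = globule64
        _, residue_sasa = compute_sasa(model)
        with pytest.raises(ValueError, match="max-ASA"):
            classify_exposure(model, residue_sasa, max_asa={"A": 129.0})

    def test_interior_recall_on_planted_globule(self, globule150):
        """Residues fully enclosed by the shell must all be called buried."""
        model, truth = globule150
        _, residue_sasa = compute_sasa(model)
        profile = classify_exposure(model, residue_sasa)
        assert all(profile.is_buried(p) for p in truth.interior_positions)

    def test_class_is_pure_function_of_threshold(self, globule64):
        model, _ = globule64
        _, residue_sasa = compute_sasa(model)
        strict = classify_exposure(model, residue_sasa, buried_below=0.0)
        assert not any(strict.is_buried(p) for p in model.positions)
        everything = classify_exposure(model, residue_sasa, buried_below=1.0)
        rel = {p: residue_sasa[p] / MAX_ASA[model[p].aa] for p in model.positions}
        assert all(everything.is_buried(p) == (rel[p] < 1.0) for p in model.positions)


class TestProximity:
    def test_radius_below_min_distance_empty(self, globule64):
        model, _ = globule64
        prox = proximity_to_targets(model, model.positions[:10], model.positions[10:], radius=0.5)
        assert prox.pairs == set()

    def test_nonpositive_radius_rejected(self, globule64):
        model, _ = globule64
        with pytest.raises(ValueError, match="radius"):
            proximity_to_targets(model, [1], [2], radius=0.0)

    def test_unmodelled_position_rejected(self, globule64):
        model, _ = globule64
        with pytest.raises(ValueError, match="not modelled"):
            proximity_to_targets(model, [1], [9999], radius=5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_all_pairs(self, seed):
        model, _ = generate_globule(50, seed=seed)
        rng = np.random.default_rng(seed)
        queries = sorted(rng.choice(model.positions, size=20, replace=False).tolist())
        targets = sorted(rng.choice(model.positions, size=15, replace=False).tolist())
        prox = proximity_to_targets(model, queries, targets, radius=5.0)
        expected_pairs, expected_d = brute_force_pairs(model, queries, targets, 5.0)
        assert prox.pairs == expected_pairs
        for pair, d in expected_d.items():
            assert prox.distances[pair] == pytest.approx(d, abs=1e-9)

    def test_metric_symmetry(self, globule64):
        model, _ = globule64
        a, b = model.positions[:20], model.positions[20:40]
        fwd = proximity_to_targets(model, a, b, radius=6.0)
        rev = proximity_to_targets(model, b, a, radius=6.0)
        assert {(q, t) for q, t in fwd.pairs} == {(t, q) for q, t in rev.pairs}

    def test_self_pairs_excluded(self, globule64):
        model, _ = globule64
        prox = proximity_to_targets(model, model.positions, model.positions, radius=5.0)
        assert all(q != t for q, t in prox.pairs)


def _translate_rotate(model, rng):
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    axis2 = rng.uniform(0, 2 * np.pi)
    rot2 = np.array(
        [[1, 0, 0], [0, np.cos(axis2), -np.sin(axis2)], [0, np.sin(axis2), np.cos(axis2)]]
    )
    shift = rng.uniform(-50, 50, size=3)
    residues = []
    for res in model.residues:
        atoms = [
            Atom(a.name, a.element, *((rot2 @ rot @ a.coords()) + shift)) for a in res.atoms
        ]
        residues.append(ResidueRecord(res.position, res.aa, atoms))
    return StructureModel(residues, chain_id=model.chain_id)


@pytest.fixture(scope="module")
def faces_setup():
    model, truth = generate_globule(150, seed=7)
    variants = plant_variants(model, truth, n_clusters=2, cluster_size=6, seed=8)
    _, residue_sasa = compute_sasa(model)
    profile = classify_exposure(model, residue_sasa)
    return model, truth, variants, profile


class TestAssignFaces:

    def test_planted_hemisphere_poles(self, faces_setup):
        model, truth, variants, profile = faces_setup
        faces = assign_faces(model, variants, profile)
        ca_z = {r.position: next(a for a in r.atoms if a.name == "CA").z for r in model.residues}
        north = max(truth.shell_positions, key=lambda p: ca_z[p])
        south = min(truth.shell_positions, key=lambda p: ca_z[p])
        assert faces.of(north) == "variable"
        assert faces.of(south) == "conserved"

    def test_equals_direct_dot_product_scan(self, faces_setup):
        model, _, variants, profile = faces_setup
        faces = assign_faces(model, variants, profile)
        center = model.all_coords().mean(axis=0)
        for res in model.residues:
            proj = float(np.dot(side_chain_centroid(res) - center, faces.axis))
            assert faces.of(res.position) == ("variable" if proj > 0 else "conserved")

    def test_every_residue_assigned(self, faces_setup):
        model, _, variants, profile = faces_setup
        faces = assign_faces(model, variants, profile)
        assert set(faces.face) == set(model.positions)

    def test_invariant_under_rigid_motion(self, faces_setup):
        model, _, variants, profile = faces_setup
        faces = assign_faces(model, variants, profile)
        rng = np.random.default_rng(0)
        moved = _translate_rotate(model, rng)
        sasa_m = {p: profile.records[p].sasa_abs for p in model.positions}
        profile_m = classify_exposure(moved, sasa_m, buried_below=profile.buried_below)
        faces_m = assign_faces(moved, variants, profile_m)
        assert faces_m.face == faces.face

    def test_no_exposed_variants_is_error(self, faces_setup):
        model, truth, _, profile = faces_setup
        buried_pos = sorted(truth.interior_positions)[0]
        buried_variant = VariantSite(position=buried_pos, aa_A1="S", aa_A2="A")
        with pytest.raises(ValueError, match="faces are undefined"):
            assign_faces(model, [buried_variant], profile)


class TestChargeEnvironment:
    def test_no_charged_neighbors_empty(self):
        residues = [
            ResidueRecord(1, "S", [Atom("CA", "C", 0, 0, 0)]),
            ResidueRecord(2, "G", [Atom("CA", "C", 4, 0, 0)]),
        ]
        model = StructureModel(residues)
        assert charge_environment(model, 1, radius=6.0) == []

    def test_charge_signs_and_variant_flag(self):
        residues = [
            ResidueRecord(1, "K", [Atom("CA", "C", 0, 0, 0)]),
            ResidueRecord(2, "D", [Atom("CA", "C", 3, 0, 0)]),
            ResidueRecord(3, "R", [Atom("CA", "C", 0, 3, 0)]),
            ResidueRecord(4, "E", [Atom("CA", "C", 40, 0, 0)]),  # out of range
        ]
        model = StructureModel(residues)
        # a D->A paralog change removes a negative charge in one isoform
        variants = [VariantSite(position=2, aa_A1="D", aa_A2="A")]
        env = charge_environment(model, 1, radius=5.0, variants=variants)
        by_pos = {e["position"]: e for e in env}
        assert set(by_pos) == {2, 3}
        assert by_pos[2]["charge"] == -1 and by_pos[2]["isoform_difference"]
        assert by_pos[2]["variant"] == "D2A"
        assert by_pos[3]["charge"] == +1 and not by_pos[3]["isoform_difference"]

    def test_charge_conserving_variant_not_flagged(self):
        residues = [
            ResidueRecord(1, "S", [Atom("CA", "C", 0, 0, 0)]),
            ResidueRecord(2, "K", [Atom("CA", "C", 3, 0, 0)]),
        ]
        model = StructureModel(residues)
        variants = [VariantSite(position=2, aa_A1="K", aa_A2="R")]  # + to +
        env = charge_environment(model, 1, radius=5.0, variants=variants)
        assert env[0]["isoform_difference"] is False

    def test_matches_brute_force_scan(self, globule64):
        model, _ = globule64
        site = model.positions[10]
        radius = 6.0
        env = charge_environment(model, site, radius=radius)
        charged = [
            r.position for r in model.residues if r.aa in "DEKR" and r.position != site
        ]
        expected, _ = brute_force_pairs(model, [site], charged, radius)
        assert {e["position"] for e in env} == {t for _, t in expected}

    def test_unmodelled_site_is_error(self, globule64):
        model, _ = globule64
        with pytest.raises(ValueError, match="not modelled"):
            charge_environment(model, 9999, radius=5.0)
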