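"""Rigid-body assemblies: chains, docking, clash filtering, ranking."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from resinsaxs.complexes import (
    AssemblyConfig,
    CentroidModel,
    build_agarose_strand,
    build_tetramer_chain,
    clash_filter,
    dock_antibody,
    radial_density_of_assembly,
    rank_stoichiometries,
    sample_library,
    score_similarity,
    structure_pair_density,
)
from resinsaxs.containers import RadialDensity


def _assembly_with_chain(domain, strand, seed=0):
    rng = np.random.default_rng(seed)
    chain = build_tetramer_chain(domain, start_point=(6.5, 0, 0), rng=rng)
    asm = CentroidModel.merge([strand, chain])
    asm.anchors = dict(chain.anchors)
    asm.axis = strand.axis
    asm.meta = {"occupied_domains": ()}
    return asm, rng


class TestCentroidModel:
    def test_rigid_transform_preserves_distances(self, toy_models):
        antibody, _, _ = toy_models
        rng = np.random.default_rng(3)
        quat = rng.standard_normal(4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        moved = antibody.transformed(rot, translation=(1.0, -2.0, 3.0))
        d0 = pdist(antibody.points[:50])
        d1 = pdist(moved.points[:50])
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_labels_conserved_by_merge_and_transform(self, toy_models, strand):
        antibody, domain, _ = toy_models
        merged = CentroidModel.merge([strand, domain, antibody])
        assert merged.points.shape[0] == (strand.points.shape[0]
                                          + domain.points.shape[0]
                                          + antibody.points.shape[0])
        for m in (strand, domain, antibody):
            for lab in m.entities:
                assert lab in merged.entities

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            CentroidModel(np.empty((0, 3)), np.array([], dtype=object))


class TestStructurePairDensity:
    def test_two_centroids_single_bin(self):
        m = CentroidModel(np.array([[0, 0, 0], [1.0, 0, 0]]),
                          np.array(["antibody_1", "antibody_1"], dtype=object))
        pd = structure_pair_density(m, bin_width=0.25)
        assert (pd.density > 0).sum() == 1
        assert pd.r[np.argmax(pd.density)] == pytest.approx(1.0, abs=0.25)

    def test_toy_antibody_pair_density_is_bimodal(self, toy_models):
        # lobe-internal distances and lobe-lobe distances are well separated
        antibody, _, _ = toy_models
        pd = structure_pair_density(antibody, bin_width=0.25)
        lo = pd.density[(pd.r > 0.5) & (pd.r < 4.0)].max()
        valley = pd.density[(pd.r > 5.2) & (pd.r < 5.8)].min()
        hi = pd.density[(pd.r > 6.0) & (pd.r < 9.5)].max()
        assert lo > valley and hi > valley


class TestChainAndStrand:
    def test_zero_linker_anchors_touch(self, toy_models):
        # degenerate tandem-repeat case: the clash guard is disabled so
        # successive anchors can coincide
        _, domain, _ = toy_models
        chain = build_tetramer_chain(domain, linker_length=0.0, seed=2,
                                     clash_cutoff=0.0)
        for k in (1, 2, 3):
            c_prev = chain.anchors[f"c_term_{k}"]
            n_next = chain.anchors[f"n_term_{k + 1}"]
            assert np.linalg.norm(c_prev - n_next) < 1e-9

    def test_seeded_chain_is_deterministic(self, toy_models):
        _, domain, _ = toy_models
        a = build_tetramer_chain(domain, seed=5)
        b = build_tetramer_chain(domain, seed=5)
        np.testing.assert_array_equal(a.points, b.points)

    def test_end_to_end_distribution_spans_loops_to_extended(self, toy_models):
        _, domain, _ = toy_models
        dom_diameter = 2 * domain.meta["radius"]
        rng = np.random.default_rng(123)
        dists = []
        for _ in range(1000):
            chain = build_tetramer_chain(domain, rng=rng)
            dists.append(np.linalg.norm(chain.anchors["c_term_4"]
                                        - chain.anchors["n_term_1"]))
        dists = np.asarray(dists)
        assert dists.min() < dom_diameter          # loop-like folds occur
        assert dists.max() > 3.0 * dom_diameter    # near-extended chains occur

    def test_strand_surface_beads_on_cylinder(self):
        strand = build_agarose_strand(radius=6.0, length=30.0, bead_spacing=1.0)
        origin, direction = strand.axis
        rel = strand.points - origin
        proj = rel @ direction
        radial = np.linalg.norm(rel - np.outer(proj, direction), axis=1)
        on_surface = radial > 1e-9
        np.testing.assert_allclose(radial[on_surface], 6.0, atol=1e-9)

    def test_strand_bead_count_scales_with_length(self):
        n1 = build_agarose_strand(length=20.0).points.shape[0]
        n2 = build_agarose_strand(length=40.0).points.shape[0]
        assert n2 == pytest.approx(2 * n1, rel=0.1)

    def test_bare_strand_radial_profile_peaks_at_radius(self):
        strand = build_agarose_strand(radius=6.0)
        # treat the strand beads themselves as the scatterers
        probe = CentroidModel(strand.points.copy(),
                              np.full(strand.points.shape[0], "ligand_domain_1",
                                      dtype=object),
                              axis=strand.axis)
        rd = radial_density_of_assembly(probe, bin_width=0.5)
        assert rd.r[np.argmax(rd.density)] == pytest.approx(6.0, abs=0.5)

    def test_degenerate_strand_rejected(self):
        with pytest.raises(ValueError):
            build_agarose_strand(radius=0.0)


class TestDocking:
    def test_anchor_contact_distance(self, toy_models, strand):
        antibody, domain, _ = toy_models
        asm, rng = _assembly_with_chain(domain, strand, seed=1)
        site = asm.anchors["binding_site_4"]
        docked = dock_antibody(asm, 4, antibody, rng=rng)
        ab_anchor = docked.anchors["consensus_site_1"]
        assert 0.4 <= np.linalg.norm(ab_anchor - site) <= 0.6

    def test_double_occupancy_rejected(self, toy_models, strand):
        antibody, domain, _ = toy_models
        asm, rng = _assembly_with_chain(domain, strand, seed=1)
        docked = dock_antibody(asm, 4, antibody, rng=rng)
        with pytest.raises(ValueError, match="occupied"):
            dock_antibody(docked, 4, antibody, rng=rng)

    def test_missing_domain_rejected(self, toy_models, strand):
        antibody, domain, _ = toy_models
        asm, rng = _assembly_with_chain(domain, strand, seed=1)
        with pytest.raises(ValueError):
            dock_antibody(asm, 7, antibody, rng=rng)


class TestClashFilter:
    def test_distant_entities_accepted(self):
        a = CentroidModel(np.array([[0, 0, 0.0]]), np.array(["agarose"], dtype=object))
        b = CentroidModel(np.array([[10, 0, 0.0]]),
                          np.array(["antibody_1"], dtype=object))
        accepted, n = clash_filter(CentroidModel.merge([a, b]), cutoff=0.4)
        assert accepted and n == 0

    def test_coincident_entities_rejected(self):
        pts = np.array([[0, 0, 0.0], [0.01, 0, 0]])
        m = CentroidModel(pts, np.array(["agarose", "antibody_1"], dtype=object))
        accepted, n = clash_filter(m, cutoff=0.4)
        assert not accepted and n == 1

    def test_intra_entity_contacts_exempt(self):
        pts = np.array([[0, 0, 0.0], [0.1, 0, 0]])
        m = CentroidModel(pts, np.array(["agarose", "agarose"], dtype=object))
        accepted, n = clash_filter(m, cutoff=0.4)
        assert accepted and n == 0


class TestLibraries:
    def test_seeded_library_is_reproducible(self, toy_models, strand):
        antibody, domain, _ = toy_models
        cfg = AssemblyConfig("1:1", (4,))
        a = sample_library(cfg, domain, antibody, strand=strand, n_target=5, seed=8)
        b = sample_library(cfg, domain, antibody, strand=strand, n_target=5, seed=8)
        assert a.n_attempted == b.n_attempted
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.points, mb.points)

    def test_acceptance_rate_decreases_with_stoichiometry(self, toy_models,
                                                          strand):
        antibody, domain, _ = toy_models
        rates = {}
        for stoich, doms in (("1:1", (4,)), ("2:1", (1, 4)), ("3:1", (1, 2, 4))):
            cfg = AssemblyConfig(stoich, doms)
            lib = sample_library(cfg, domain, antibody, strand=strand,
                                 n_target=None, max_attempts=300, seed=11)
            rates[stoich] = lib.acceptance_rate
        assert rates["3:1"] < rates["2:1"] <= rates["1:1"]
        assert rates["3:1"] < rates["1:1"]

    def test_members_are_clash_free(self, toy_models, strand):
        antibody, domain, _ = toy_models
        cfg = AssemblyConfig("1:1", (4,))
        lib = sample_library(cfg, domain, antibody, strand=strand, n_target=5,
                             seed=8)
        for m in lib.members:
            accepted, _ = clash_filter(m, cutoff=cfg.clash_cutoff)
            assert accepted

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AssemblyConfig("2:1", (4,))
        with pytest.raises(ValueError):
            AssemblyConfig("2:1", (4, 4))
        with pytest.raises(ValueError):
            AssemblyConfig("1:1", (5,))


class TestRadialDensityAndScoring:
    def test_single_offset_centroid(self, strand):
        pts = np.vstack([strand.points, [[5.0, 0.0, 1.0]]])
        labels = np.concatenate([strand.labels, ["antibody_1"]])
        m = CentroidModel(pts, labels, axis=strand.axis)
        rd = radial_density_of_assembly(m, bin_width=0.5)
        assert rd.r[np.argmax(rd.density)] == pytest.approx(5.0, abs=0.5)

    def test_translation_along_axis_invariant(self, toy_models, strand):
        antibody, domain, _ = toy_models
        lib = sample_library(AssemblyConfig("1:1", (4,)), domain, antibody,
                             strand=strand, n_target=1, seed=3)
        m = lib.members[0]
        rd0 = radial_density_of_assembly(m, bin_width=0.5)
        shifted = m.transformed(translation=(0, 0, 7.5))
        shifted.axis = m.axis  # same strand axis reference
        rd1 = radial_density_of_assembly(shifted, bin_width=0.5)
        n = min(rd0.density.size, rd1.density.size)
        np.testing.assert_allclose(rd0.density[:n], rd1.density[:n], atol=1e-12)

    def test_library_support_bounded_by_geometry(self, toy_models, strand):
        antibody, domain, _ = toy_models
        cfg = AssemblyConfig("1:1", (4,))
        lib = sample_library(cfg, domain, antibody, strand=strand, n_target=10,
                             seed=4)
        chain_extent = 4 * 2 * domain.meta["radius"] + 3 * cfg.linker_length
        ab_extent = 6 * antibody.meta["lobe_radius"]  # conservative Y extent
        bound = cfg.strand_radius + chain_extent + ab_extent
        for m in lib.members:
            rd = radial_density_of_assembly(m, bin_width=0.5)
            assert rd.r[-1] <= bound

    def test_score_identity_and_symmetry(self):
        r = np.linspace(0.25, 20, 80)
        a = RadialDensity(r, np.exp(-0.5 * (r - 5) ** 2), kind="radial_density")
        b = RadialDensity(r, np.exp(-0.5 * (r - 9) ** 2), kind="radial_density")
        assert score_similarity(a, a) == 0.0
        assert score_similarity(a, b) == pytest.approx(score_similarity(b, a))
        assert score_similarity(a, b) > 0

    def test_zero_area_rejected(self):
        r = np.linspace(0.25, 20, 80)
        z = RadialDensity(r, np.zeros_like(r), kind="radial_density")
        a = RadialDensity(r, np.exp(-r), kind="radial_density")
        with pytest.raises(ValueError):
            score_similarity(a, z)


class TestRanking:
    def test_own_member_density_ranks_first(self, toy_models, strand):
        antibody, domain, _ = toy_models
        libs = {}
        for stoich, doms, seed in (("1:1", (4,), 21), ("2:1", (1, 4), 22)):
            libs[stoich] = sample_library(AssemblyConfig(stoich, doms), domain,
                                          antibody, strand=strand, n_target=8,
                                          seed=seed)
        target = radial_density_of_assembly(libs["1:1"].members[0], 0.5)
        table = rank_stoichiometries(libs, target)
        assert table.iloc[0]["stoichiometry"] == "1:1"
        assert table.iloc[0]["best_score"] == pytest.approx(0.0, abs=1e-12)

    def test_long_tailed_target_prefers_two_antibodies(self, toy_models, strand):
        antibody, domain, _ = toy_models
        libs = {}
        for stoich, doms, seed in (("1:1", (4,), 21), ("2:1", (1, 4), 22)):
            libs[stoich] = sample_library(AssemblyConfig(stoich, doms), domain,
                                          antibody, strand=strand, n_target=8,
                                          seed=seed)
        target = radial_density_of_assembly(libs["2:1"].members[3], 0.5)
        table = rank_stoichiometries(libs, target)
        assert table.iloc[0]["stoichiometry"] == "2:1"

    def test_self_recognition_over_noisy_observations(self, toy_models, strand):
        # the generating member's density scores best against its own noisy
        # observation in at least 18 of 20 seeded trials
        antibody, domain, _ = toy_models
        lib = sample_library(AssemblyConfig("1:1", (4,)), domain, antibody,
                             strand=strand, n_target=6, seed=33)
        densities = [radial_density_of_assembly(m, 0.5) for m in lib.members]
        wins = 0
        rng = np.random.default_rng(7)
        for t in range(20):
            k = t % len(densities)
            d = densities[k]
            noisy = RadialDensity(
                d.r, np.maximum(
                    d.density * (1 + 0.05 * rng.standard_normal(d.r.size)), 0.0),
                kind=d.kind)
            scores = [score_similarity(x, noisy) for x in densities]
            wins += int(np.argmin(scores) == k)
        assert wins >= 18

    def test_empty_library_rejected(self, toy_models):
        with pytest.raises(ValueError):
            rank_stoichiometries({}, RadialDensity(np.linspace(0.5, 5, 10),
                                                   np.ones(10)))
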