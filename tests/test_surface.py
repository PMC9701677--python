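"""Grid construction, scoring, thresholding, patches and occlusion calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stf

import networkx as nx

from coronamap.sasa import compute_sasa, relative_sidechain_accessibility
from coronamap.scale import default_scale
from coronamap.structure import generate_toy_structure
from coronamap.surface import (
    VirtualAtom,
    apply_threshold,
    build_surface_grid,
    classify_active_site,
    cluster_patches,
    residue_affinities,
    score_grid,
    write_outputs,
)
from conftest import merge_structures, single_sg_cys
from coronamap.structure import Structure


@pytest.fixture(scope="module")
def hairpin_affinities(hairpin):
    sasa = compute_sasa(hairpin)
    relative_sidechain_accessibility(sasa, hairpin)
    return residue_affinities(hairpin, default_scale(), sasa)


class TestResidueAffinities:
    def test_score_is_alpha_times_accessibility(self, hairpin, hairpin_affinities):
        for aff in hairpin_affinities:
            if not aff.excluded:
                assert aff.score == pytest.approx(aff.alpha * aff.rel_access)
                assert 0 <= aff.score <= aff.alpha

    def test_excluded_residues_carry_zero_score(self, hairpin_affinities):
        for aff in hairpin_affinities:
            if aff.excluded:
                assert aff.score == 0.0
                assert aff.exclusion_reason

    def test_disulfide_cys_score_drops_under_serine_policy(self):
        s = Structure([
            single_sg_cys("A", 1, (0.0, 0.0, 0.0)),
            single_sg_cys("A", 2, (2.04, 0.0, 0.0)),
        ])
        sasa = compute_sasa(s)
        free = residue_affinities(s, sg_cutoff=0.5)      # cutoff too small: free Cys
        bridged = residue_affinities(s, sg_cutoff=2.5)   # bonded pair
        assert free[0].alpha == pytest.approx(5.69)
        assert bridged[0].alpha == pytest.approx(0.57)

    def test_mismatched_sasa_rejected(self, hairpin):
        other = generate_toy_structure("gxg_tripeptide", x="ALA")
        sasa = compute_sasa(other)
        with pytest.raises(ValueError, match="match"):
            residue_affinities(hairpin, sasa_result=sasa)


class TestSurfaceGrid:
    def test_single_atom_shell_is_hollow(self):
        s = generate_toy_structure("single_atom")
        pts = build_surface_grid(s, spacing=1.0, shell=(1.4, 3.0))
        d_surface = np.linalg.norm(pts, axis=1) - s.atoms[0].radius
        assert len(pts) > 0
        assert d_surface.min() >= 1.4
        assert d_surface.max() <= 3.0

    def test_oversized_spacing_warns_and_returns_empty(self):
        s = generate_toy_structure("single_atom")
        with pytest.warns(UserWarning, match="empty"):
            pts = build_surface_grid(s, spacing=50.0, shell=(1.4, 2.0))
        assert len(pts) == 0

    def test_midplane_symmetry_for_a_dimer(self):
        s = generate_toy_structure("two_atoms", d=3.0)
        pts = build_surface_grid(s, spacing=1.0, shell=(1.4, 3.0))
        # reflect through the x = 1.5 midplane; the retained set maps onto itself
        reflected = pts.copy()
        reflected[:, 0] = 3.0 - reflected[:, 0]
        original = {tuple(np.round(p, 6)) for p in pts}
        mirrored = {tuple(np.round(p, 6)) for p in reflected}
        assert original == mirrored

    def test_invalid_parameters(self, hairpin):
        with pytest.raises(ValueError):
            build_surface_grid(hairpin, spacing=-1.0)
        with pytest.raises(ValueError):
            build_surface_grid(hairpin, shell=(4.0, 1.4))


def brute_force_scores(points, affinities, cutoff):
    """O(N*M) re-derivation of the grid scores used as the oracle."""
    expected = []
    for p in points:
        scores = []
        for aff in affinities:
            if aff.excluded:
                continue
            dmin = min(
                np.linalg.norm(a.coord - p) for a in aff.residue.sidechain_atoms()
            )
            if dmin <= cutoff:
                scores.append(aff.score)
        if scores:
            expected.append((tuple(p), np.mean(scores), len(scores)))
    return expected


class TestScoreGrid:
    def test_single_contributor_passes_through(self, hairpin, hairpin_affinities):
        aff = next(a for a in hairpin_affinities if not a.excluded)
        atom = aff.residue.sidechain_atoms()[0]
        point = atom.coord + np.array([3.0, 0.0, 0.0])
        out = score_grid([point], [aff], neighbor_cutoff=8.0)
        assert len(out) == 1
        assert out[0].affinity == pytest.approx(aff.score)
        assert out[0].n_contributors == 1

    def test_uniform_mean_of_two_contributors(self, hairpin_affinities):
        pair = [a for a in hairpin_affinities if not a.excluded][:2]
        mid = np.mean([p.residue.atom("CA").coord for p in pair], axis=0)
        out = score_grid([mid], pair, neighbor_cutoff=20.0)
        assert out[0].affinity == pytest.approx(np.mean([p.score for p in pair]))

    def test_matches_brute_force_oracle_exactly(self, hairpin, hairpin_affinities):
        pts = build_surface_grid(hairpin, spacing=2.0, shell=(1.4, 4.0))
        cutoff = 6.0
        ours = score_grid(pts, hairpin_affinities, neighbor_cutoff=cutoff)
        oracle = brute_force_scores(pts, hairpin_affinities, cutoff)
        assert len(ours) == len(oracle)
        for got, (coord, aff, n) in zip(ours, oracle):
            assert tuple(got.coord) == coord
            assert got.affinity == pytest.approx(aff, rel=1e-12)
            assert got.n_contributors == n

    def test_out_of_range_points_dropped(self, hairpin_affinities):
        far = np.array([[500.0, 500.0, 500.0]])
        assert score_grid(far, hairpin_affinities, neighbor_cutoff=8.0) == []

    def test_requires_scoreable_residues(self):
        with pytest.raises(ValueError, match="scoreable"):
            score_grid(np.zeros((1, 3)), [], neighbor_cutoff=8.0)


def make_vatoms(affinities):
    return [VirtualAtom(np.array([float(i), 0, 0]), a, 1) for i, a in enumerate(affinities)]


class TestThreshold:
    def test_threshold_above_max_empties_the_set(self):
        vs = make_vatoms([0.1, 0.5, 0.9])
        assert apply_threshold(vs, absolute=1.0) == []

    def test_zero_threshold_keeps_everything(self):
        vs = make_vatoms([0.1, 0.5, 0.9])
        assert len(apply_threshold(vs, absolute=0.0)) == 3

    def test_percentile_against_sort_oracle(self):
        affs = [0.05, 0.1, 0.2, 0.3, 0.45, 0.6, 0.8, 0.9]
        retained = apply_threshold(make_vatoms(affs), percentile=75.0)
        cut = np.percentile(affs, 75.0)
        expected = [a for a in affs if a >= cut]
        assert sorted(v.affinity for v in retained) == pytest.approx(sorted(expected))
        assert len(retained) == 2  # the two largest of eight

    def test_ties_at_threshold_are_retained(self):
        vs = make_vatoms([0.5, 0.5, 0.2])
        assert len(apply_threshold(vs, absolute=0.5)) == 2

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            apply_threshold(make_vatoms([0.1]), percentile=120.0)

    @settings(max_examples=100, derandomize=True)
    @given(stf.floats(min_value=0.0, max_value=2.0))
    def test_monotone_filtering(self, threshold):
        affs = [0.03, 0.1, 0.24, 0.3, 0.3, 0.55, 0.71, 0.9, 1.4, 1.9]
        lower = apply_threshold(make_vatoms(affs), absolute=threshold)
        higher = apply_threshold(make_vatoms(affs), absolute=threshold + 0.1)
        assert len(higher) <= len(lower)


class TestClusterPatches:
    def test_two_separated_groups(self):
        a = [VirtualAtom(np.array([float(i), 0, 0]), 1.0, 1) for i in range(3)]
        b = [VirtualAtom(np.array([float(i) + 20.0, 0, 0]), 0.5, 1) for i in range(3)]
        patches = cluster_patches(a + b, adjacency=1.5)
        assert len(patches) == 2
        assert patches[0].mean_affinity >= patches[1].mean_affinity

    def test_single_connected_blob(self):
        vs = [VirtualAtom(np.array([float(i), 0, 0]), 1.0, 1) for i in range(10)]
        assert len(cluster_patches(vs, adjacency=1.1)) == 1

    def test_small_patches_flagged_not_dropped(self):
        vs = [VirtualAtom(np.zeros(3), 1.0, 1)]
        patches = cluster_patches(vs, adjacency=1.0, min_size=3)
        assert len(patches) == 1 and patches[0].small

    def test_matches_union_find_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.uniform(0, 12, size=(40, 3))
            vs = [VirtualAtom(p, float(a), 1) for p, a in zip(pts, rng.uniform(0, 1, 40))]
            adjacency = 2.5
            patches = cluster_patches(vs, adjacency)
            g = nx.Graph()
            g.add_nodes_from(range(len(pts)))
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    if np.linalg.norm(pts[i] - pts[j]) <= adjacency:
                        g.add_edge(i, j)
            expected = {frozenset(map(tuple, pts[list(c)])) for c in nx.connected_components(g)}
            got = {frozenset(tuple(m.coord) for m in p.members) for p in patches}
            assert got == expected

    def test_empty_input(self):
        assert cluster_patches([], adjacency=1.0) == []


class TestOcclusion:
    def test_no_patches_means_exposed(self, hairpin):
        report = classify_active_site([], hairpin, ["A:6"])
        assert report.call == "exposed"
        assert report.overlap_fraction == 0.0

    def test_site_inside_contact_shell_is_occluded(self, hairpin):
        site_res = hairpin.get_residue("A", 6)
        v = VirtualAtom(site_res.atom("CA").coord + 1.0, 1.0, 1)
        patches = cluster_patches([v], adjacency=1.0)
        report = classify_active_site(patches, hairpin, [site_res])
        assert report.call == "occluded"
        assert report.overlap_fraction == 1.0

    def test_unknown_residue_lists_valid_numbering(self, hairpin):
        with pytest.raises(KeyError, match="valid numbering"):
            classify_active_site([], hairpin, ["A:999"])

    def test_string_and_tuple_references_agree(self, hairpin):
        a = classify_active_site([], hairpin, ["A:6"])
        b = classify_active_site([], hairpin, [("A", 6)])
        assert a.active_site == b.active_site


class TestWriteOutputs:
    def test_minimal_run_produces_four_files(self, tmp_path, hairpin, hairpin_affinities):
        pts = build_surface_grid(hairpin, 1.5, (1.4, 4.0))
        vs = score_grid(pts, hairpin_affinities)
        retained = apply_threshold(vs, percentile=75.0)
        patches = cluster_patches(retained, 1.5 * np.sqrt(3))
        report = classify_active_site(patches, hairpin, ["A:6"])
        paths = write_outputs(vs, patches, report, tmp_path / "run",
                              affinities=hairpin_affinities)
        assert set(paths) == {"pdb", "pml", "tsv", "json"}
        assert all(p.exists() for p in paths.values())
        n_hetatm = sum(
            1 for line in paths["pdb"].read_text().splitlines()
            if line.startswith("HETATM")
        )
        assert n_hetatm == len(retained)

    def test_pseudo_atom_round_trip(self, tmp_path):
        vs = [VirtualAtom(np.array([1.234, -5.678, 9.012]), 0.87, 2)]
        apply_threshold(vs, absolute=0.0)
        paths = write_outputs(vs, [], None, tmp_path / "rt")
        from coronamap.structure import load_structure

        again = load_structure(paths["pdb"], keep_het=True)
        atom = again.atoms[0]
        np.testing.assert_allclose(atom.coord, vs[0].coord, atol=1e-3)
        assert atom.bfactor == pytest.approx(0.87, abs=5e-3)

    def test_empty_retained_set_warns(self, tmp_path):
        vs = make_vatoms([0.1])
        apply_threshold(vs, absolute=99.0)
        with pytest.warns(UserWarning, match="empty"):
            paths = write_outputs(vs, [], None, tmp_path / "empty")
        assert paths["pdb"].read_text().strip() == "END"


class TestEndToEndInvariants:
    def test_rigid_motion_leaves_affinities_invariant(self, two_face_structure):
        from scipy.spatial.transform import Rotation
        from coronamap import predict_binding_surface, RunConfig

        cfg = RunConfig(n_sphere_points=240, grid_spacing=2.0)
        base = predict_binding_surface(two_face_structure, config=cfg)
        rot = Rotation.from_euler("xyz", [25, 40, -15], degrees=True).as_matrix()
        moved = two_face_structure.transformed(rot, np.array([5.0, -8.0, 3.0]))
        after = predict_binding_surface(moved, config=cfg)
        # the grid is regenerated in the rotated frame, so compare summaries
        mean_base = np.mean([v.affinity for v in base.virtual_atoms])
        mean_after = np.mean([v.affinity for v in after.virtual_atoms])
        assert mean_after == pytest.approx(mean_base, rel=0.05)
        assert len(after.retained) == pytest.approx(len(base.retained), rel=0.15)

    def test_total_weighted_affinity_never_rises_when_a_score_is_zeroed(
        self, hairpin, hairpin_affinities
    ):
        import copy

        pts = build_surface_grid(hairpin, 2.0, (1.4, 4.0))
        base = score_grid(pts, hairpin_affinities)
        total = sum(v.affinity * v.n_contributors for v in base)
        for idx in range(0, len(hairpin_affinities), 3):
            mutated = copy.deepcopy(list(hairpin_affinities))
            mutated[idx].score = 0.0
            after = score_grid(pts, mutated)
            total_after = sum(v.affinity * v.n_contributors for v in after)
            assert total_after <= total + 1e-9

    def test_high_affinity_face_outscores_low_affinity_face(self, two_face_structure):
        """Virtual atoms near the cysteine-rich chain must dominate those near
        the glutamate chain, the analogue of a sheet face outscoring a helix
        face on a real protein."""
        from coronamap import predict_binding_surface, RunConfig

        res = predict_binding_surface(two_face_structure,
                                      config=RunConfig(n_sphere_points=240))
        cys_ca = np.array([
            r.atom("CA").coord for r in two_face_structure.residues if r.chain_id == "A"
        ])
        glu_ca = np.array([
            r.atom("CA").coord for r in two_face_structure.residues if r.chain_id == "B"
        ])
        near_cys, near_glu = [], []
        for v in res.virtual_atoms:
            d_c = np.linalg.norm(cys_ca - v.coord, axis=1).min()
            d_e = np.linalg.norm(glu_ca - v.coord, axis=1).min()
            (near_cys if d_c < d_e else near_glu).append(v.affinity)
        assert np.mean(near_cys) > np.mean(near_glu)
        # and every retained patch hugs the cysteine chain
        top = res.patches[0]
        d_c = np.linalg.norm(cys_ca - top.centroid, axis=1).min()
        d_e = np.linalg.norm(glu_ca - top.centroid, axis=1).min()
        assert d_c < d_e
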