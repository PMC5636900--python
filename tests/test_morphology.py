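"""Morphometry: SWC I/O, laminar apportioning, feature vectors, PCA."""

import numpy as np
import pytest

from barrelpt.cohort import default_config, generate_morphology
from barrelpt.morphology import (
    FEATURE_NAMES,
    LayerScheme,
    NeuronMorphology,
    SwcParseError,
    default_layers,
    feature_vector,
    laminar_profile,
    pca_features,
    read_swc,
    write_swc,
)


def make_morph(nodes):
    """nodes: list of (kind, (x, y, z), parent_index)."""
    return NeuronMorphology(
        node_ids=np.arange(1, len(nodes) + 1),
        parent_index=np.array([p for _, _, p in nodes]),
        kinds=np.array([k for k, _, _ in nodes], dtype=object),
        xyz=np.array([xyz for _, xyz, _ in nodes], dtype=float),
        radius=np.ones(len(nodes)),
    )


class TestSwcIO:
    def test_roundtrip_identity(self, tmp_path):
        m = make_morph(
            [
                ("soma", (0, 1100, 0), -1),
                ("basal", (50, 1100, 0), 0),
                ("basal", (120, 1100, 30), 1),
                ("apical", (0, 900, 0), 0),
                ("apical", (10, 500, 0), 3),
                ("apical", (40, 480, 5), 4),
            ]
        )
        path = tmp_path / "cell.swc"
        write_swc(m, path)
        back = read_swc(path)
        assert np.array_equal(back.parent_index, m.parent_index)
        assert np.array_equal(back.kinds, m.kinds)
        np.testing.assert_allclose(back.xyz, m.xyz, atol=1e-6)

    def test_three_node_cable_length(self, tmp_path):
        path = tmp_path / "cable.swc"
        path.write_text(
            "1 1 0 1000 0 8 -1\n2 3 0 1000 0 1 1\n3 3 300 1000 0 1 2\n"
        )
        m = read_swc(path)
        prof = laminar_profile(m)
        assert prof.path_length.sum() == pytest.approx(300.0)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("1 1 0 0 0 1 -1\n2 3 0 1 0 1 9\n", "parent 9 not declared"),
            ("1 1 0 0 0 1 -1\n2 7 0 1 0 1 1\n", "unknown structure code"),
            ("1 1 0 0 0 1 -1\n2 1 5 0 0 1 -1\n", "one root"),
            ("1 1 0 0 0 1 -1\n2 3 0 1 0 1\n", "7 columns"),
        ],
    )
    def test_malformed_inputs_raise(self, tmp_path, content, match):
        path = tmp_path / "bad.swc"
        path.write_text(content)
        with pytest.raises(SwcParseError, match=match):
            read_swc(path)

    def test_generated_cohort_roundtrip(self, tmp_path):
        group = default_config().groups[0]
        m = generate_morphology(group, 1100.0, seed=5)
        path = tmp_path / "gen.swc"
        write_swc(m, path)
        back = read_swc(path)
        orig = laminar_profile(m)
        again = laminar_profile(back)
        np.testing.assert_allclose(again.path_length, orig.path_length, rtol=1e-5)
        assert np.array_equal(again.branch_points, orig.branch_points)


class TestLaminarProfile:
    def test_vertical_cable_split_at_boundary(self):
        scheme = LayerScheme(names=("A", "B"), boundaries=(0.0, 100.0, 400.0))
        m = make_morph([("soma", (0, 300, 0), -1), ("apical", (0, 0, 0), 0)])
        prof = laminar_profile(m, scheme)
        assert prof.path_length[0] == pytest.approx(100.0)
        assert prof.path_length[1] == pytest.approx(200.0)

    def test_fork_counted_in_containing_layer(self, layers):
        # bifurcation at depth 500 falls in L2/3 under the default scheme
        m = make_morph(
            [
                ("soma", (0, 1100, 0), -1),
                ("apical", (0, 500, 0), 0),
                ("apical", (-50, 400, 0), 1),
                ("apical", (50, 400, 0), 1),
            ]
        )
        prof = laminar_profile(m, layers)
        assert prof.branch_points[layers.index_of("L2/3")] == 1
        assert prof.branch_points.sum() == 1

    def test_complexity_zero_without_branch_points(self, layers):
        m = make_morph([("soma", (0, 1100, 0), -1), ("basal", (800, 1100, 0), 0)])
        prof = laminar_profile(m, layers)
        assert prof.path_length[layers.index_of("L5B")] == pytest.approx(800.0)
        assert np.all(prof.complexity == 0)

    def test_matches_dense_sampling_oracle(self, rng, layers):
        """Analytic segment clipping equals brute-force 0.1 um sampling."""
        m = generate_morphology(default_config().groups[2], 1131.0, seed=9)
        prof = laminar_profile(m, layers)

        boundaries = np.asarray(layers.boundaries)
        dense = np.zeros(layers.n_layers)
        p_xyz, c_xyz, c_kind = m.edge_arrays()
        for a, b, kind in zip(p_xyz, c_xyz, c_kind):
            if kind == "soma":
                continue
            length = np.linalg.norm(b - a)
            n = max(int(np.ceil(length / 0.1)), 1)
            ts = (np.arange(n) + 0.5) / n
            depths = a[1] + (b[1] - a[1]) * ts
            idx = np.clip(np.searchsorted(boundaries, depths, side="right") - 1, 0, layers.n_layers - 1)
            np.add.at(dense, idx, length / n)
        np.testing.assert_allclose(prof.path_length, dense, rtol=1e-3, atol=1e-3)

    def test_invariant_to_edge_subdivision(self, layers):
        m = make_morph([("soma", (0, 1100, 0), -1), ("apical", (0, 200, 0), 0)])
        m2 = make_morph(
            [
                ("soma", (0, 1100, 0), -1),
                ("apical", (0, 650, 0), 0),
                ("apical", (0, 200, 0), 1),
            ]
        )
        p1, p2 = laminar_profile(m, layers), laminar_profile(m2, layers)
        np.testing.assert_allclose(p1.path_length, p2.path_length, atol=1e-9)
        assert np.array_equal(p1.branch_points, p2.branch_points)

    def test_negative_depth_clipped_with_warning(self, layers):
        m = make_morph([("soma", (0, 100, 0), -1), ("apical", (0, -50, 0), 0)])
        with pytest.warns(UserWarning, match="above the pia"):
            prof = laminar_profile(m, layers)
        assert prof.path_length.sum() == pytest.approx(150.0)


class TestFeatureVector:
    def test_unbranched_basal_cable(self):
        m = make_morph([("soma", (0, 1100, 0), -1), ("basal", (1000, 1100, 0), 0)])
        with pytest.warns(UserWarning, match="apical"):
            fv = feature_vector(m)
        assert fv["total_length"] == pytest.approx(1000.0)
        assert fv["total_branch_points"] == 0
        assert fv["max_branch_order"] == 1
        assert fv["n_primary_basal_stems"] == 1

    def test_fixed_length_and_order(self, small_cohort):
        fv = feature_vector(small_cohort[0].morphology)
        assert fv.names == FEATURE_NAMES
        assert len(fv.values) == 21

    def test_totals_consistent_with_laminar_sums(self, small_cohort, layers):
        cell = small_cohort[3]
        fv = feature_vector(cell.morphology, layers)
        prof = laminar_profile(cell.morphology, layers)
        assert fv["total_length"] == pytest.approx(prof.path_length.sum(), rel=1e-6)
        assert fv["total_branch_points"] == prof.branch_points.sum()

    def test_generation_targets_recovered(self, small_cohort):
        """Round trip: extraction recovers each cell's laminar targets."""
        for cell in small_cohort[:6]:
            fv = feature_vector(cell.morphology)
            assert fv["total_length"] == pytest.approx(sum(cell.laminar_length), rel=0.05)
            assert fv["total_branch_points"] == sum(cell.laminar_bp)


class TestPCA:
    def test_identical_cells_score_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (2, 1)) + np.array([[0.0], [0.0]])
        X[:, 0] = [1.0, 2.0]  # one varying column to avoid all-constant input
        with pytest.warns(UserWarning, match="constant feature"):
            scores, _, _ = pca_features(X)
        assert scores.shape[1] == 1

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(15, 6))
        scores, loadings, _ = pca_features(X)
        Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        np.testing.assert_allclose(scores @ loadings, Xz, atol=1e-10)
        np.testing.assert_allclose(loadings @ loadings.T, np.eye(6), atol=1e-10)

    def test_pc1_separates_thick_from_slender_tufted(self, small_cohort):
        """Halving all dendritic quantities (the slender-tufted contrast:
        7.4 mm vs 14.7 mm total length) must separate on PC1."""
        thick = np.array([feature_vector(c.morphology).values for c in small_cohort[:8]])
        slender = thick.copy()
        slender[:, 1:] *= 0.5
        X = np.vstack([thick, slender])
        scores, _, _ = pca_features(X)
        pc1 = scores[:, 0]
        assert (pc1[:8].mean() - pc1[8:].mean()) ** 2 > (pc1[:8].var() + pc1[8:].var())
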