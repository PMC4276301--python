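"""Alignment, grids, interaction fields, kNN-MFA."""

import numpy as np
import pytest

from thioqsar import field3d as f3
from thioqsar.selection import SelectionConfig
from thioqsar.synthetic import Toy3DSpec, gen_toy_3d_set


def _rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return R, rng.uniform(-5, 5, 3)


class TestAlignment:
    def test_self_alignment(self, rng):
        coords = rng.normal(size=(8, 3))
        aligned, rmsd = f3.align_to_template(coords, range(8), coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert aligned == pytest.approx(coords, abs=1e-10)

    def test_rigid_motion_recovered(self, rng):
        coords = rng.normal(size=(6, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = coords @ Rz.T + np.array([3.0, -1.0, 2.0])
        aligned, rmsd = f3.align_to_template(moved, range(6), coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert aligned == pytest.approx(coords, abs=1e-9)

    def test_noisy_copy_matches_scipy_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        ref = rng.normal(size=(7, 3))
        R, t = _rigid(rng)
        noisy = (ref + rng.normal(0, 0.1, (7, 3))) @ R.T + t
        _, rmsd = f3.align_to_template(noisy, range(7), ref)
        # independent optimizer over rotations
        a = noisy - noisy.mean(0)
        b = ref - ref.mean(0)
        rot, rssd = Rotation.align_vectors(b, a)
        assert rmsd == pytest.approx(rssd / np.sqrt(7), abs=1e-6)

    def test_too_few_or_collinear(self, rng):
        coords = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="at least 3"):
            f3.align_to_template(coords, [0, 1], coords)
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="collinear"):
            f3.align_to_template(line, range(5), line)


class TestGrid:
    def test_single_atom_box(self):
        grid = f3.build_grid([np.zeros((1, 3))], spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.n_points == 125

    def test_margin_monotone(self, rng):
        coords = [rng.normal(size=(6, 3))]
        n = [f3.build_grid(coords, 2.0, m).n_points for m in (2.0, 4.0, 6.0)]
        assert n[0] <= n[1] <= n[2]

    def test_x_fastest_raster_order(self):
        grid = f3.Grid(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(3, 2, 2))
        pts = grid.points()
        assert pts[0] == pytest.approx([0, 0, 0])
        assert pts[1] == pytest.approx([1, 0, 0])  # x varies fastest
        assert pts[3] == pytest.approx([0, 1, 0])
        assert pts[6] == pytest.approx([0, 0, 1])

    def test_4500_field_columns_for_1500_points(self):
        grid = f3.Grid(origin=(0.0, 0.0, 0.0), spacing=2.0, dims=(10, 15, 10))
        assert grid.n_points == 1500
        from thioqsar.compound_data import Compound

        comp = Compound(id="probe", coords=np.array([[9.0, 14.0, 9.0]]),
                        elements=["C"], charges=np.array([0.1]))
        table = f3.compute_field_table([comp], grid)
        assert table.n_columns == 4500


class TestElectrostaticField:
    def test_single_charge_truncated_to_cutoff(self):
        # 332.0*1*1/(r=1 * 1) = 332 kcal/mol -> clipped at +10
        e = f3.electrostatic_field([1.0], [[0.0, 0.0, 0.0]],
                                   np.array([[1.0, 0.0, 0.0]]))
        assert e[0] == pytest.approx(10.0)

    def test_zero_charges_zero_field(self, rng):
        pts = rng.normal(size=(20, 3)) * 5
        e = f3.electrostatic_field(np.zeros(4), rng.normal(size=(4, 3)), pts)
        assert np.allclose(e, 0.0)

    def test_charge_negation_antisymmetry(self, rng):
        charges = rng.uniform(-0.3, 0.3, 5)
        coords = rng.normal(size=(5, 3))
        pts = rng.normal(size=(30, 3)) * 6
        a = f3.electrostatic_field(charges, coords, pts)
        b = f3.electrostatic_field(-charges, coords, pts)
        assert a == pytest.approx(-b, abs=1e-12)  # linear pre-truncation

    def test_constant_dielectric_closed_form(self):
        e = f3.electrostatic_field([0.01], [[0.0, 0.0, 0.0]],
                                   np.array([[2.0, 0.0, 0.0]]),
                                   dielectric="constant", epsilon=4.0)
        assert e[0] == pytest.approx(332.0 * 0.01 / (4.0 * 2.0), abs=1e-12)


class TestStericField:
    def test_far_point_negligible(self):
        s = f3.steric_field(["C"], [[0.0, 0.0, 0.0]],
                            np.array([[25.0, 0.0, 0.0]]))
        assert abs(s[0]) < 1e-4

    def test_contact_distance_truncated(self):
        s = f3.steric_field(["C"], [[0.0, 0.0, 0.0]],
                            np.array([[0.5, 0.0, 0.0]]))
        assert s[0] == pytest.approx(30.0)

    def test_minimum_at_analytic_rmin(self):
        # dV/dr = 0 at r_min = (2A/B)^(1/6)
        probe = f3.ProbeParameters()
        sig_i, eps_i = f3.LJ_TABLE["C"]
        sig = 0.5 * (sig_i + probe.sigma)
        eps = np.sqrt(eps_i * probe.epsilon)
        A, B = 4 * eps * sig**12, 4 * eps * sig**6
        r_min = (2 * A / B) ** (1 / 6)
        r = np.linspace(r_min - 0.5, r_min + 0.5, 2001)
        pts = np.column_stack([r, np.zeros_like(r), np.zeros_like(r)])
        v = f3.steric_field(["C"], [[0.0, 0.0, 0.0]], pts)
        assert r[np.argmin(v)] == pytest.approx(r_min, abs=1e-3)
        assert v.min() == pytest.approx(-eps, abs=1e-6)

    def test_unknown_element(self):
        with pytest.raises(KeyError, match="Xx"):
            f3.steric_field(["Xx"], [[0.0, 0.0, 0.0]], np.zeros((1, 3)))


class TestHydrophobicField:
    def test_zero_increments(self):
        h = f3.hydrophobic_field(np.zeros(3), np.zeros((3, 3)),
                                 np.ones((5, 3)))
        assert np.allclose(h, 0.0)

    def test_linearity_in_increments(self, rng):
        inc = rng.uniform(0, 0.2, 4)
        coords = rng.normal(size=(4, 3))
        pts = rng.normal(size=(10, 3)) * 5
        assert f3.hydrophobic_field(2 * inc, coords, pts) == pytest.approx(
            2 * f3.hydrophobic_field(inc, coords, pts), abs=1e-12
        )

    def test_single_atom_hand_formula(self):
        h = f3.hydrophobic_field([0.5], [[0.0, 0.0, 0.0]],
                                 np.array([[3.0, 0.0, 0.0]]))
        assert h[0] == pytest.approx(0.5 / 4.0, abs=1e-12)


class TestFieldInvariants:
    def test_rigid_motion_invariance(self, rng):
        charges = rng.uniform(-0.4, 0.4, 6)
        elements = ["C", "N", "O", "S", "C", "H"]
        coords = rng.normal(size=(6, 3)) * 2
        pts = rng.normal(size=(40, 3)) * 5
        R, t = _rigid(rng)
        for fn in (
            lambda c, p: f3.electrostatic_field(charges, c, p),
            lambda c, p: f3.steric_field(elements, c, p),
            lambda c, p: f3.hydrophobic_field(elements, c, p),
        ):
            a = fn(coords, pts)
            b = fn(coords @ R.T + t, pts @ R.T + t)
            assert a == pytest.approx(b, abs=1e-8)

    def test_truncation_bounds_on_generated_set(self):
        comps, y, truth = gen_toy_3d_set(Toy3DSpec(seed=3))
        ref = comps[int(np.argmax(y))]
        aligned = [f3.align_to_template(c, truth["core_indices"], ref)[0]
                   for c in comps]
        grid = f3.build_grid(aligned, 2.0, 4.0)
        table = f3.compute_field_table(comps, grid, aligned_coords=aligned)
        e_cols = [c for c in table.df.columns if c.startswith("E_")]
        s_cols = [c for c in table.df.columns if c.startswith("S_")]
        assert np.abs(table.df[e_cols].to_numpy()).max() <= 10.0 + 1e-12
        assert np.abs(table.df[s_cols].to_numpy()).max() <= 30.0 + 1e-12


class TestKNN:
    def _model(self, X, y, cols, k):
        import pandas as pd

        df = pd.DataFrame(X, columns=cols)
        return f3.KNNFieldModel(selected_points=cols, k=k, train_fields=df,
                                train_activities=np.asarray(y, float))

    def test_exact_match_returns_activity(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = self._model(X, y, ["a", "b", "c"], k=1)
        assert f3.knn_predict(model, X[4]) == pytest.approx(y[4])

    def test_equidistant_neighbors_average(self):
        X = np.array([[1.0], [-1.0], [5.0]])
        y = np.array([7.0, 8.0, 0.0])
        model = self._model(X, y, ["a"], k=2)
        assert f3.knn_predict(model, np.array([0.0])) == pytest.approx(7.5)

    def test_matches_naive_sort_oracle(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = self._model(X, y, list("abcd"), k=3)
        for q in rng.normal(size=(6, 4)):
            dists = sorted(
                (float(np.linalg.norm(X[i] - q)), i) for i in range(10)
            )[:3]
            w = [1.0 / d for d, _ in dists]
            expected = sum(wi * y[i] for wi, (_, i) in zip(w, dists)) / sum(w)
            assert f3.knn_predict(model, q) == pytest.approx(expected, abs=1e-12)

    def test_full_k_uniformish_baseline(self, rng):
        # LOO with k = n-1: predictions pool nearly all other compounds, so
        # q2 sits near the mean-predictor baseline (0) on structureless data
        X = rng.normal(size=(15, 1)) * 1e-3  # nearly uniform distances
        y = rng.normal(size=15)
        q2 = f3.knn_loo_q2(X, y, k=14)
        assert q2 < 0.5


class TestKNNMFA:
    def test_planted_single_column_signal(self):
        comps, y, truth = gen_toy_3d_set(Toy3DSpec(seed=5, noise_sd=0.0))
        ref = comps[int(np.argmax(y))]
        aligned = [f3.align_to_template(c, truth["core_indices"], ref)[0]
                   for c in comps]
        grid = f3.build_grid(aligned, 2.0, 4.0)
        table = f3.compute_field_table(comps, grid, aligned_coords=aligned)
        model = f3.knn_mfa_fit(
            table, y, SelectionConfig(max_terms=2, seed=0, generations=40), k=2
        )
        assert model.q2 >= 0.9

    def test_exhaustive_two_subset_enumeration(self, rng):
        from itertools import combinations

        import pandas as pd

        X = rng.normal(size=(12, 5))
        y = X[:, 1] + 0.1 * rng.normal(size=12)
        df = pd.DataFrame(X, columns=[f"F_{i}" for i in range(5)])
        best = max(
            f3.knn_loo_q2(X[:, list(s)], y, 2)
            for r in (1, 2) for s in combinations(range(5), r)
        )
        model = f3.knn_mfa_fit(df, y,
                               SelectionConfig(max_terms=2, seed=1,
                                               generations=30), k=2)
        assert model.q2 == pytest.approx(best, abs=1e-10)

    def test_constant_columns_rejected(self):
        import pandas as pd

        df = pd.DataFrame(np.ones((8, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            f3.knn_mfa_fit(df, np.arange(8.0),
                           SelectionConfig(max_terms=2, seed=0))
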