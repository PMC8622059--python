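import numpy as np
import pytest

import landsec as ls
from landsec.ahp_weights import RI_TABLE, geometric_mean_weights
from landsec.errors import (
    ConsistencyError,
    SaatyScaleWarning,
    SchemaError,
    UnsupportedOrderError,
    ValidationError,
)


def dense_principal(values):
    """Oracle: principal eigenpair from a full dense eigendecomposition."""
    eigvals, eigvecs = np.linalg.eig(values)
    k = int(np.argmax(eigvals.real))
    v = np.abs(eigvecs[:, k].real)
    return v / v.sum(), float(eigvals[k].real)


CONSISTENT_3 = ls.JudgmentMatrix(
    ("a", "b", "c"),
    np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]], dtype=float),
)
INCONSISTENT_3 = ls.JudgmentMatrix(
    ("a", "b", "c"),
    np.array([[1, 2, 0.5], [0.5, 1, 4], [2, 0.25, 1]], dtype=float),
)


class TestJudgmentMatrix:
    def test_bad_diagonal(self):
        with pytest.raises(ValidationError):
            ls.JudgmentMatrix(("a", "b"), np.array([[1.0, 2.0], [0.5, 1.1]]))

    def test_broken_reciprocity(self):
        with pytest.raises(ValidationError):
            ls.JudgmentMatrix(("a", "b"), np.array([[1.0, 2.0], [0.6, 1.0]]))

    def test_nonpositive_entry(self):
        with pytest.raises(ValidationError):
            ls.JudgmentMatrix(("a", "b"), np.array([[1.0, -2.0], [-0.5, 1.0]]))

    def test_scale_warning(self):
        w = ls.WeightVector(("a", "b"), np.array([0.95, 0.05]))
        with pytest.warns(SaatyScaleWarning):
            ls.judgment_from_weights(w)  # ratio 19 exceeds the 1-9 scale


class TestJudgmentFromWeights:
    def test_exact_ratios(self):
        w = ls.WeightVector(("a", "b", "c"), np.array([0.5, 0.3, 0.2]))
        m = ls.judgment_from_weights(w)
        assert m.values[0, 1] == pytest.approx(5 / 3, abs=1e-15)
        assert m.values[1, 0] == pytest.approx(3 / 5, abs=1e-15)
        assert (np.diag(m.values) == 1.0).all()

    def test_zero_perturbation_is_consistent(self, main_weights):
        report = ls.consistency(ls.judgment_from_weights(main_weights))
        assert report.cr == pytest.approx(0.0, abs=1e-9)
        assert report.consistent

    def test_recovers_published_main_weights(self, main_weights):
        m = ls.judgment_from_weights(main_weights)
        recovered, lam = ls.principal_eigen(m)
        np.testing.assert_allclose(recovered.weights, main_weights.weights, atol=1e-9)
        assert lam == pytest.approx(3.0, abs=1e-9)

    def test_reciprocity_exact_under_perturbation(self):
        w = ls.WeightVector(("a", "b", "c", "d"), np.full(4, 0.25))
        m = ls.judgment_from_weights(w, perturbation=0.3, seed=7)
        np.testing.assert_allclose(m.values * m.values.T, 1.0, rtol=0, atol=1e-15)

    def test_determinism(self, main_weights):
        m1 = ls.judgment_from_weights(main_weights, perturbation=0.1, seed=3)
        m2 = ls.judgment_from_weights(main_weights, perturbation=0.1, seed=3)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_zero_weight_rejected(self):
        w = ls.WeightVector(("a", "b"), np.array([1.0, 0.0]))
        with pytest.raises(ValidationError):
            ls.judgment_from_weights(w)


class TestPrincipalEigen:
    def test_2x2_closed_form(self):
        m = ls.JudgmentMatrix(("a", "b"), np.array([[1.0, 2.0], [0.5, 1.0]]))
        w, lam = ls.principal_eigen(m)
        np.testing.assert_allclose(w.weights, [2 / 3, 1 / 3], atol=1e-12)
        assert lam == pytest.approx(2.0, abs=1e-12)

    def test_consistent_3x3(self):
        w, lam = ls.principal_eigen(CONSISTENT_3)
        np.testing.assert_allclose(w.weights, [4 / 7, 2 / 7, 1 / 7], atol=1e-12)
        assert lam == pytest.approx(3.0, abs=1e-12)
        # independent oracle: root of the characteristic polynomial
        roots = np.roots(np.poly(CONSISTENT_3.values))
        assert lam == pytest.approx(max(roots.real), abs=1e-9)

    def test_inconsistent_exceeds_order(self):
        _, lam = ls.principal_eigen(INCONSISTENT_3)
        oracle_w, oracle_lam = dense_principal(INCONSISTENT_3.values)
        assert lam > 3.0
        assert lam == pytest.approx(oracle_lam, abs=1e-8)

    @pytest.mark.parametrize("n", range(3, 11))
    def test_oracle_equivalence(self, n, rng):
        base = ls.WeightVector(
            tuple(f"c{i}" for i in range(n)),
            np.sort(rng.dirichlet(np.ones(n)))[::-1],
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SaatyScaleWarning)
            m = ls.judgment_from_weights(base, perturbation=0.15, seed=n)
        w, lam = ls.principal_eigen(m)
        oracle_w, oracle_lam = dense_principal(m.values)
        assert lam == pytest.approx(oracle_lam, abs=1e-8)
        np.testing.assert_allclose(w.weights, oracle_w, atol=1e-8)
        assert lam >= n - 1e-12

    def test_nonconvergence_raises(self):
        with pytest.raises(ls.NumericError):
            ls.principal_eigen(INCONSISTENT_3, tol=1e-15, max_iter=2)

    def test_geometric_mean_agrees_on_consistent(self):
        gm = geometric_mean_weights(CONSISTENT_3)
        pe, _ = ls.principal_eigen(CONSISTENT_3)
        np.testing.assert_allclose(gm.weights, pe.weights, atol=1e-12)


class TestConsistency:
    def test_ri_table_values(self):
        assert RI_TABLE[3] == 0.58
        assert RI_TABLE[10] == 1.49

    def test_any_2x2_consistent(self):
        m = ls.JudgmentMatrix(("a", "b"), np.array([[1.0, 7.0], [1 / 7, 1.0]]))
        report = ls.consistency(m)
        assert report.cr == 0.0 and report.consistent

    def test_inconsistent_cr_positive(self):
        report = ls.consistency(INCONSISTENT_3)
        _, oracle_lam = dense_principal(INCONSISTENT_3.values)
        assert report.cr == pytest.approx((oracle_lam - 3) / 2 / 0.58, abs=1e-8)
        assert report.cr > 0.1 and not report.consistent

    def test_order_limit(self):
        w = ls.WeightVector(tuple(f"c{i}" for i in range(11)), np.full(11, 1 / 11))
        m = ls.judgment_from_weights(w)
        with pytest.raises(UnsupportedOrderError):
            ls.consistency(m)
        # extendable via a caller-supplied table
        table = {**RI_TABLE, 11: 1.51}
        assert ls.consistency(m, ri_table=table).cr == pytest.approx(0.0, abs=1e-9)


class TestHierarchicalWeights:
    def test_uniform_product_rule(self):
        top = ls.judgment_from_weights(
            ls.WeightVector(("S1", "S2", "S3"), np.full(3, 1 / 3))
        )
        groups = {
            "S1": ls.judgment_from_weights(
                ls.WeightVector(tuple(f"S1{i}" for i in range(6)), np.full(6, 1 / 6))
            ),
            "S2": ls.judgment_from_weights(
                ls.WeightVector(tuple(f"S2{i}" for i in range(6)), np.full(6, 1 / 6))
            ),
            "S3": ls.judgment_from_weights(
                ls.WeightVector(tuple(f"S3{i}" for i in range(5)), np.full(5, 1 / 5))
            ),
        }
        _, global_w = ls.hierarchical_weights(top, groups)
        expected = {**{f"S1{i}": 1 / 18 for i in range(6)},
                    **{f"S2{i}": 1 / 18 for i in range(6)},
                    **{f"S3{i}": 1 / 15 for i in range(5)}}
        assert global_w.as_dict() == pytest.approx(expected, abs=1e-12)

    def test_published_rank_structure(self, registry, main_weights, global_weights):
        top = ls.judgment_from_weights(main_weights)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SaatyScaleWarning)
            groups = {
                g: ls.judgment_from_weights(
                    global_weights.subset(registry.group_ids(g))
                )
                for g in registry.groups
            }
        main, global_w = ls.hierarchical_weights(top, groups)
        np.testing.assert_allclose(main.weights, main_weights.weights, atol=1e-9)
        assert global_w.weights.sum() == pytest.approx(1.0, abs=1e-9)
        gw = global_w.as_dict()
        assert max(gw, key=gw.get) == "S31"
        assert min(gw, key=gw.get) == "S26"
        # within-group ordering matches the published within-group ordering
        for g in registry.groups:
            ids = registry.group_ids(g)
            published = global_weights.subset(ids).weights
            derived = np.array([gw[i] for i in ids])
            assert list(np.argsort(published)) == list(np.argsort(derived))

    def test_inconsistent_matrix_blocks(self):
        top = ls.JudgmentMatrix(
            ("S1", "S2", "S3"), INCONSISTENT_3.values.copy()
        )
        groups = {
            g: ls.judgment_from_weights(ls.WeightVector((f"{g}a", f"{g}b"), np.array([0.5, 0.5])))
            for g in ("S1", "S2", "S3")
        }
        with pytest.raises(ConsistencyError) as excinfo:
            ls.hierarchical_weights(top, groups)
        assert excinfo.value.report.cr > 0.1
        main, global_w = ls.hierarchical_weights(top, groups, force=True)
        assert global_w.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_label_mismatch(self):
        top = ls.judgment_from_weights(
            ls.WeightVector(("S1", "S2"), np.array([0.5, 0.5]))
        )
        with pytest.raises(SchemaError):
            ls.hierarchical_weights(top, {"S1": top})


class TestMatrixIO:
    def test_csv_roundtrip(self, tmp_path, main_weights):
        m = ls.judgment_from_weights(main_weights, perturbation=0.05, seed=1)
        path = tmp_path / "m.csv"
        ls.write_judgment_matrix(m, path)
        back = ls.read_judgment_matrix(path)
        assert back.labels == m.labels
        np.testing.assert_allclose(back.values, m.values, atol=1e-12)

    def test_json_read(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(
            '{"labels": ["a", "b"], "rows": [[1.0, 4.0], [0.25, 1.0]]}'
        )
        m = ls.read_judgment_matrix(path)
        assert m.values[0, 1] == 4.0

    def test_upper_triangular_autocomplete(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",a,b\na,1.0,3.0\nb,,1.0\n")
        m = ls.read_judgment_matrix(path, auto_complete=True)
        assert m.values[1, 0] == pytest.approx(1 / 3, abs=1e-15)
        with pytest.raises(ValidationError):
            ls.read_judgment_matrix(path)
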