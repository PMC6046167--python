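"""Twin SVM: dual solutions vs brute force, distances, OVO voting."""

import numpy as np
import pytest

from afcsp.twsvm import (KernelSpec, OVOTwinModel, TwinPlanePair, fit_binary,
                         fit_ovo, model_from_json, model_to_json,
                         plane_distance, predict, predict_batch)
from afcsp.csp import PairFeatureSet

TOY_I = np.array([[0.0, 0.0], [0.0, 1.0]])
TOY_J = np.array([[2.0, 0.0], [2.0, 1.0]])


def primal_objective_plane1(w, b, A, B, c):
    """0.5||Aw + b||^2 + c * sum max(0, 1 + (Bw + b)) — class-i plane."""
    xi = np.maximum(0.0, 1.0 + (B @ w + b))
    return 0.5 * np.sum((A @ w + b) ** 2) + c * np.sum(xi)


def _grid_min_plane1(A, B, c, thetas, betas, scales):
    best, arg = np.inf, (thetas[0], betas[0], scales[0])
    for theta in thetas:
        wh = np.array([np.cos(theta), np.sin(theta)])
        a_proj = A @ wh
        b_proj = B @ wh
        for beta in betas:
            quad = 0.5 * np.sum(
                (a_proj[:, None] + beta) ** 2, axis=0) * scales ** 2
            hinge = np.maximum(
                0.0, 1.0 + scales[None, :] * (b_proj[:, None] + beta)
            ).sum(axis=0)
            vals = quad + c * hinge
            k = int(np.argmin(vals))
            if vals[k] < best:
                best, arg = float(vals[k]), (theta, beta, float(scales[k]))
    return best, arg


def brute_force_plane1(A, B, c):
    """Exhaustive grid over plane angle, offset and scale, with two
    refinement passes around the coarse argmin."""
    thetas = np.linspace(0, 2 * np.pi, 240, endpoint=False)
    betas = np.linspace(-4.0, 4.0, 81)
    scales = np.geomspace(1e-3, 10.0, 100)
    best, (t0, b0, s0) = _grid_min_plane1(A, B, c, thetas, betas, scales)
    dt, db = 2 * np.pi / 240, 8.0 / 80
    for _ in range(3):
        thetas = np.linspace(t0 - dt, t0 + dt, 41)
        betas = np.linspace(b0 - db, b0 + db, 41)
        scales = np.geomspace(max(s0 / 3, 1e-5), s0 * 3, 81)
        val, (t0, b0, s0) = _grid_min_plane1(A, B, c, thetas, betas, scales)
        best = min(best, val)
        dt /= 15
        db /= 15
    return best


class TestBinaryFit:
    def test_toy_planes_land_on_classes(self):
        p = fit_binary(TOY_I, TOY_J, 1.0, 1.0, KernelSpec("linear"))
        for x in TOY_I:
            assert plane_distance(x, p, "i") < 1e-3
            assert plane_distance(x, p, "j") == pytest.approx(2.0, abs=1e-3)
        for x in TOY_J:
            assert plane_distance(x, p, "j") < 1e-3
            assert plane_distance(x, p, "i") == pytest.approx(2.0, abs=1e-3)

    @pytest.mark.parametrize("seed,c", [(0, 1.0), (1, 0.3), (2, 3.0)])
    def test_primal_objective_matches_brute_force(self, seed, c):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 2))
        B = rng.normal(size=(3, 2)) + np.array([2.5, 0.0])
        p = fit_binary(A, B, c, c, KernelSpec("linear"))
        ours = primal_objective_plane1(p.w_i, p.b_i, A, B, c)
        brute = brute_force_plane1(A, B, c)
        assert ours <= brute * 1.01 + 1e-9
        assert ours >= brute * 0.9  # brute grid cannot beat us by much

    def test_duplication_symmetry(self):
        p1 = fit_binary(TOY_I, TOY_J, 1.0, 1.0, KernelSpec("linear"))
        p2 = fit_binary(np.vstack([TOY_I, TOY_I]), np.vstack([TOY_J, TOY_J]),
                        1.0, 1.0, KernelSpec("linear"))
        x = np.array([0.7, 0.3])
        for side in "ij":
            assert plane_distance(x, p1, side) == pytest.approx(
                plane_distance(x, p2, side), abs=1e-3)

    def test_dual_feasibility(self):
        p = fit_binary(TOY_I, TOY_J, 0.7, 1.3, KernelSpec("linear"))
        assert np.all(p.alpha_i >= -1e-6) and np.all(p.alpha_i <= 0.7 + 1e-6)
        assert np.all(p.alpha_j >= -1e-6) and np.all(p.alpha_j <= 1.3 + 1e-6)

    def test_rbf_small_width_identity_limit(self):
        """Width -> 0 drives the Gram matrix to identity; the toy still
        separates perfectly on its training points."""
        k = KernelSpec("rbf", 0.01)
        K = k.apply(np.vstack([TOY_I, TOY_J]), np.vstack([TOY_I, TOY_J]))
        np.testing.assert_allclose(K, np.eye(4), atol=1e-10)
        p = fit_binary(TOY_I, TOY_J, 1.0, 1.0, k)
        for x in TOY_I:
            assert plane_distance(x, p, "i") < plane_distance(x, p, "j")
        for x in TOY_J:
            assert plane_distance(x, p, "j") < plane_distance(x, p, "i")

    def test_increasing_c1_shrinks_margin_violations(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 2))
        B = rng.normal(size=(6, 2)) + 0.5  # heavy overlap
        viol = []
        for c1 in (0.01, 0.1, 1.0, 10.0):
            p = fit_binary(A, B, c1, 1.0, KernelSpec("linear"))
            viol.append(np.maximum(0, 1 + (B @ p.w_i + p.b_i)).sum())
        assert all(a >= b - 1e-6 for a, b in zip(viol, viol[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="nonempty"):
            fit_binary(np.empty((0, 2)), TOY_J, 1.0, 1.0)
        with pytest.raises(ValueError, match="positive"):
            fit_binary(TOY_I, TOY_J, 0.0, 1.0)
        with pytest.raises(ValueError, match="kernel"):
            KernelSpec("poly")

    def test_degenerate_duplicate_classes_flagged(self):
        p = fit_binary(TOY_I, TOY_I.copy(), 1.0, 1.0, KernelSpec("linear"))
        assert p.degenerate


class TestPlaneDistance:
    def test_point_on_plane_and_geometry(self):
        pair = TwinPlanePair("a", "b", w_i=np.array([1.0, 0.0]), b_i=0.0,
                             w_j=np.array([5.0, 0.0]), b_j=-10.0,
                             kernel=KernelSpec("linear"))
        assert plane_distance(np.array([0.0, 7.0]), pair, "i") == 0.0
        assert plane_distance(np.array([3.0, 0.0]), pair, "i") == 3.0
        # (w, b) scaled by 5 leaves the distance unchanged
        assert plane_distance(np.array([3.0, 0.0]), pair, "j") == \
            pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        pair = TwinPlanePair("a", "b", w_i=np.zeros(2), b_i=1.0,
                             w_j=np.ones(2), b_j=0.0,
                             kernel=KernelSpec("linear"))
        with pytest.raises(ValueError, match="zero-norm"):
            plane_distance(np.zeros(2), pair, "i")


def three_class_features(seed=0, n=12, spread=0.25):
    """Well-separated 2-D clusters for each OVO pair feature space."""
    rng = np.random.default_rng(seed)
    centers = {"flexion": (0, 0), "extension": (3, 0), "abduction": (0, 3)}
    feats = {}
    from afcsp.csp import PAIRS
    for pid, (a, b) in PAIRS.items():
        pts, labs = [], []
        for cls in (a, b):
            pts.append(rng.normal(scale=spread, size=(n, 2)) + centers[cls])
            labs += [cls] * n
        feats[pid] = PairFeatureSet(np.vstack(pts), labs, pid)
    return feats, centers


class TestOVO:
    def test_structure_and_training_accuracy(self):
        feats, centers = three_class_features()
        model = fit_ovo(feats, 1.0, 1.0, KernelSpec("linear"))
        assert len(model.pairs) == 3
        for pid, fs in feats.items():
            batch = {p: None for p in model.pairs}
            preds = predict_batch(
                {p: fs.vectors for p in model.pairs}, model)
        # every training point classified correctly through full voting
        for cls, c in centers.items():
            x = np.array(c, dtype=float)
            label, votes = predict({p: x for p in model.pairs}, model)
            assert label == cls
            assert votes[cls] == 2

    def test_vote_walkthrough_2_1_0(self):
        """A class-1 point wins two subclassifiers: votes (2,1,0)."""
        feats, _ = three_class_features()
        model = fit_ovo(feats, 1.0, 1.0, KernelSpec("linear"))
        x = np.array([0.0, 0.0])  # flexion centre
        label, votes = predict({p: x for p in model.pairs}, model)
        assert label == "flexion"
        assert sorted(votes.values(), reverse=True) == [2, 1, 0]

    def test_equidistant_tie_breaks_to_lowest_class(self):
        pair_kw = dict(kernel=KernelSpec("linear"))
        pairs = {
            "f1": TwinPlanePair("flexion", "extension",
                                w_i=np.array([1.0, 0]), b_i=-1.0,
                                w_j=np.array([1.0, 0]), b_j=1.0, **pair_kw),
            "f2": TwinPlanePair("flexion", "abduction",
                                w_i=np.array([1.0, 0]), b_i=-1.0,
                                w_j=np.array([1.0, 0]), b_j=1.0, **pair_kw),
            "f3": TwinPlanePair("extension", "abduction",
                                w_i=np.array([1.0, 0]), b_i=-1.0,
                                w_j=np.array([1.0, 0]), b_j=1.0, **pair_kw),
        }
        model = OVOTwinModel(pairs, 1.0, 1.0, KernelSpec("linear"))
        label, votes = predict({p: np.zeros(2) for p in pairs}, model)
        assert label == "flexion"  # lowest class index after full tie

    def test_missing_pair_rejected(self):
        feats, _ = three_class_features()
        del feats["f3"]
        with pytest.raises(ValueError, match="missing pair"):
            fit_ovo(feats, 1.0, 1.0)

    @pytest.mark.parametrize("kind,lam", [("linear", 1.0), ("rbf", 0.8)])
    def test_serialization_round_trip(self, kind, lam):
        feats, _ = three_class_features()
        model = fit_ovo(feats, 0.9, 1.1, KernelSpec(kind, lam))
        back = model_from_json(model_to_json(model))
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=2) * 2
            a, _ = predict({p: x for p in model.pairs}, model)
            b, _ = predict({p: x for p in back.pairs}, back)
            assert a == b
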