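"""Twin support vector machine (TWSVM) with one-vs-one multiclass voting.

A binary TWSVM learns two nonparallel hyperplanes, each fitted close to
one class while the other class is pushed to at least unit distance, via
two small convex QPs.  For classes i (samples A) and j (samples B):

    plane 1:  min_(w1,b1)  1/2 ||A w1 + e b1||^2 + c1 e^T xi
              s.t.  -(B w1 + e b1) + xi >= e,  xi >= 0
    plane 2:  min_(w2,b2)  1/2 ||B w2 + e b2||^2 + c2 e^T xi
              s.t.   (A w2 + e b2) + xi >= e,  xi >= 0

Solved through the standard Wolfe duals: with H = [A e], G = [B e],

    plane 1 dual:  max  e^T a - 1/2 a^T G (H^T H)^-1 G^T a,  0 <= a <= c1
                   [w1; b1] = -(H^T H)^-1 G^T a
    plane 2 dual:  max  e^T g - 1/2 g^T H (G^T G)^-1 H^T g,  0 <= g <= c2
                   [w2; b2] = +(G^T G)^-1 H^T g

For the nonlinear case the planes live in kernel space,
K(x^T, C^T) w + b = 0 with C the stacked training samples of both
classes; A and B above are replaced by K(A, C^T) and K(B, C^T).  The RBF
kernel is parameterised by its width: k(u, v) = exp(-||u-v||^2 / (2 lambda^2)).

Multiclass: one binary TWSVM per class pair; a test point votes for the
class whose hyperplane is nearer in each pair, majority wins, ties broken
by the smallest summed normalised plane distance, then lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from afcsp.csp import PAIRS, PairFeatureSet
from afcsp.synth import CLASSES

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"            # "linear" or "rbf"
    lam: float = 1.0             # RBF width lambda

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and not self.lam > 0:
            raise ValueError("RBF width lambda must be positive")

    def apply(self, U: np.ndarray, V: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            raise ValueError("linear kernel has no Gram map")
        d2 = cdist(np.atleast_2d(U), np.atleast_2d(V), "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.lam ** 2))


@dataclass
class TwinPlanePair:
    """Fitted planes for one class pair (class_i, class_j)."""

    class_i: str
    class_j: str
    w_i: np.ndarray
    b_i: float
    w_j: np.ndarray
    b_j: float
    kernel: KernelSpec
    C: np.ndarray | None = None          # stacked training samples (kernel)
    alpha_i: np.ndarray | None = None    # duals, kept for diagnostics
    alpha_j: np.ndarray | None = None
    degenerate: bool = False             # identical class sample multisets

    def _norm(self, w: np.ndarray) -> float:
        if self.kernel.kind == "linear":
            return float(np.linalg.norm(w))
        K = self.kernel.apply(self.C, self.C)
        return float(np.sqrt(max(w @ K @ w, 0.0)))

    def _raw(self, x: np.ndarray, w: np.ndarray, b: float) -> float:
        if self.kernel.kind == "linear":
            return float(x @ w + b)
        return float(self.kernel.apply(x[None, :], self.C)[0] @ w + b)


def _solve_box_qp(M: np.ndarray, ub: float) -> np.ndarray:
    """min 1/2 a^T M a - e^T a  subject to  0 <= a <= ub.

    M is symmetric PSD and small (one row per sample of one class), so a
    bound-constrained quasi-Newton solve is accurate and deterministic.
    """
    n = M.shape[0]
    e = np.ones(n)
    x0 = np.full(n, min(ub, 1.0) / 2.0)
    res = minimize(
        lambda a: 0.5 * a @ M @ a - e @ a,
        x0,
        jac=lambda a: M @ a - e,
        bounds=[(0.0, ub)] * n,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    if not (res.success or res.status == 0):
        # L-BFGS-B occasionally reports precision-loss on flat objectives;
        # accept only if the projected gradient is genuinely small
        pg = np.where((res.x <= 0) | (res.x >= ub), 0.0, M @ res.x - e)
        if np.max(np.abs(pg)) > 1e-4:
            raise RuntimeError(f"TWSVM dual QP failed: {res.message}")
    return np.clip(res.x, 0.0, ub)


def fit_binary(A_i: np.ndarray, A_j: np.ndarray, c1: float, c2: float,
               kernel: KernelSpec = KernelSpec("linear"),
               labels: tuple[str, str] = ("", ""),
               ridge: float = 1e-7) -> TwinPlanePair:
    """Fit the two planes for one class pair by solving the paired duals."""
    A_i = np.atleast_2d(np.asarray(A_i, dtype=float))
    A_j = np.atleast_2d(np.asarray(A_j, dtype=float))
    if len(A_i) == 0 or len(A_j) == 0:
        raise ValueError("both classes must be nonempty")
    if not (c1 > 0 and c2 > 0):
        raise ValueError("penalties c1, c2 must be positive")
    C = np.vstack([A_i, A_j])
    if kernel.kind == "linear":
        Phi_i, Phi_j = A_i, A_j
        C_ref = None
    else:
        Phi_i = kernel.apply(A_i, C)
        Phi_j = kernel.apply(A_j, C)
        C_ref = C
    H = np.hstack([Phi_i, np.ones((len(Phi_i), 1))])
    G = np.hstack([Phi_j, np.ones((len(Phi_j), 1))])

    def plane(S, T, ub, sign):
        # min-norm plane for S-rows with T-rows as margin constraints
        StS = S.T @ S
        StS = StS + ridge * np.trace(StS) * np.eye(StS.shape[0])
        cf = cho_factor(StS)
        M = T @ cho_solve(cf, T.T)
        M = 0.5 * (M + M.T)
        a = _solve_box_qp(M, ub)
        u = sign * cho_solve(cf, T.T @ a)
        return u[:-1], float(u[-1]), a

    w_i, b_i, alpha_i = plane(H, G, c1, -1.0)
    w_j, b_j, alpha_j = plane(G, H, c2, +1.0)
    degenerate = A_i.shape == A_j.shape and bool(
        np.allclose(np.sort(A_i, axis=0), np.sort(A_j, axis=0)))
    return TwinPlanePair(class_i=labels[0], class_j=labels[1],
                         w_i=w_i, b_i=b_i, w_j=w_j, b_j=b_j,
                         kernel=kernel, C=C_ref,
                         alpha_i=alpha_i, alpha_j=alpha_j,
                         degenerate=degenerate)


def plane_distance(x: np.ndarray, pair: TwinPlanePair, side: str) -> float:
    """Perpendicular distance |w . phi(x) + b| / ||w|| to one plane.

    In the kernel case ||w|| is taken in the reproducing feature space,
    ||w||^2 = w^T K(C, C^T) w.
    """
    if side not in ("i", "j"):
        raise ValueError("side must be 'i' or 'j'")
    x = np.asarray(x, dtype=float)
    w, b = (pair.w_i, pair.b_i) if side == "i" else (pair.w_j, pair.b_j)
    norm = pair._norm(w)
    if norm <= 1e-300:
        raise ValueError(f"plane {side} has zero-norm normal vector")
    return abs(pair._raw(x, w, b)) / norm


@dataclass
class OVOTwinModel:
    """Three binary TWSVMs under the shared-penalty convention.

    The six per-subclassifier penalties collapse to two: c1 for every
    'own-class' plane and c2 for every opposite plane.
    """

    pairs: dict[str, TwinPlanePair]
    c1: float
    c2: float
    kernel: KernelSpec

    def __post_init__(self) -> None:
        if set(self.pairs) != set(PAIRS):
            raise ValueError(f"expected pair ids {sorted(PAIRS)}, "
                             f"got {sorted(self.pairs)}")


def fit_ovo(features: dict[str, PairFeatureSet], c1: float, c2: float,
            kernel: KernelSpec = KernelSpec("rbf", 1.0)) -> OVOTwinModel:
    """Train one TwinPlanePair per one-vs-one pair from CSP feature sets."""
    missing = set(PAIRS) - set(features)
    if missing:
        raise ValueError(f"missing pair feature sets: {sorted(missing)}")
    pairs = {}
    for pid, (a, b) in PAIRS.items():
        fs = features[pid]
        lab = np.asarray(fs.labels)
        A = fs.vectors[lab == a]
        B = fs.vectors[lab == b]
        pairs[pid] = fit_binary(A, B, c1, c2, kernel=kernel, labels=(a, b))
    return OVOTwinModel(pairs=pairs, c1=c1, c2=c2, kernel=kernel)


def predict(x_per_pair: dict[str, np.ndarray], model: OVOTwinModel,
            ) -> tuple[str, dict[str, int]]:
    """Classify one sample given its feature vector in each pair's space.

    Each subclassifier votes for the class whose plane is nearer (exact
    plane-distance ties go to the pair's first class).  Vote ties are
    broken by the smallest summed normalised distance to the candidate's
    planes, then by class order (flexion, extension, abduction).
    """
    votes = {c: 0 for c in CLASSES}
    dist_sum = {c: 0.0 for c in CLASSES}
    for pid, pair in model.pairs.items():
        x = np.asarray(x_per_pair[pid], dtype=float)
        d_i = plane_distance(x, pair, "i")
        d_j = plane_distance(x, pair, "j")
        votes[pair.class_i if d_i <= d_j else pair.class_j] += 1
        dist_sum[pair.class_i] += d_i
        dist_sum[pair.class_j] += d_j
    best = max(votes.values())
    tied = [c for c in CLASSES if votes[c] == best]
    if len(tied) > 1:
        lo = min(dist_sum[c] for c in tied)
        tied = [c for c in tied if dist_sum[c] <= lo + 1e-12]
    return tied[0], votes


def predict_batch(features_per_pair: dict[str, np.ndarray],
                  model: OVOTwinModel) -> list[str]:
    """Vectorised-over-samples OVO prediction (one row per trial)."""
    n = len(next(iter(features_per_pair.values())))
    out = []
    for k in range(n):
        label, _ = predict({pid: features_per_pair[pid][k]
                            for pid in model.pairs}, model)
        out.append(label)
    return out


# ----------------------------- serialization -----------------------------

def model_to_json(model: OVOTwinModel) -> str:
    def pair_dict(p: TwinPlanePair):
        return {
            "class_i": p.class_i, "class_j": p.class_j,
            "w_i": p.w_i.tolist(), "b_i": p.b_i,
            "w_j": p.w_j.tolist(), "b_j": p.b_j,
            "C": None if p.C is None else p.C.tolist(),
            "degenerate": p.degenerate,
        }
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "c1": model.c1, "c2": model.c2,
        "kernel": {"kind": model.kernel.kind, "lam": model.kernel.lam},
        "pairs": {pid: pair_dict(p) for pid, p in model.pairs.items()},
    }
    return json.dumps(doc, indent=1)


def model_from_json(text: str) -> OVOTwinModel:
    doc = json.loads(text)
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {doc.get('format_version')}")
    kernel = KernelSpec(doc["kernel"]["kind"], doc["kernel"]["lam"])
    pairs = {}
    for pid, d in doc["pairs"].items():
        pairs[pid] = TwinPlanePair(
            class_i=d["class_i"], class_j=d["class_j"],
            w_i=np.array(d["w_i"]), b_i=float(d["b_i"]),
            w_j=np.array(d["w_j"]), b_j=float(d["b_j"]),
            kernel=kernel,
            C=None if d["C"] is None else np.array(d["C"]),
            degenerate=bool(d["degenerate"]))
    return OVOTwinModel(pairs=pairs, c1=doc["c1"], c2=doc["c2"], kernel=kernel)
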