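"""Common spatial pattern filtering of AF matrices (AF-CSP).

CSP finds a projection W that simultaneously diagonalises the two class
covariances so the leading filters maximise variance for one class while
minimising it for the other.  Here the "signals" are 8 x M
amplitude-frequency matrices rather than raw time series; everything else
is the classical two-class recipe:

    R     = X X^T / trace(X X^T)                 (per-trial, trace 1)
    R_l   = mean over class-l trials of R        (class covariance)
    R_C   = R_l + R_r = U_C A_C U_C^T            (composite eigendecomposition)
    P     = A_C^{-1/2} U_C^T                     (whitening: P R_C P^T = I)
    S_j   = P R_l P^T = B A B^T                  (shared eigenvectors with S_k)
    W     = B^T P                                (rows = spatial filters)

Eigenvalues of S_j and S_k pair to lambda_j + lambda_k = 1.  Rows of W are
ordered by descending eigenvalue of S_j; with m filters kept per side the
feature vector for a trial X is

    f_p = log( var(Z_p) / sum_i var(Z_i) ),   Z = W X,

over the 2m retained rows (first m and last m), giving 4-D features for
m = 2.  One filter is fitted per one-vs-one class pair:
f1 = (flexion, extension), f2 = (flexion, abduction),
f3 = (extension, abduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from afcsp.emd_af import AFMatrix

#: one-vs-one pair ids in the order the pairwise features are defined
PAIR_IDS: tuple[str, ...] = ("f1", "f2", "f3")
PAIRS: dict[str, tuple[str, str]] = {
    "f1": ("flexion", "extension"),
    "f2": ("flexion", "abduction"),
    "f3": ("extension", "abduction"),
}


@dataclass
class SpatialFilter:
    W: np.ndarray                     # N x N, rows = filters
    m: int
    pair: tuple[str, str]
    selected_rows: np.ndarray         # first m and last m indices
    eigenvalues: np.ndarray           # of S_j, descending
    degenerate: bool = False          # R_l ~= R_r: no discriminative filter


@dataclass
class PairFeatureSet:
    vectors: np.ndarray               # n x 2m
    labels: list[str]
    pair_id: str


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, AFMatrix) else np.asarray(X, dtype=float)


def normalized_covariance(X) -> np.ndarray:
    """Trace-normalised covariance R = X X^T / trace(X X^T)."""
    A = _as_array(X)
    C = A @ A.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("covariance undefined for an all-zero matrix")
    return C / tr


def class_covariance(trials: list, label: str) -> np.ndarray:
    """Arithmetic mean of per-trial normalised covariances of one class."""
    Rs = [normalized_covariance(t) for t in trials
          if not isinstance(t, AFMatrix) or t.trial_label == label]
    if not Rs:
        raise ValueError(f"no trials of class {label!r}")
    return np.mean(Rs, axis=0)


def fit_csp(R_l: np.ndarray, R_r: np.ndarray, m: int = 2,
            ridge: float = 1e-8,
            pair: tuple[str, str] = ("", "")) -> SpatialFilter:
    """Fit the CSP projection from two class covariances.

    A ridge eps*trace(R)/N is added to each covariance before whitening
    because AF matrices can be rank-deficient.  Row signs are
    canonicalised so each filter's largest-magnitude coefficient is
    positive (eigenvector signs are arbitrary).
    """
    R_l = np.asarray(R_l, dtype=float)
    R_r = np.asarray(R_r, dtype=float)
    n = R_l.shape[0]
    if R_l.shape != (n, n) or R_r.shape != (n, n):
        raise ValueError("class covariances must be square and same size")
    eye = np.eye(n)
    R_l = R_l + ridge * np.trace(R_l) / n * eye
    R_r = R_r + ridge * np.trace(R_r) / n * eye
    R_c = R_l + R_r
    evals, U = np.linalg.eigh(R_c)
    if evals.min() <= 0:
        raise ValueError("composite covariance not positive definite "
                         "after regularization")
    P = np.diag(evals ** -0.5) @ U.T
    S_j = P @ R_l @ P.T
    S_j = 0.5 * (S_j + S_j.T)
    lam, B = np.linalg.eigh(S_j)
    order = np.argsort(lam)[::-1]
    lam, B = lam[order], B[:, order]
    W = B.T @ P
    # canonical signs
    signs = np.sign(W[np.arange(n), np.argmax(np.abs(W), axis=1)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    selected = np.concatenate([np.arange(m), np.arange(n - m, n)])
    degenerate = bool(np.max(np.abs(lam - 0.5)) < 1e-6)
    return SpatialFilter(W=W, m=m, pair=pair, selected_rows=selected,
                         eigenvalues=lam, degenerate=degenerate)


def extract_features(X, filt: SpatialFilter) -> np.ndarray:
    """Log-normalised variances of the retained CSP components (2m-vector)."""
    Z = filt.W @ _as_array(X)
    v = Z.var(axis=1)[filt.selected_rows]
    if np.any(v <= 0):
        raise ValueError("zero-variance CSP component; cannot take log")
    return np.log(v / v.sum())


def fit_pair_filters(train: list[AFMatrix], m: int = 2,
                     ridge: float = 1e-8,
                     pair_ids: tuple[str, ...] = PAIR_IDS,
                     ) -> dict[str, SpatialFilter]:
    """One CSP filter per requested one-vs-one pair, fitted on `train`."""
    labels = {t.trial_label for t in train}
    filters = {}
    for pid in pair_ids:
        a, b = PAIRS[pid]
        if a not in labels or b not in labels:
            raise ValueError(f"pair {pid} needs classes {a!r} and {b!r}; "
                             f"have {sorted(labels)}")
        R_a = class_covariance(train, a)
        R_b = class_covariance(train, b)
        filters[pid] = fit_csp(R_a, R_b, m=m, ridge=ridge, pair=(a, b))
    return filters


def build_ovo_features(train: list[AFMatrix], m: int = 2, ridge: float = 1e-8,
                       filters: dict[str, SpatialFilter] | None = None,
                       pair_ids: tuple[str, ...] = PAIR_IDS,
                       ) -> dict[str, PairFeatureSet]:
    """Pairwise training feature sets {f1, f2, f3}.

    Filters are fitted on `train` unless pre-fitted ones are supplied
    (e.g. to featurise a held-out partition without leakage); each pair's
    set contains only trials of its two classes.
    """
    if filters is None:
        filters = fit_pair_filters(train, m=m, ridge=ridge, pair_ids=pair_ids)
    out = {}
    for pid in pair_ids:
        filt = filters[pid]
        a, b = filt.pair
        members = [t for t in train if t.trial_label in (a, b)]
        vecs = np.array([extract_features(t, filt) for t in members])
        out[pid] = PairFeatureSet(vectors=vecs,
                                  labels=[t.trial_label for t in members],
                                  pair_id=pid)
    return out


def transform_all(afms: list[AFMatrix],
                  filters: dict[str, SpatialFilter]) -> dict[str, np.ndarray]:
    """Features of *every* trial in each pair's CSP space (for prediction)."""
    return {pid: np.array([extract_features(t, filt) for t in afms])
            for pid, filt in filters.items()}
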