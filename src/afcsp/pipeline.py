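"""Cross-validated decoding pipeline and the per-fold feature cache.

The CSP stage depends only on the fold split, never on the classifier
hyperparameters, so when many (c1, c2, lambda) candidates are scored over
the same folds — as NSGA-II does — the expensive EMD + CSP work is done
once per fold and reused.  Filters are always fitted on the training
partition of a fold only; held-out trials are featurised with those
train-fitted filters (no label leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from afcsp import csp as _csp
from afcsp import twsvm as _twsvm
from afcsp.emd_af import AFMatrix, build_af_matrices
from afcsp.evaluation import ConfusionMatrix3, confusion_and_rates, pooled_cr
from afcsp.preprocess import FilterSpec, preprocess_trialset
from afcsp.synth import TrialSet


def trialset_to_afms(ts: TrialSet, spec: FilterSpec | None = None,
                     car_scope: str = "selected4",
                     window: tuple[float, float] = (1.0, 4.0),
                     band: tuple[float, float] = (8.0, 30.0),
                     ) -> list[AFMatrix]:
    """Notch + CAR + EMD + AF-matrix construction for a whole trial set."""
    pre = preprocess_trialset(ts, spec=spec, car_scope=car_scope)
    return build_af_matrices(pre, ts.labels, fs=ts.fs, window=window, band=band)


def make_folds(labels: list[str], n_splits: int = 5, seed: int = 0,
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold index pairs, fixed by `seed` for a whole run."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    y = np.asarray(labels)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class _FoldFeatures:
    train_sets: dict[str, _csp.PairFeatureSet]
    test_features: dict[str, np.ndarray]
    test_labels: list[str]


@dataclass
class CVFeatureCache:
    """Per-fold CSP features, shared by every hyperparameter candidate."""

    afms: list[AFMatrix]
    folds: list[tuple[np.ndarray, np.ndarray]]
    m: int = 2
    ridge: float = 1e-8
    _fold_features: list[_FoldFeatures] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [a.trial_label for a in self.afms]
        for tr, te in self.folds:
            train = [self.afms[i] for i in tr]
            filters = _csp.fit_pair_filters(train, m=self.m, ridge=self.ridge)
            train_sets = _csp.build_ovo_features(train, filters=filters)
            test = [self.afms[i] for i in te]
            self._fold_features.append(_FoldFeatures(
                train_sets=train_sets,
                test_features=_csp.transform_all(test, filters),
                test_labels=[labels[i] for i in te]))

    def score(self, c1: float, c2: float, kernel: _twsvm.KernelSpec,
              ) -> tuple[float, float, float, float, list[ConfusionMatrix3]]:
        """Pooled 5-fold (CRF, CRE, CRA, CR) for one hyperparameter triple."""
        cms = []
        for k, ff in enumerate(self._fold_features):
            try:
                model = _twsvm.fit_ovo(ff.train_sets, c1, c2, kernel=kernel)
                pred = _twsvm.predict_batch(ff.test_features, model)
            except Exception as exc:  # noqa: BLE001 - annotate the fold
                raise RuntimeError(f"classifier failed on fold {k}: {exc}"
                                   ) from exc
            cm, *_ = confusion_and_rates(ff.test_labels, pred)
            cms.append(cm)
        crf, cre, cra, cr = pooled_cr(cms)
        return crf, cre, cra, cr, cms


def crossval_cr(afms: list[AFMatrix], c1: float, c2: float,
                kernel: _twsvm.KernelSpec, n_splits: int = 5, seed: int = 0,
                ) -> tuple[float, float, float, float]:
    """One-shot pooled CV rates without building a reusable cache."""
    folds = make_folds([a.trial_label for a in afms], n_splits, seed)
    cache = CVFeatureCache(afms=afms, folds=folds)
    return cache.score(c1, c2, kernel)[:4]


def train_full(afms: list[AFMatrix], c1: float, c2: float,
               kernel: _twsvm.KernelSpec, m: int = 2, ridge: float = 1e-8,
               ) -> tuple[dict[str, _csp.SpatialFilter], _twsvm.OVOTwinModel]:
    """Fit CSP filters and the OVO TWSVM on an entire trial set."""
    filters = _csp.fit_pair_filters(afms, m=m, ridge=ridge)
    feats = _csp.build_ovo_features(afms, filters=filters)
    model = _twsvm.fit_ovo(feats, c1, c2, kernel=kernel)
    return filters, model


def evaluate_model(afms: list[AFMatrix],
                   filters: dict[str, _csp.SpatialFilter],
                   model: _twsvm.OVOTwinModel):
    """Predict every trial and return (predictions, confusion, rates)."""
    feats = _csp.transform_all(afms, filters)
    pred = _twsvm.predict_batch(feats, model)
    labels = [a.trial_label for a in afms]
    cm, crf, cre, cra, cr = confusion_and_rates(labels, pred)
    return pred, cm, (crf, cre, cra, cr)
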