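"""Symptom prediction from voxelwise ALFF patterns.

A linear support-vector regression (epsilon-insensitive loss, linear
kernel) maps the voxelwise standardized-ALFF pattern inside the
diagnosis-related clusters to an ADOS subscale score.  Performance is the
Pearson correlation R between observed scores and leave-one-out
cross-validated (LOOCV) predictions; significance comes from a permutation
null in which the scores are shuffled and the entire LOOCV procedure is
repeated, with p = #(R_perm > R) / n_perm (strict inequality).  Bonferroni
control over the three subscales gates significance at 0.05 / 3.

Leakage control: feature standardization statistics (per-column mean/SD)
are computed within each training fold only, never on the held-out subject.
Because the folds do not depend on the target, the per-fold standardized
features and their Gram matrices are precomputed once and reused across all
permutations, which makes the 1000-permutation null affordable.

A study-design caveat applies: the clusters defining the features are
selected on the same subjects that the prediction is evaluated on, so R is
an in-study association strength, not an out-of-sample accuracy claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

try:  # fast path: call the libsvm solver directly inside the hot LOOCV loop
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - fall back to the public estimator
    _libsvm = None

__all__ = [
    "FeatureMatrix",
    "build_feature_matrix",
    "SymptomSVR",
    "SymptomSVRResults",
    "PredictionResult",
    "loocv_svr",
    "permutation_test",
    "bonferroni_gate",
]


@dataclass
class FeatureMatrix:
    """Subjects x voxels ALFF feature matrix with full column provenance."""

    X: np.ndarray
    subject_ids: list[str]
    provenance: list  # (cluster_label, (x, y, z)) per column
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        if self.X.shape[1] != len(self.provenance):
            raise ValueError("provenance must cover every column")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")


def build_feature_matrix(
    alff_stack: np.ndarray,
    mask: np.ndarray,
    cluster_sets: dict,
    phenotypes: pd.DataFrame,
    target: str = "ados_social",
) -> tuple[FeatureMatrix, np.ndarray]:
    """Assemble ASD-subject features from the significant clusters.

    ``alff_stack`` is (n_subjects, n_in-mask voxels) in phenotype row order;
    ``cluster_sets`` maps a cluster label to its (k, 3) voxel coordinates.
    Columns are ordered by (cluster label, lexicographic voxel coordinate),
    which makes the layout deterministic across runs.  ASD subjects missing
    the target score are excluded (counted in ``n_excluded``).
    """
    mask = np.asarray(mask, dtype=bool)
    index_map = -np.ones(mask.shape, dtype=int)
    index_map[mask] = np.arange(mask.sum())
    cols, prov = [], []
    for label in sorted(cluster_sets):
        voxels = np.asarray(cluster_sets[label])
        order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
        for v in voxels[order]:
            j = index_map[tuple(v)]
            if j < 0:
                raise ValueError(f"cluster {label} voxel {tuple(v)} outside the mask")
            cols.append(j)
            prov.append((label, tuple(int(x) for x in v)))
    if not cols:
        raise ValueError("no cluster voxels to build features from")
    is_asd = (phenotypes["diagnosis"] == "ASD").to_numpy()
    scores = phenotypes[target].to_numpy(dtype=float)
    usable = is_asd & np.isfinite(scores)
    n_excluded = int(is_asd.sum() - usable.sum())
    X = alff_stack[np.ix_(usable, cols)]
    ids = list(phenotypes.loc[usable, "subject_id"])
    return FeatureMatrix(X, ids, prov, n_excluded), scores[usable]


# ---------------------------------------------------------------------------
# LOOCV machinery


def _fold_cache(X: np.ndarray, scaling: str):
    """Per-fold standardized training Grams and test kernel rows.

    The folds depend only on X, so this cache is shared by the observed fit
    and every permutation.
    """
    n = X.shape[0]
    cache = []
    for i in range(n):
        tr = np.arange(n) != i
        Xtr, Xte = X[tr], X[i:i + 1]
        if scaling == "fold":
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        elif scaling != "none":
            raise ValueError("scaling must be 'fold' or 'none'")
        cache.append((tr, Xtr @ Xtr.T, Xte @ Xtr.T))
    return cache


def _loocv_from_cache(
    cache, y: np.ndarray, C: float, epsilon: float, tol: float = 1e-3,
    use_fast: bool = True,
) -> np.ndarray:
    """LOOCV predictions from precomputed fold kernels.

    The fast path invokes the libsvm epsilon-SVR solver directly and forms
    predictions from the returned dual coefficients; it is numerically
    identical to fitting :class:`sklearn.svm.SVR` per fold (asserted in the
    test suite) and several times faster, which matters inside the
    1000-permutation null.
    """
    n = len(y)
    pred = np.empty(n)
    if use_fast and _libsvm is not None:
        for i, (tr, Ktr, Kte) in enumerate(cache):
            out = _libsvm.fit(
                Ktr, y[tr], svm_type=3, kernel="precomputed", C=C, epsilon=epsilon,
                tol=tol,
            )
            support, coef, intercept = out[0], out[3], out[4]
            pred[i] = Kte[0, support] @ coef[0] + intercept[0]
        return pred
    svr = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol)
    for i, (tr, Ktr, Kte) in enumerate(cache):
        svr.fit(Ktr, y[tr])
        pred[i] = svr.predict(Kte)[0]
    return pred


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PredictionResult:
    """LOOCV prediction of one subscale with its permutation null."""

    target: str
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    permutation_r: np.ndarray | None = None
    p_perm: float | None = None
    n_perm: int = 0
    bonferroni_alpha: float = 0.05 / 3

    @property
    def significant(self) -> bool | None:
        if self.p_perm is None:
            return None
        return bool(self.p_perm < self.bonferroni_alpha)


class SymptomSVR:
    """Linear-kernel epsilon-SVR of a symptom score on ALFF features.

    Parameters
    ----------
    X, y
        Feature matrix (subjects x voxels) and per-subject scores.
    C, epsilon
        SVR regularization and insensitivity-tube width.  The solver the
        original toolbox lineage used ships no tuned values; the library
        defaults C=1, epsilon=0.1 are kept, fixed and configurable.
    scaling
        "fold" (default): per-column z-scoring with training-fold statistics
        only.  "none": use features as given (for oracle comparisons and the
        leakage demonstration).
    """

    def __init__(self, X, y, C: float = 1.0, epsilon: float = 0.1,
                 scaling: str = "fold", target: str = "", tol: float = 1e-3):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows must match y length")
        if self.X.shape[0] < 3:
            raise ValueError("need at least 3 subjects for LOOCV")
        if np.ptp(self.y) == 0:
            raise ValueError("constant target score: correlation undefined")
        self.C = C
        self.epsilon = epsilon
        self.tol = tol
        self.scaling = scaling
        self.target = target
        self._cache = None

    def _folds(self):
        if self._cache is None:
            self._cache = _fold_cache(self.X, self.scaling)
        return self._cache

    def fit(self) -> "SymptomSVRResults":
        pred = _loocv_from_cache(self._folds(), self.y, self.C, self.epsilon, self.tol)
        return SymptomSVRResults(self, pred, _safe_pearson(pred, self.y))


@dataclass
class SymptomSVRResults:
    model: SymptomSVR
    predicted: np.ndarray
    r: float

    def permutation_test(self, n_perm: int = 1000, seed: int = 0) -> PredictionResult:
        """Shuffle scores, rerun the full LOOCV, and count R_perm > R."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        cache = self.model._folds()
        r_perm = np.empty(n_perm)
        for b in range(n_perm):
            yb = rng.permutation(self.model.y)
            pred = _loocv_from_cache(cache, yb, self.model.C, self.model.epsilon, self.model.tol)
            r_perm[b] = _safe_pearson(pred, yb)
        p = float(np.sum(r_perm > self.r) / n_perm)
        return PredictionResult(
            self.model.target, self.predicted, self.model.y, self.r, r_perm, p, n_perm
        )

    def summary(self) -> str:
        return (
            f"SVR LOOCV [{self.model.target or 'score'}]: n={len(self.predicted)}, "
            f"R(observed, predicted) = {self.r:.3f}"
        )


def loocv_svr(X, y, C: float = 1.0, epsilon: float = 0.1, scaling: str = "fold",
              tol: float = 1e-3) -> np.ndarray:
    """Out-of-fold LOOCV predictions (functional form)."""
    return SymptomSVR(X, y, C=C, epsilon=epsilon, scaling=scaling, tol=tol).fit().predicted


def permutation_test(
    X, y, n_perm: int = 1000, seed: int = 0, C: float = 1.0, epsilon: float = 0.1
) -> tuple[float, np.ndarray]:
    """(p_perm, permutation R distribution) for the LOOCV correlation."""
    res = SymptomSVR(X, y, C=C, epsilon=epsilon).fit().permutation_test(n_perm, seed)
    return res.p_perm, res.permutation_r


def bonferroni_gate(p_values, family_alpha: float = 0.05) -> list[bool]:
    """Significance flags for the three subscales at p < alpha/3 (strict)."""
    p_values = list(p_values)
    if len(p_values) != 3:
        raise ValueError("expected exactly 3 p values (one per ADOS subscale)")
    cut = family_alpha / 3.0
    return [bool(p < cut) for p in p_values]
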