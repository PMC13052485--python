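"""Classical comparators: SVM with three-step feature selection, and a
random forest.

The three-step selector treats every grid point of the spectrum as a
candidate feature and applies, on the training fold only:

1. a variance filter (keep features with variance > 0.03 by default),
2. a correlation filter (keep features whose point-biserial correlation
   with the binary label exceeds 0.9 in absolute value; if none survive, the
   top-k by |r| are kept instead and the fallback is recorded),
3. L1-regularized logistic selection, tightening the regularization until at
   most 10 features carry nonzero weight.

Two literature peak sets are provided as fixed feature alternatives:
phenylalanine / collagen / nucleic-acid / phospholipid bands selected in an
in-vivo prostate study, and tryptophan / collagen / beta-carotene /
phenylalanine-tyrosine bands from an ex-vivo study.  Peak features are the
maximum intensity inside a +-window around each band (a printed range such
as 1307-1310 uses the full interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import Cohort

__all__ = [
    "FeatureSelectionConfig",
    "PeakFeatureSet",
    "PEAKS_IN_VIVO",
    "PEAKS_EX_VIVO",
    "select_features_threestep",
    "extract_peak_features",
    "fit_svm",
    "fit_rf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSelectionConfig:
    variance_threshold: float = 0.03
    correlation_threshold: float = 0.9
    max_features: int = 10
    fallback_top_k: int = 50

    def __post_init__(self) -> None:
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.variance_threshold < 0 or self.correlation_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.fallback_top_k < 1:
            raise ValueError("fallback_top_k must be >= 1")


@dataclass(frozen=True)
class PeakFeatureSet:
    """A named list of Raman bands; entries are single shifts (cm^-1) or
    ``(low, high)`` intervals."""

    name: str
    bands: tuple

    def centers(self) -> list[float]:
        return [
            (b[0] + b[1]) / 2.0 if isinstance(b, tuple) else float(b) for b in self.bands
        ]


#: Bands selected in an in-vivo prostate study: phenylalanine (994, 1007),
#: collagen/DNA/RNA (1334), DNA/RNA/proteins/phospholipids (1766, 1772).
PEAKS_IN_VIVO = PeakFeatureSet("in_vivo", (994.0, 1007.0, 1334.0, 1766.0, 1772.0))

#: Bands from an ex-vivo prostate study: tryptophan (881), collagen
#: (1307-1310), beta-carotene (1396), phenylalanine (1583) and
#: phenylalanine/tyrosine/tryptophan (1602).
PEAKS_EX_VIVO = PeakFeatureSet(
    "ex_vivo", (881.0, (1307.0, 1310.0), 1396.0, 1583.0, 1602.0)
)


def _point_biserial(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| between each feature column and a binary label vector."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.nan_to_num(r, nan=0.0)


def select_features_threestep(
    train_spectra: np.ndarray,
    labels: np.ndarray,
    config: FeatureSelectionConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the three-step selector on a training fold.

    Returns ``(indices, info)`` with at most ``config.max_features`` feature
    indices into the spectrum grid; ``info`` records per-step survivor
    counts and whether the correlation fallback fired.
    """
    config = config or FeatureSelectionConfig()
    x = np.asarray(train_spectra, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("train_spectra must be a 2-D matrix")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")

    info: dict = {}
    variances = x.var(axis=0)
    if np.all(variances == 0):
        raise ValueError("all features are constant; nothing to select")
    step1 = np.flatnonzero(variances > config.variance_threshold)
    if step1.size == 0:
        # The variance gate is data-scale dependent; keep going rather than
        # return nothing, and record that the gate was bypassed.
        logger.info(
            "variance filter (> %g) removed every feature; continuing with all "
            "non-constant features",
            config.variance_threshold,
        )
        step1 = np.flatnonzero(variances > 0)
        info["variance_filter_bypassed"] = True
    info["n_after_variance"] = int(step1.size)

    r = _point_biserial(x[:, step1], y)
    strong = np.abs(r) > config.correlation_threshold
    if strong.any():
        step2 = step1[strong]
        info["correlation_fallback"] = False
    else:
        k = min(config.fallback_top_k, step1.size)
        top = np.argsort(-np.abs(r), kind="stable")[:k]
        step2 = step1[np.sort(top)]
        info["correlation_fallback"] = True
        logger.info(
            "no feature reached |r| > %g; falling back to the top %d by |r|",
            config.correlation_threshold,
            k,
        )
    info["n_after_correlation"] = int(step2.size)

    # Step 3: L1 logistic regression, tightening C until few enough survive.
    sub = StandardScaler().fit_transform(x[:, step2])
    c = 1.0
    chosen = step2
    for _ in range(30):
        lasso = LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", random_state=0, max_iter=2000
        ).fit(sub, y)
        nonzero = np.flatnonzero(np.abs(lasso.coef_[0]) > 1e-10)
        if 0 < nonzero.size <= config.max_features:
            chosen = step2[nonzero]
            break
        if nonzero.size == 0:
            # Over-regularized: keep the strongest-|r| survivors instead.
            order = np.argsort(-np.abs(_point_biserial(x[:, step2], y)), kind="stable")
            chosen = step2[np.sort(order[: config.max_features])]
            break
        c /= 2.0
    else:
        order = np.argsort(-np.abs(lasso.coef_[0]), kind="stable")
        chosen = step2[np.sort(order[: config.max_features])]
    info["n_selected"] = int(chosen.size)
    return np.sort(chosen), info


def extract_peak_features(
    cohort_or_matrix,
    peaks: PeakFeatureSet,
    window: float = 4.0,
    wavenumbers: np.ndarray | None = None,
) -> np.ndarray:
    """Per-band features: maximum intensity within ``+-window`` cm^-1 of the
    band (an interval band uses ``[low - window, high + window]``).

    Accepts a :class:`Cohort` or an intensity matrix plus its grid.
    """
    if isinstance(cohort_or_matrix, Cohort):
        x = cohort_or_matrix.intensity_matrix()
        wn = cohort_or_matrix.wavenumbers
    else:
        if wavenumbers is None:
            raise ValueError("wavenumbers required when passing a matrix")
        x = np.asarray(cohort_or_matrix, dtype=float)
        wn = np.asarray(wavenumbers, dtype=float)
    if window < 0:
        raise ValueError("window must be >= 0")

    cols = []
    for band in peaks.bands:
        lo, hi = (band if isinstance(band, tuple) else (band, band))
        if lo < wn[0] or hi > wn[-1]:
            raise ValueError(f"band {band} cm^-1 outside grid range [{wn[0]}, {wn[-1]}]")
        mask = (wn >= lo - window) & (wn <= hi + window)
        if not mask.any():
            # window = 0 with an off-grid centre: use the nearest grid point
            mask = np.zeros_like(wn, dtype=bool)
            mask[int(np.argmin(np.abs(wn - (lo + hi) / 2)))] = True
        cols.append(x[:, mask].max(axis=1))
    return np.column_stack(cols)


def fit_svm(
    features: np.ndarray,
    labels: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    seed: int = 0,
) -> Pipeline:
    """Standardized-feature SVM; ``decision_function`` provides the
    continuous score used for AUC."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("SVM training data must contain both classes")
    model = Pipeline(
        [
            ("scaler", StandardScaler()),
            ("svc", SVC(kernel=kernel, C=C, random_state=seed)),
        ]
    )
    return model.fit(np.asarray(features, dtype=float), y)


def fit_rf(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> RandomForestClassifier:
    """Random forest: 100 trees, depth <= 5, all features at each split, no
    class weighting."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("random-forest training data must contain both classes")
    model = RandomForestClassifier(
        n_estimators=100,
        max_depth=5,
        max_features=None,
        class_weight=None,
        random_state=seed,
    )
    return model.fit(np.asarray(features, dtype=float), y)
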