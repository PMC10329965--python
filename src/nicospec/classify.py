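"""Hyperaccumulator-vs-normal classification from baseline-subtracted spectra.

Pipeline: subtract each spectrum's reflectance at 1350 nm, feed all
channels into a random forest (default 100 trees) after a stratified 75/25
train/validation split, then read off validation accuracy and per-channel
impurity importance, summarised as the shortest wavelength interval holding
half the total importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .grid import WavelengthGrid
from .io import SpectraSet
from .preprocess import BASELINE_REF_NM, baseline_subtract_set, hyperaccumulator_label

LABEL_HYPER = "hyper"
LABEL_NORMAL = "normal"


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split settings."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must be in (0,1), got {self.train_fraction}"
            )


@dataclass
class ClassifierReport:
    """Validation results of the spectral random forest."""

    validation_accuracy: float
    confusion: dict[str, int]
    importance: np.ndarray
    dominant_region: tuple[float, float]
    n_trees: int
    seed: int
    grid: WavelengthGrid
    n_train: int
    n_validation: int
    hyperparameters: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "validation_accuracy": self.validation_accuracy,
            "confusion": self.confusion,
            "dominant_region_nm": list(self.dominant_region),
            "n_trees": self.n_trees,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "grid": {
                "start": self.grid.start,
                "stop": self.grid.stop,
                "step": self.grid.step,
            },
            "hyperparameters": self.hyperparameters,
        }


def prepare_features(
    spectra: SpectraSet,
    meta: pd.DataFrame,
    label_from: Literal["threshold", "meta"] = "threshold",
    ref_wavelength: float = BASELINE_REF_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted full-channel feature matrix plus class labels.

    Labels come from the Ni hyperaccumulation threshold applied to
    ``ni_conc`` (default) or from the metadata ``group`` column.
    """
    wl = spectra.grid.wavelengths
    if not wl[0] <= ref_wavelength <= wl[-1]:
        raise ValueError(
            f"grid [{wl[0]}, {wl[-1]}] nm does not contain the "
            f"{ref_wavelength} nm baseline reference"
        )
    features = baseline_subtract_set(spectra, ref_wavelength).values
    by_id = meta.set_index("sample_id")
    if label_from == "threshold":
        labels = np.array(
            [
                LABEL_HYPER
                if hyperaccumulator_label(float(by_id.loc[sid, "ni_conc"]))
                else LABEL_NORMAL
                for sid in spectra.sample_ids
            ]
        )
    elif label_from == "meta":
        labels = by_id.loc[spectra.sample_ids, "group"].to_numpy(dtype=object)
        labels = labels.astype(str)
    else:
        raise ValueError(f"label_from must be 'threshold' or 'meta', got {label_from!r}")
    return features, labels


def split_dataset(
    features: np.ndarray, labels: np.ndarray, spec: SplitSpec | None = None
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive train/validation partition, seeded.

    Stratified by class when ``spec.stratified``; raises if any class is
    absent from the training portion.
    """
    spec = spec or SplitSpec()
    n = len(labels)
    if n < 4:
        raise ValueError(f"need >= 4 samples to split, got {n}")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present before splitting")
    X_tr, X_va, y_tr, y_va = train_test_split(
        features,
        labels,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=labels if spec.stratified else None,
        shuffle=True,
    )
    if len(np.unique(y_tr)) < len(np.unique(labels)):
        raise ValueError(
            "a class is absent from the training set after splitting; "
            "use a stratified split or more samples"
        )
    return (X_tr, y_tr), (X_va, y_va)


def train_and_evaluate(
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    grid: WavelengthGrid,
    n_trees: int = 100,
    seed: int = 0,
    importance_mode: Literal["impurity", "permutation"] = "impurity",
) -> ClassifierReport:
    """Fit the tree ensemble and report accuracy, confusion and importance.

    Importance is impurity-based (mean decrease), normalised to sum to 1;
    permutation importance (on the validation set) is available behind
    ``importance_mode``. All other tree hyperparameters are the library
    defaults and are echoed into the report.
    """
    X_tr, y_tr = train
    X_va, y_va = validation
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set holds a single class; cannot fit")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X_tr, y_tr)
    y_hat = clf.predict(X_va)
    acc = float(np.mean(y_hat == y_va))

    classes = sorted(np.unique(np.concatenate([y_tr, y_va])).tolist())
    cm = confusion_matrix(y_va, y_hat, labels=classes)
    confusion = {
        f"true_{t}_pred_{p}": int(cm[i, j])
        for i, t in enumerate(classes)
        for j, p in enumerate(classes)
    }

    if importance_mode == "impurity":
        imp = clf.feature_importances_.astype(float)
    elif importance_mode == "permutation":
        res = permutation_importance(
            clf, X_va, y_va, n_repeats=5, random_state=seed
        )
        imp = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance_mode {importance_mode!r}")
    total = imp.sum()
    if total > 0:
        imp = imp / total

    region = dominant_importance_region(imp, grid)
    return ClassifierReport(
        validation_accuracy=acc,
        confusion=confusion,
        importance=imp,
        dominant_region=region,
        n_trees=n_trees,
        seed=seed,
        grid=grid,
        n_train=len(y_tr),
        n_validation=len(y_va),
        hyperparameters={k: v for k, v in clf.get_params().items()},
    )


def dominant_importance_region(
    importance: np.ndarray,
    grid: WavelengthGrid,
    window_nm: float = 100.0,
    coverage: float = 0.5,
) -> tuple[float, float]:
    """Shortest contiguous wavelength interval holding >= ``coverage`` of importance.

    Found by a two-pointer sweep over channels, then widened outward to
    whole multiples of ``window_nm`` from the grid start (and clamped to
    the grid range), so the report reads in round wavelength blocks.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0,1], got {coverage}")
    imp = np.asarray(importance, dtype=float)
    if imp.shape != (grid.n_channels,):
        raise ValueError("importance vector does not match the grid")
    total = imp.sum()
    if total <= 0:
        raise ValueError("importance sums to zero; region undefined")
    # tiny slack so coverage=1.0 survives sequential-summation rounding
    target = coverage * total - 1e-12 * total
    wl = grid.wavelengths

    best: tuple[float, int, int] | None = None  # (span, lo, hi)
    lo = 0
    acc = 0.0
    for hi in range(imp.size):
        acc += imp[hi]
        while acc - imp[lo] >= target and lo < hi:
            acc -= imp[lo]
            lo += 1
        if acc >= target:
            span = wl[hi] - wl[lo]
            if best is None or span < best[0]:
                best = (span, lo, hi)
    assert best is not None  # coverage <= 1 guarantees a window
    _, lo, hi = best
    low_nm = grid.start + np.floor((wl[lo] - grid.start) / window_nm) * window_nm
    high_nm = grid.start + np.ceil((wl[hi] - grid.start) / window_nm) * window_nm
    if high_nm == low_nm:
        high_nm = low_nm + window_nm
    return (float(max(low_nm, grid.start)), float(min(high_nm, grid.stop)))
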