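"""Dual-readout siRNA screen scoring: classifier probability + tubulation index.

Each siRNA condition is scored two ways: (1) the arithmetic mean, over its
images, of a trained classifier's probability that the image shows the
knockout phenotype; (2) the tubulation index of its tubule density, rescaled
between same-experiment wild-type (1) and knockout (0) means.  Conditions
are gated against positive-control siRNAs targeting the gene itself: by
default a candidate must reach at least the *minimal* effect among the
positive controls on each readout (the dashed-line rule; the stricter
all-controls rule is available), and a hit must pass both gates.

The classifier is a pluggable interface.  The built-in desk-scale backend
fits a regularized logistic regression on per-image morphometry features
(particle counts, tubule density, shape-metric summaries); a convolutional
backend can be plugged in through the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import detection, morphometry

__all__ = [
    "SplitSpec",
    "SplitCounts",
    "ScreenRecord",
    "GateThresholds",
    "FeatureClassifier",
    "split_counts",
    "split_indices",
    "extract_features",
    "train_classifier",
    "score_condition",
    "derive_gates",
    "call_hits",
]

FEATURE_NAMES = [
    "n_particles_per_um2",
    "tubules_per_um2",
    "tubular_fraction",
    "mean_circularity",
    "sd_circularity",
    "mean_eccentricity",
    "sd_eccentricity",
    "mean_axis_ratio",
    "mean_area_um2",
    "total_area_fraction",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split sizes for the two labelled classes."""

    n_class_a: int
    n_class_b: int
    test_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class_a <= 0 or self.n_class_b <= 0:
            raise ValueError("class sizes must be positive")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SplitCounts:
    test_a: int
    test_b: int
    train_a: int
    train_b: int


@dataclass(frozen=True)
class ScreenRecord:
    """Scores and gate verdicts of one siRNA condition."""

    condition_id: str
    mean_ko_probability: float
    tubulation_index: float
    passes_nn_gate: bool | None = None
    passes_tub_gate: bool | None = None

    @property
    def is_hit(self) -> bool | None:
        if self.passes_nn_gate is None or self.passes_tub_gate is None:
            return None
        return self.passes_nn_gate and self.passes_tub_gate


@dataclass(frozen=True)
class GateThresholds:
    """Derived gates: thresholds are control statistics, not free parameters."""

    nn_min_probability: float
    tub_max_index: float
    rule: str = "minimal_effect"


def split_counts(spec: SplitSpec) -> SplitCounts:
    """Per-class test counts by ceil(test_fraction × n); the rest train.

    A 15% split of 742 knockout and 735 wild-type images gives test sets of
    112 and 111.
    """
    test_a = math.ceil(spec.test_fraction * spec.n_class_a)
    test_b = math.ceil(spec.test_fraction * spec.n_class_b)
    if test_a >= spec.n_class_a or test_b >= spec.n_class_b:
        raise ValueError("test split consumes an entire class")
    return SplitCounts(
        test_a=test_a,
        test_b=test_b,
        train_a=spec.n_class_a - test_a,
        train_b=spec.n_class_b - test_b,
    )


def split_indices(spec: SplitSpec) -> tuple[dict, dict]:
    """Deterministic test/train index membership per class under the seed."""
    counts = split_counts(spec)
    rng = np.random.default_rng(spec.seed)
    out = []
    for n, n_test in ((spec.n_class_a, counts.test_a), (spec.n_class_b, counts.test_b)):
        perm = rng.permutation(n)
        out.append({"test": np.sort(perm[:n_test]), "train": np.sort(perm[n_test:])})
    return out[0], out[1]


def extract_features(
    image: np.ndarray,
    pixel_size_nm: float,
    thresholds: morphometry.ShapeThresholds = morphometry.ShapeThresholds(),
    scale_px: float = 2.0,
    k_sigma: float = 3.0,
) -> np.ndarray:
    """Per-image morphometry feature vector (see :data:`FEATURE_NAMES`)."""
    px_um = pixel_size_nm / 1000.0
    area_um2 = image.shape[0] * image.shape[1] * px_um**2
    mask = detection.binarize_spots(image, scale_px=scale_px, k_sigma=k_sigma)
    records = detection.label_regions(mask, pixel_size_nm)
    if not records:
        return np.zeros(len(FEATURE_NAMES))
    verdicts = morphometry.classify_regions(records, thresholds)
    n = len(records)
    n_tub = sum(1 for v in verdicts if v.tubular)
    circ = np.array([r.circularity for r in records])
    ecc = np.array([r.eccentricity for r in records])
    ratios = np.array(
        [min(v.axis_ratio, 50.0) for v in verdicts]  # cap degenerate ratios
    )
    areas = np.array([r.area_um2 for r in records])
    return np.array(
        [
            n / area_um2,
            n_tub / area_um2,
            n_tub / n,
            circ.mean(),
            circ.std(),
            ecc.mean(),
            ecc.std(),
            ratios.mean(),
            areas.mean(),
            areas.sum() / area_um2,
        ]
    )


class FeatureClassifier:
    """Morphometry-feature logistic-regression backend.

    Predicts the probability that an image shows the knockout phenotype.
    ``augment_flips`` mirrors training images before feature extraction; it
    is off by default for this backend because the feature vector is
    flip-invariant (the flag matters for image-level backends plugged in
    through the same interface).
    """

    def __init__(
        self,
        pixel_size_nm: float,
        thresholds: morphometry.ShapeThresholds = morphometry.ShapeThresholds(),
        scale_px: float = 2.0,
        k_sigma: float = 3.0,
        C: float = 1.0,
        augment_flips: bool = False,
        seed: int = 0,
    ) -> None:
        self.pixel_size_nm = pixel_size_nm
        self.thresholds = thresholds
        self.scale_px = scale_px
        self.k_sigma = k_sigma
        self.augment_flips = augment_flips
        self.seed = seed
        self._model = make_pipeline(
            StandardScaler(), LogisticRegression(C=C, max_iter=2000)
        )

    def _features(self, images) -> np.ndarray:
        return np.array(
            [
                extract_features(
                    img,
                    self.pixel_size_nm,
                    thresholds=self.thresholds,
                    scale_px=self.scale_px,
                    k_sigma=self.k_sigma,
                )
                for img in images
            ]
        )

    def fit(self, ko_images, wt_images) -> "FeatureClassifier":
        if len(ko_images) == 0 or len(wt_images) == 0:
            raise ValueError("both classes need at least one image")
        ko, wt = list(ko_images), list(wt_images)
        if self.augment_flips:
            ko = ko + [np.fliplr(i) for i in ko] + [np.flipud(i) for i in ko]
            wt = wt + [np.fliplr(i) for i in wt] + [np.flipud(i) for i in wt]
        X = np.vstack([self._features(ko), self._features(wt)])
        y = np.concatenate([np.ones(len(ko)), np.zeros(len(wt))])
        self._model.fit(X, y)
        return self

    def predict_ko_probability(self, images) -> np.ndarray:
        X = self._features(list(images))
        return self._model.predict_proba(X)[:, 1]


def train_classifier(
    ko_images,
    wt_images,
    pixel_size_nm: float,
    backend: str = "baseline_features",
    test_fraction: float = 0.15,
    seed: int = 0,
    **backend_kwargs,
) -> tuple[FeatureClassifier, float]:
    """Train a knockout-vs-wild-type image classifier and report test accuracy.

    Images are split per class with ceil-rounded ``test_fraction`` test sets
    (deterministic under ``seed``), the backend is fitted on the training
    images, and held-out accuracy is computed on the test images.
    """
    if backend != "baseline_features":
        raise ValueError(
            f"unknown backend {backend!r}; plug external classifiers in "
            "through the FeatureClassifier interface"
        )
    ko_images, wt_images = list(ko_images), list(wt_images)
    if len(ko_images) == 0 or len(wt_images) == 0:
        raise ValueError("both classes need at least one image")
    spec = SplitSpec(
        n_class_a=len(ko_images),
        n_class_b=len(wt_images),
        test_fraction=test_fraction,
        seed=seed,
    )
    idx_ko, idx_wt = split_indices(spec)
    clf = FeatureClassifier(pixel_size_nm, seed=seed, **backend_kwargs)
    clf.fit(
        [ko_images[i] for i in idx_ko["train"]],
        [wt_images[i] for i in idx_wt["train"]],
    )
    p_ko = clf.predict_ko_probability([ko_images[i] for i in idx_ko["test"]])
    p_wt = clf.predict_ko_probability([wt_images[i] for i in idx_wt["test"]])
    correct = int((p_ko >= 0.5).sum()) + int((p_wt < 0.5).sum())
    accuracy = correct / (len(p_ko) + len(p_wt))
    return clf, float(accuracy)


def score_condition(
    images,
    classifier: FeatureClassifier,
    wt_mean: float,
    ko_mean: float,
    condition_id: str = "",
    pixel_size_nm: float | None = None,
) -> ScreenRecord:
    """Score one condition: mean knockout probability + tubulation index.

    The knockout probability is averaged arithmetically over the condition's
    images; the tubule density is likewise averaged per image and rescaled
    with the same-experiment control means.
    """
    images = list(images)
    if len(images) == 0:
        raise ValueError("score_condition needs at least one image")
    px = pixel_size_nm if pixel_size_nm is not None else classifier.pixel_size_nm
    probs = classifier.predict_ko_probability(images)
    densities = []
    for img in images:
        feats = extract_features(
            img, px, thresholds=classifier.thresholds,
            scale_px=classifier.scale_px, k_sigma=classifier.k_sigma,
        )
        densities.append(feats[FEATURE_NAMES.index("tubules_per_um2")])
    index = morphometry.tubulation_index(
        float(np.mean(densities)), wt_mean, ko_mean, condition_id=condition_id
    )
    return ScreenRecord(
        condition_id=condition_id,
        mean_ko_probability=float(probs.mean()),
        tubulation_index=index.index,
    )


def derive_gates(
    control_records: list[ScreenRecord], rule: str = "minimal_effect"
) -> GateThresholds:
    """Gates from the positive-control (gene-targeting) siRNA scores.

    ``minimal_effect`` (default, the dashed-line rule): a candidate must be
    at least as knockout-like as the *weakest* control — gate at the minimum
    control probability and the maximum control index.  ``all_controls``:
    at least as knockout-like as *every* control — maximum probability,
    minimum index.
    """
    if not control_records:
        raise ValueError("derive_gates needs at least one positive control")
    probs = [r.mean_ko_probability for r in control_records]
    idxs = [r.tubulation_index for r in control_records]
    if rule == "minimal_effect":
        return GateThresholds(min(probs), max(idxs), rule=rule)
    if rule == "all_controls":
        return GateThresholds(max(probs), min(idxs), rule=rule)
    raise ValueError(f"unknown gate rule {rule!r}")


def call_hits(
    records: list[ScreenRecord], gates: GateThresholds
) -> tuple[list[ScreenRecord], list[str]]:
    """Apply both gates; a hit passes the classifier AND the tubule readout.

    The classifier gate passes when the mean knockout probability is at least
    the gate probability; the tubule gate when the tubulation index is at
    most the gate index (lower index = stronger tubule loss).  Returns the
    updated records and the hit list sorted by condition id.
    """
    out = []
    for r in records:
        out.append(
            replace(
                r,
                passes_nn_gate=r.mean_ko_probability >= gates.nn_min_probability,
                passes_tub_gate=r.tubulation_index <= gates.tub_max_index,
            )
        )
    hits = sorted(r.condition_id for r in out if r.is_hit)
    return out, hits
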