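"""End-to-end orchestration of the mapping scheme on a scene.

Chains the four processing steps — feature extraction, per-stratum training
on harvested reliable pixels, membership prediction with stratum buffers and
geometric-mean fusion, and confidence-weighted majority filtering — followed
by binarization and accuracy assessment against the scene truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import contains_xy

from . import assess, classifier, features, postfilter, sampler
from .scene_sim import SceneBundle
from .types import (
    ConfidenceImage,
    FeatureImage,
    LabelImage,
    MembershipImage,
    TrainingSet,
    pixel_centers,
)

DEFAULT_BUFFER_PIXELS = 8.0


@dataclass
class PipelineResult:
    features: FeatureImage
    training: TrainingSet
    memberships: MembershipImage
    confidence: ConfidenceImage
    labels_raw: LabelImage  # argmax before filtering
    labels_filtered: LabelImage
    binary: LabelImage
    report: assess.AccuracyReport | None = None
    report_eroded: assess.AccuracyReport | None = None
    gini_by_stratum: np.ndarray | None = None  # (n_strata, 12)
    tie_count: int = 0
    models: list = field(default_factory=list)


def stratum_masks(bundle: SceneBundle, buffer: float = 0.0) -> list[np.ndarray]:
    """Boolean pixel masks of each (optionally buffered) stratum polygon."""
    h, w = bundle.shape
    xs, ys = pixel_centers((h, w), bundle.truth.transform)
    masks = []
    for poly in bundle.strata:
        geom = poly.buffer(buffer) if buffer else poly
        masks.append(contains_xy(geom, xs.ravel(), ys.ravel()).reshape(h, w))
    return masks


def run_pipeline(
    bundle: SceneBundle,
    outdated: LabelImage,
    seed: int = 0,
    n_training: int = sampler.TRAINING_TARGET,
    buffer: float = DEFAULT_BUFFER_PIXELS,
    filter_mode: str = "weighted",
    min_valid: int = features.DEFAULT_MIN_VALID,
    som_shape: tuple[int, int] | None = (8, 8),
    assess_truth: bool = True,
) -> PipelineResult:
    """Run the full scheme on a synthetic scene.

    ``filter_mode`` is one of "weighted", "majority", "none".
    ``som_shape`` defaults to a fixed 8x8 grid, adequate for the synthetic
    class structure and much cheaper than the 16x16 cap.
    """
    rng = np.random.default_rng(seed)
    feats = features.extract_features(bundle.stack, min_valid=min_valid)

    cores = stratum_masks(bundle, buffer=0.0)
    memberships: list[MembershipImage] = []
    trainings: list[TrainingSet] = []
    models = []
    gini_rows = []
    for sid, core in enumerate(cores):
        training, _ = sampler.harvest_training_set(
            feats,
            outdated,
            stratum_id=sid,
            stratum_mask=core,
            n_total=n_training,
            seed=int(rng.integers(0, 2**31 - 1)),
            som_shape=som_shape,
        )
        model = classifier.train_stratum_rf(training, seed=int(rng.integers(0, 2**31 - 1)))
        member = classifier.predict_memberships(
            model, feats, bundle.strata[sid], buffer=buffer
        )
        trainings.append(training)
        models.append(model)
        gini_rows.append(model.feature_importances_)
        memberships.append(member)

    fused = classifier.fuse_memberships(classifier.align_classes(memberships))
    confidence = classifier.erp_image(fused)
    labels_raw, ties = classifier.argmax_label(
        fused, legend=dict(bundle.truth.legend), nodata=bundle.truth.nodata
    )

    if filter_mode == "weighted":
        filtered = postfilter.weighted_majority_filter(labels_raw, confidence)
    elif filter_mode == "majority":
        filtered = postfilter.majority_filter(labels_raw)
    elif filter_mode == "none":
        filtered = labels_raw
    else:
        raise ValueError(f"unknown filter mode: {filter_mode}")

    binary = postfilter.binarize(filtered)
    result = PipelineResult(
        features=feats,
        training=TrainingSet.concat(trainings) if len(trainings) > 1 else trainings[0],
        memberships=fused,
        confidence=confidence,
        labels_raw=labels_raw,
        labels_filtered=filtered,
        binary=binary,
        gini_by_stratum=np.vstack(gini_rows),
        tie_count=ties,
        models=models,
    )
    if assess_truth:
        binary_truth = postfilter.binarize(bundle.truth)
        result.report = assess.confusion_and_scores(binary, binary_truth)
        result.report_eroded = assess.confusion_and_scores(
            binary, binary_truth, erode_edges=True
        )
    return result


def training_label_accuracy(training: TrainingSet, truth: LabelImage) -> float:
    """Fraction of training rows whose harvested label matches the truth."""
    return float((truth.labels[training.rows, training.cols] == training.y).mean())


def map_agreement(a: LabelImage, b: LabelImage) -> float:
    """Pixelwise agreement of two label maps over jointly valid pixels."""
    both = a.mask() & b.mask()
    return float((a.labels[both] == b.labels[both]).mean())
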