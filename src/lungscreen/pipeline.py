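"""End-to-end orchestration: recordings -> features -> selection -> model.

The staged order mirrors the screening workflow: bandpass filtering,
peak normalization, 6 s segmentation, 13-feature extraction, Kruskal-Wallis
ranking, and training of the feed-forward classifier on the accepted
features. :func:`run_pipeline` performs the whole chain on a labeled corpus
and returns every intermediate artifact, which is what the CLI commands and
the acceptance checks build on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lungscreen.audio_io import AudioRecording
from lungscreen.classifier import (
    ModelConfig,
    TrainedModel,
    balance_classes,
    evaluate_accuracy,
    predict,
    predict_proba,
    split_dataset,
    train,
)
from lungscreen.config import PipelineConfig
from lungscreen.errors import ContractError
from lungscreen.evaluation import ConfusionMatrix, MetricsReport, confusion_matrix, per_class_metrics
from lungscreen.features import feature_table
from lungscreen.preprocessing import apply_filter, design_filter, normalize, segment
from lungscreen.selection import FeatureRanking, rank_features


def preprocess_recording(
    recording: AudioRecording, config: PipelineConfig = PipelineConfig()
):
    """Filter -> normalize -> segment one recording."""
    spec = design_filter(
        config.filter_family,
        config.filter_order,
        config.low_cut_hz,
        config.high_cut_hz,
        recording.sample_rate,
    )
    filtered = apply_filter(spec, recording)
    return segment(normalize(filtered), seg_seconds=config.segment_seconds)


def corpus_feature_table(
    recordings: Sequence[AudioRecording], config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Labeled feature table over every 6 s segment of every recording."""
    segments, labels = [], []
    for rec in recordings:
        segs = preprocess_recording(rec, config)
        segments.extend(segs)
        labels.extend([rec.label.value if rec.label is not None else None] * len(segs))
    if not segments:
        raise ContractError("no segments produced from the corpus")
    return feature_table(segments, labels=labels)


@dataclass
class PipelineResult:
    """Artifacts of a full training run."""

    features: pd.DataFrame
    ranking: FeatureRanking
    selected_features: tuple[str, ...]
    model: TrainedModel
    train_table: pd.DataFrame
    test_table: pd.DataFrame
    cm: ConfusionMatrix
    metrics: MetricsReport
    train_accuracy: float
    test_accuracy: float


def run_pipeline(
    recordings: Sequence[AudioRecording],
    config: PipelineConfig = PipelineConfig(),
    selected_features: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Train and evaluate the screening model on a labeled corpus.

    Steps: feature extraction, stratified 80:20 split, oversampling of the
    training split to class balance, Kruskal-Wallis ranking on the training
    split, training on the accepted features (or an explicit
    ``selected_features`` subset), and held-out evaluation.
    """
    features = corpus_feature_table(recordings, config)
    if features["label"].isna().any():
        raise ContractError("every recording needs a class label to train")
    train_tbl, test_tbl = split_dataset(
        features, test_fraction=config.test_fraction, seed=config.split_seed
    )
    balanced = balance_classes(train_tbl, seed=config.balance_seed)
    ranking = rank_features(balanced, alpha=config.selection_alpha)
    if selected_features is None:
        selected = ranking.accepted_names or ranking.names[:1]
    else:
        selected = tuple(selected_features)
    model = train(balanced, config.model, feature_names=selected)
    true_labels = test_tbl["label"].astype(str).to_numpy()
    predicted = predict(model, test_tbl)
    cm = confusion_matrix(true_labels, predicted, class_order=model.class_order)
    return PipelineResult(
        features=features,
        ranking=ranking,
        selected_features=tuple(selected),
        model=model,
        train_table=balanced,
        test_table=test_tbl,
        cm=cm,
        metrics=per_class_metrics(cm),
        train_accuracy=evaluate_accuracy(model, balanced),
        test_accuracy=evaluate_accuracy(model, test_tbl),
    )


def screen_recording(
    recording: AudioRecording,
    model: TrainedModel,
    config: PipelineConfig = PipelineConfig(),
) -> np.ndarray:
    """Mean class probabilities over a recording's segments.

    Each 6 s segment is scored independently; the recording-level screen is
    the average probability vector, aligned to the model's class order.
    """
    segs = preprocess_recording(recording, config)
    table = feature_table(segs)
    probs = predict_proba(model, table)
    return probs.mean(axis=0)
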