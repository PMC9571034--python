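"""Assembling classifier datasets from bipolar recordings.

This module wires the per-channel chain together — denoise, segment,
extract features — and builds the labelled sequence sets the classifier
trains on.  The training design mirrors the clinical study: the
epileptic class is the ground-truth affected LB channels of focal
subjects, and the normal class is the same channel labels taken from
normal subjects (so both classes cover the same scalp regions and the
classifier cannot learn channel identity instead of pathology).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureSequence, build_sequence
from .montage import BipolarRecording
from .preprocessing import DenoiseConfig, dwt_denoise, segment_signal


def channel_sequence(
    signal,
    fs: float,
    channel_label: str = "",
    feature_subset=FEATURE_NAMES,
    denoise_config: DenoiseConfig | None = None,
    window_s: float = 1.0,
    overlap_fraction: float = 0.5,
    denoise: bool = True,
    label: str = "unknown",
    subject_id: str = "",
) -> FeatureSequence:
    """Denoise -> segment -> extract features for one LB channel."""
    x = np.asarray(signal, dtype=float)
    if denoise:
        x = dwt_denoise(x, denoise_config or DenoiseConfig())
    segments = segment_signal(
        x, window_s=window_s, overlap_fraction=overlap_fraction, fs=fs
    )
    return build_sequence(
        segments,
        feature_subset=feature_subset,
        channel_label=channel_label,
        label=label,
        subject_id=subject_id,
    )


def recording_sequences(
    recording: BipolarRecording,
    channels=None,
    feature_subset=FEATURE_NAMES,
    label_from_ground_truth: bool = False,
    **chain_kwargs,
) -> list[FeatureSequence]:
    """Feature sequences for (a subset of) one recording's LB channels.

    With ``label_from_ground_truth`` the ground-truth affected channels
    are labelled ``"epileptic"`` and the rest ``"normal"``; otherwise all
    sequences are labelled ``"unknown"``.
    """
    channels = list(channels) if channels is not None else list(recording.channels)
    out = []
    for ch in channels:
        if label_from_ground_truth:
            label = (
                "epileptic" if ch in recording.affected_channels else "normal"
            )
        else:
            label = "unknown"
        out.append(
            channel_sequence(
                recording.channel(ch),
                fs=recording.fs,
                channel_label=ch,
                feature_subset=feature_subset,
                label=label,
                subject_id=recording.subject_id,
                **chain_kwargs,
            )
        )
    return out


def training_sequences(
    focal_recordings: list[BipolarRecording],
    normal_recordings: list[BipolarRecording],
    feature_subset=FEATURE_NAMES,
    **chain_kwargs,
) -> list[FeatureSequence]:
    """Build the labelled channel set for classifier training.

    Epileptic sequences come from each focal subject's affected LB
    channels.  Normal sequences come from normal subjects, each mirroring
    the affected channel set of a focal subject (cycled in order), so the
    two classes span the same channel labels.
    """
    if not focal_recordings or not normal_recordings:
        raise ValueError("need both focal and normal recordings")
    sequences: list[FeatureSequence] = []
    affected_sets = []
    for rec in focal_recordings:
        affected = sorted(rec.affected_channels)
        if not affected:
            raise ValueError(
                f"focal recording {rec.subject_id} has no affected channels"
            )
        affected_sets.append(affected)
        for ch in affected:
            seq = channel_sequence(
                rec.channel(ch),
                fs=rec.fs,
                channel_label=ch,
                feature_subset=feature_subset,
                label="epileptic",
                subject_id=rec.subject_id,
                **chain_kwargs,
            )
            sequences.append(seq)
    for i, rec in enumerate(normal_recordings):
        for ch in affected_sets[i % len(affected_sets)]:
            sequences.append(
                channel_sequence(
                    rec.channel(ch),
                    fs=rec.fs,
                    channel_label=ch,
                    feature_subset=feature_subset,
                    label="normal",
                    subject_id=rec.subject_id,
                    **chain_kwargs,
                )
            )
    return sequences


def feature_table(sequences: list[FeatureSequence]) -> pd.DataFrame:
    """Flatten sequences into a per-segment table for the feature screen.

    One row per (subject, channel, segment); feature columns plus
    ``subject_id``, ``channel``, ``segment`` and ``label``.
    """
    rows = []
    for seq in sequences:
        for k, vec in enumerate(seq.vectors):
            row = dict(zip(seq.feature_names, vec))
            row.update(
                subject_id=seq.subject_id,
                channel=seq.channel_label,
                segment=k,
                label=seq.label,
            )
            rows.append(row)
    if not rows:
        raise ValueError("no sequences supplied")
    return pd.DataFrame(rows)
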