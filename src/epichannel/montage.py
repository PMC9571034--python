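"""Longitudinal bipolar (LB) montage derivation.

The "double banana" montage re-references a 16-electrode referential
recording into 16 bipolar channels along the anterior-posterior chains of
the 10-20 system.  Each channel is the sample-wise difference between two
adjacent electrodes of a chain, anterior electrode first, so any common
reference signal cancels exactly.  The midline leads (Fz, Cz, Pz) are not
part of this montage and are ignored if present in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ReferentialRecording

#: The 16 electrodes of the reduced 10-20 set, in canonical order.
ELECTRODES = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "P3", "P4", "T3", "T4", "T5", "T6", "O1", "O2",
)

# Anode (anterior) / cathode pairs, chain by chain: left temporal, left
# parasagittal, right temporal, right parasagittal.
_LB_PAIRS = (
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
)

#: Canonical LB channel labels ("anode-cathode").
LB_CHANNELS = tuple(f"{a}-{b}" for a, b in _LB_PAIRS)

#: Electrode chains feeding the left / right temporal LB channels.
TEMPORAL_CHAINS = {
    "left": ("Fp1", "F7", "T3", "T5", "O1"),
    "right": ("Fp2", "F8", "T4", "T6", "O2"),
}


def lb_channel_pairs() -> list[tuple[str, str]]:
    """Return the 16 (anode, cathode) electrode pairs of the LB montage.

    Pairs are ordered left temporal, left parasagittal, right temporal,
    right parasagittal; within a chain the first element of each pair is
    the more anterior electrode.
    """
    return list(_LB_PAIRS)


@dataclass
class BipolarRecording:
    """A 16-channel longitudinal-bipolar recording for one subject.

    Attributes
    ----------
    subject_id : str
    channels : tuple of str
        The 16 LB channel labels, always :data:`LB_CHANNELS`.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (16, n_samples)
        Bipolar potentials in microvolt.
    affected_channels : frozenset of str
        Ground-truth affected LB channels (non-empty only for synthetic
        recordings with a known pathology).
    group : str
        Population label carried over from the source recording.
    """

    subject_id: str
    fs: float
    data: np.ndarray
    channels: tuple[str, ...] = LB_CHANNELS
    affected_channels: frozenset = field(default_factory=frozenset)
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows for "
                f"{len(self.channels)} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise KeyError(f"no LB channel named {label!r}") from None


def _affected_lb_channels(
    affected_electrodes, rule: str = "both"
) -> frozenset:
    affected = set(affected_electrodes)
    out = set()
    for (a, b), label in zip(_LB_PAIRS, LB_CHANNELS):
        if rule == "both":
            hit = a in affected and b in affected
        elif rule == "either":
            hit = a in affected or b in affected
        else:
            raise ValueError(f"unknown affected-channel rule {rule!r}")
        if hit:
            out.add(label)
    return frozenset(out)


def compute_lb(
    recording: ReferentialRecording, affected_rule: str = "both"
) -> BipolarRecording:
    """Derive the longitudinal bipolar montage from a referential recording.

    For each (anode, cathode) pair of :func:`lb_channel_pairs` the output
    channel is ``V_anode(t) - V_cathode(t)``; the recording's common
    reference cancels in the subtraction.  An LB channel is marked
    affected when, under ``affected_rule="both"`` (default), both of its
    electrodes are in the recording's ``affected_electrodes`` set, or under
    ``"either"``, at least one is.

    Raises
    ------
    KeyError
        If a required electrode is missing from the recording.
    """
    index = {lab: i for i, lab in enumerate(recording.electrodes)}
    rows = []
    for a, b in _LB_PAIRS:
        for electrode in (a, b):
            if electrode not in index:
                raise KeyError(
                    f"electrode {electrode!r} required for LB channel "
                    f"{a}-{b} is missing from the recording"
                )
        rows.append(recording.data[index[a]] - recording.data[index[b]])
    return BipolarRecording(
        subject_id=recording.subject_id,
        fs=recording.fs,
        data=np.vstack(rows),
        affected_channels=_affected_lb_channels(
            recording.affected_electrodes, affected_rule
        ),
        group=recording.group,
    )
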