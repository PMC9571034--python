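"""Shared domain containers for referential recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("normal", "focal", "generalized")


@dataclass
class ReferentialRecording:
    """One subject's referential EEG: 16 electrodes at a common reference.

    Attributes
    ----------
    subject_id : str
    group : str
        One of ``"normal"``, ``"focal"``, ``"generalized"`` (or
        ``"unknown"`` for externally loaded data).
    electrodes : tuple of str
        Ordered electrode labels.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_electrodes, n_samples)
        Scalp potentials in microvolt.
    affected_electrodes : frozenset of str
        Ground-truth affected electrodes; empty for normal subjects and
        for data of unknown provenance.
    """

    subject_id: str
    group: str
    electrodes: tuple[str, ...]
    fs: float
    data: np.ndarray
    affected_electrodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.electrodes):
            raise ValueError(
                "data must be a (n_electrodes, n_samples) matrix matching "
                f"the {len(self.electrodes)} electrode labels; "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        unknown = set(self.affected_electrodes) - set(self.electrodes)
        if unknown:
            raise ValueError(
                f"affected electrodes {sorted(unknown)} not in electrode list"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
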