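"""Epoch segmentation and screening, sign-flip averaging, label grouping.

Continuous recordings are cut into fixed-length non-overlapping epochs and
screened by a peak-to-peak amplitude rule: an epoch is good only if every
channel's max−min stays below the threshold for its channel type, and the
first ``n_keep`` good epochs are retained (a subject with fewer good epochs
is excluded).  For real MEG the conventional thresholds are 10 pT for
magnetometers and 10 pT/cm for gradiometers; for simulated data thresholds
are supplied in simulation units.

Parcel time series are formed by averaging source signals within a parcel.
Sources on opposite sulcal walls have near-opposite orientations, so naive
averaging cancels signal; a sign-flip is applied first to every source whose
orientation differs from the parcel's dominant direction by more than 90°.
The dominant direction is the principal axis of the orientation second-moment
matrix (robust to large flipped fractions), with its sign chosen to align
with the orientation sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EpochScreenRule",
    "ParcellationMap",
    "SubjectExcludedError",
    "segment_epochs",
    "screen_epochs",
    "dominant_orientation",
    "signflip_average",
    "group_labels",
]


class SubjectExcludedError(RuntimeError):
    """Raised when a subject has fewer good epochs than required."""


@dataclass(frozen=True)
class EpochScreenRule:
    """Peak-to-peak screening rule.

    thresholds maps channel type (e.g. "mag", "grad", "sim") to the maximum
    allowed per-channel peak-to-peak amplitude, in the physical units of that
    channel type.
    """

    thresholds: dict
    n_keep: int = 10
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        if self.n_keep < 1:
            raise ValueError("n_keep must be ≥ 1")
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be positive")


#: conventional defaults for real MEG channel types
MEG_THRESHOLDS = {"mag": 10e-12, "grad": 10e-12 / 1e-2}  # 10 pT, 10 pT/cm


@dataclass(frozen=True)
class ParcellationMap:
    """Assignment of fine parcel labels to coarse region labels."""

    fine_labels: list
    coarse_labels: list
    assignment: dict  # fine label -> coarse label

    def __post_init__(self) -> None:
        if set(self.assignment) != set(self.fine_labels):
            raise ValueError("every fine label must be assigned exactly once")
        used = set(self.assignment.values())
        if not used.issubset(set(self.coarse_labels)):
            raise ValueError("assignment targets unknown coarse labels")
        if set(self.coarse_labels) - used:
            raise ValueError("every coarse label must be non-empty")

    def members(self, coarse_label) -> list:
        return [f for f in self.fine_labels if self.assignment[f] == coarse_label]

    @classmethod
    def identity(cls, labels) -> "ParcellationMap":
        labels = list(labels)
        return cls(labels, labels, {x: x for x in labels})

    @classmethod
    def from_tsv(cls, path) -> "ParcellationMap":
        """Read a two-column TSV (fine_label, coarse_label); no header."""
        fine, assignment = [], {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f, c = line.rstrip("\n").split("\t")
            fine.append(f)
            assignment[f] = c
        coarse = sorted(set(assignment.values()))
        return cls(fine, coarse, assignment)

    @classmethod
    def from_json(cls, path) -> "ParcellationMap":
        d = json.loads(Path(path).read_text())
        return cls(d["fine_labels"], d["coarse_labels"], d["assignment"])

    def to_tsv(self, path) -> None:
        lines = [f"{f}\t{self.assignment[f]}" for f in self.fine_labels]
        Path(path).write_text("\n".join(lines) + "\n")


def segment_epochs(
    continuous: np.ndarray, fs: float, epoch_len: float
) -> np.ndarray:
    """Cut continuous signals into non-overlapping epochs.

    Parameters
    ----------
    continuous
        (n_channels, n_samples) real array.
    fs, epoch_len
        Sampling rate (Hz) and epoch length (s); the trailing remainder that
        does not fill a whole epoch is discarded.

    Returns
    -------
    (n_channels, n_epochs, samples_per_epoch) array.
    """
    continuous = np.atleast_2d(np.asarray(continuous))
    n_samples = continuous.shape[-1]
    samples_per_epoch = int(round(epoch_len * fs))
    if samples_per_epoch < 1:
        raise ValueError("epoch_len × fs must be at least one sample")
    n_epochs = n_samples // samples_per_epoch
    if n_epochs == 0:
        raise ValueError(
            f"signal of {n_samples} samples is shorter than one "
            f"{samples_per_epoch}-sample epoch"
        )
    trimmed = continuous[:, : n_epochs * samples_per_epoch]
    return trimmed.reshape(continuous.shape[0], n_epochs, samples_per_epoch)


def screen_epochs(
    epochs: np.ndarray, rule: EpochScreenRule, channel_types=None
) -> np.ndarray:
    """Return the indices of the first ``n_keep`` good epochs, in temporal order.

    An epoch is good iff every channel's peak-to-peak amplitude is within the
    threshold for its channel type.  Raises SubjectExcludedError when fewer
    than ``n_keep`` epochs survive.
    """
    epochs = np.asarray(epochs)
    n_channels, n_epochs = epochs.shape[0], epochs.shape[1]
    if channel_types is None:
        if len(rule.thresholds) != 1:
            raise ValueError("channel_types required with multiple thresholds")
        channel_types = [next(iter(rule.thresholds))] * n_channels
    thr = np.array([rule.thresholds[t] for t in channel_types])
    ptp = epochs.max(axis=-1) - epochs.min(axis=-1)  # (channels, epochs)
    good = np.flatnonzero(np.all(ptp <= thr[:, None], axis=0))
    if good.size < rule.n_keep:
        raise SubjectExcludedError(
            f"subject excluded: only {good.size} good epochs "
            f"(need {rule.n_keep})"
        )
    return good[: rule.n_keep]


def dominant_orientation(orientations: np.ndarray) -> np.ndarray:
    """Principal axis of the orientation cloud, sign-aligned with the mean.

    The dominant direction is the leading eigenvector of the second-moment
    matrix Σ vᵀv; unlike the vector mean it is stable when many sources are
    flipped.  Its sign is chosen to have a non-negative dot product with the
    orientation sum (ties left as-is).
    """
    o = np.asarray(orientations, dtype=float)
    if o.ndim != 2 or o.shape[0] < 1:
        raise ValueError("need at least one orientation vector")
    if np.allclose(o, 0):
        raise ValueError("all orientations are zero")
    moment = o.T @ o
    evals, evecs = np.linalg.eigh(moment)
    v = evecs[:, -1]
    if v @ o.sum(axis=0) < 0:
        v = -v
    return v / np.linalg.norm(v)


def signflip_average(patch) -> np.ndarray:
    """Sign-flip parcel averaging.

    Source signals whose orientation has a strictly negative dot product with
    the parcel's dominant direction (i.e. differ by more than 90°) are negated
    before the arithmetic mean across sources; exact 90° is not flipped.
    """
    dominant = dominant_orientation(patch.orientations)
    signs = np.where(patch.orientations @ dominant < 0, -1.0, 1.0)
    return (signs[:, None] * patch.source_signals).mean(axis=0)


def group_labels(parcellation: ParcellationMap) -> dict:
    """Index fine-parcel pairs by coarse-region pair.

    For coarse pair (A, B), A ≠ B: all fine pairs (i ∈ A, j ∈ B).  For the
    within-region entry (A, A): all unordered fine pairs i ≠ j inside A.
    The returned key order follows coarse label order; pair keys are
    (coarse_a, coarse_b) with a ≤ b in that order.
    """
    out: dict = {}
    coarse = parcellation.coarse_labels
    members = {c: parcellation.members(c) for c in coarse}
    for ai, a in enumerate(coarse):
        ma = members[a]
        out[(a, a)] = [(ma[i], ma[j]) for i in range(len(ma)) for j in range(i + 1, len(ma))]
        for b in coarse[ai + 1 :]:
            out[(a, b)] = [(fa, fb) for fa in ma for fb in members[b]]
    return out
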