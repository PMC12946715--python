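"""Phase- and amplitude-based connectivity metrics and network summaries.

The primary metric is the weighted phase-lag index (WPLI), which quantifies
the asymmetry of the phase-difference distribution between two narrowband
analytic signals ``x(f,t)`` and ``y(f,t)`` over the N_t valid time points at
frequency f::

    WPLI(f) = | mean_t Im S_xy(f,t) |  /  mean_t | Im S_xy(f,t) |

with cross-spectral density ``S_xy = x · conj(y)``.  WPLI is insensitive to
zero-lag coupling (Im S = 0), which makes it robust to source leakage, and it
is invariant to positive rescaling of either signal.  Values lie in [0, 1];
0/0 is defined as 0.

As a complementary metric, the orthogonalized amplitude-envelope correlation
(AEC) correlates narrowband amplitude envelopes after removing, per sample,
the component of one signal that is instantaneously collinear with the other
— again suppressing artificial zero-lag interactions.

Networks are analyzed unthresholded.  Fine-parcellation matrices are
aggregated into a coarser parcellation by spatially averaging edge weights;
summaries are the per-region mean connection strength and the global mean
over all distinct links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .filterbank import AnalyticTensor
from .prep import ParcellationMap, group_labels

__all__ = [
    "ConnectivityMatrix",
    "DEFAULT_BANDS",
    "wpli",
    "orthogonalized_aec",
    "band_average",
    "aggregate_matrix",
    "mean_region_connectivity",
    "global_connectivity",
    "cohort_decade_average",
]

#: canonical frequency bands, Hz; the 30–40 Hz gap is intentional
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (40.0, 90.0),
}


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel × parcel edge weights for one frequency bin or band.

    The diagonal (self-connectivity) is undefined and stored as NaN; it is
    excluded from every summary statistic.
    """

    weights: np.ndarray
    metric: str  # "WPLI" | "AEC"
    frequency: float | str  # Hz bin center, or band name
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        off = ~np.eye(w.shape[0], dtype=bool)
        if not np.allclose(
            np.where(off, w, 0.0), np.where(off, w.T, 0.0), equal_nan=True
        ):
            raise ValueError("weights must be symmetric off the diagonal")
        np.fill_diagonal(w, np.nan)
        if self.metric == "WPLI":
            vals = w[off]
            if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
                raise ValueError("WPLI weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]


def _pooled_valid(analytic: AnalyticTensor, fi: int) -> np.ndarray:
    """Valid samples at bin fi pooled across epochs: (n_parcels, N_t) complex."""
    mask = analytic.valid_mask[fi]
    vals = analytic.values[:, fi][:, :, mask]  # (P, E, T_valid)
    return vals.reshape(vals.shape[0], -1)


def wpli(analytic: AnalyticTensor, labels=None) -> list[ConnectivityMatrix]:
    """All-to-all WPLI, one matrix per frequency bin.

    Time samples are pooled across all epochs into a single estimate per
    pair and frequency (one N_t), matching the single-sum definition.
    """
    out = []
    for fi, f in enumerate(analytic.freqs):
        z = _pooled_valid(analytic, fi)
        if z.shape[1] < 2:
            raise ValueError(f"fewer than 2 valid samples at {f:g} Hz")
        re, im = z.real, z.imag
        # Im S_xy = Im(x conj y) = im_x re_y − re_x im_y
        imS = im[:, None, :] * re[None, :, :] - re[:, None, :] * im[None, :, :]
        num = np.abs(imS.sum(axis=-1))
        den = np.abs(imS).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        w = np.clip(0.5 * (w + w.T), 0.0, 1.0)  # exact symmetry
        out.append(
            ConnectivityMatrix(
                weights=w, metric="WPLI", frequency=float(f),
                labels=list(labels) if labels is not None else [],
            )
        )
    return out


def orthogonalized_aec(analytic: AnalyticTensor, labels=None) -> list[ConnectivityMatrix]:
    """Pairwise-orthogonalized amplitude-envelope correlation per frequency bin.

    For the (x → y) direction the instantaneously collinear part of y is
    removed per sample, ``y⊥(t) = Im( y(t) · conj(x(t)) / |x(t)| )``, and the
    Pearson correlation of |x| with |y⊥| is taken over valid samples.  The
    matrix is symmetrized by averaging the two directions.  Raw amplitude
    envelopes are used (no log transform).
    """
    out = []
    for fi, f in enumerate(analytic.freqs):
        z = _pooled_valid(analytic, fi)
        n_parcels, n_t = z.shape
        if n_t < 3:
            raise ValueError(f"fewer than 3 valid samples at {f:g} Hz")
        amp = np.abs(z)
        c = np.full((n_parcels, n_parcels), np.nan)
        for i in range(n_parcels):
            for j in range(n_parcels):
                if i == j:
                    continue
                x, y = z[i], z[j]
                ok = amp[i] > 0
                if not ok.any():
                    raise ValueError("all-zero reference signal in AEC")
                y_orth = np.abs((y[ok] * np.conj(x[ok]) / amp[i][ok]).imag)
                ax = amp[i][ok]
                # collinear pair: the residual vanishes up to rounding noise
                degenerate = np.sqrt(np.mean(y_orth**2)) <= 1e-10 * np.sqrt(
                    np.mean(np.abs(y[ok]) ** 2)
                )
                if degenerate or np.std(y_orth) == 0 or np.std(ax) == 0:
                    c[i, j] = 0.0
                else:
                    c[i, j] = np.corrcoef(ax, y_orth)[0, 1]
        w = 0.5 * (c + c.T)
        np.fill_diagonal(w, np.nan)
        out.append(
            ConnectivityMatrix(
                weights=w, metric="AEC", frequency=float(f),
                labels=list(labels) if labels is not None else [],
            )
        )
    return out


def band_average(
    matrices: list[ConnectivityMatrix], band: tuple[float, float], name: str | None = None
) -> ConnectivityMatrix:
    """Arithmetic mean of per-bin matrices whose center frequency is in [low, high).

    Half-open membership: a 13-Hz bin belongs to beta, a 4-Hz bin to theta.
    Bins in the 30–40 Hz gap belong to no band.
    """
    low, high = band
    members = [m for m in matrices if low <= float(m.frequency) < high]
    if not members:
        raise ValueError(f"no frequency bins fall inside band [{low:g}, {high:g}) Hz")
    stack = np.stack([m.weights for m in members])
    return ConnectivityMatrix(
        weights=stack.mean(axis=0),
        metric=members[0].metric,
        frequency=name if name is not None else f"{low:g}-{high:g}Hz",
        labels=members[0].labels,
    )


def aggregate_matrix(
    fine: ConnectivityMatrix, parcellation: ParcellationMap
) -> ConnectivityMatrix:
    """Spatially average a fine-parcellation matrix into the coarse parcellation.

    Coarse weight (A, B) is the mean of all fine weights (i ∈ A, j ∈ B); the
    within-region diagonal averages fine pairs i ≠ j inside the region and is
    stored for completeness but excluded from statistics (set to NaN by the
    ConnectivityMatrix contract).
    """
    pair_index = group_labels(parcellation)
    fine_pos = {lab: k for k, lab in enumerate(parcellation.fine_labels)}
    coarse_labels = parcellation.coarse_labels
    n = len(coarse_labels)
    out = np.full((n, n), np.nan)
    for (ca, cb), fine_pairs in pair_index.items():
        ia, ib = coarse_labels.index(ca), coarse_labels.index(cb)
        if not fine_pairs:
            if ca == cb:  # singleton region: within-region diagonal undefined
                continue
            raise ValueError(f"empty fine-pair set for coarse pair ({ca}, {cb})")
        vals = [fine.weights[fine_pos[a], fine_pos[b]] for a, b in fine_pairs]
        out[ia, ib] = out[ib, ia] = float(np.mean(vals))
    return ConnectivityMatrix(
        weights=out, metric=fine.metric, frequency=fine.frequency,
        labels=list(coarse_labels),
    )


def mean_region_connectivity(matrix: ConnectivityMatrix) -> np.ndarray:
    """Mean strength of the connections associated with each region."""
    if matrix.n_parcels < 2:
        raise ValueError("need at least 2 regions")
    w = matrix.weights
    off = ~np.eye(w.shape[0], dtype=bool)
    return np.array([np.nanmean(w[i][off[i]]) for i in range(w.shape[0])])


def global_connectivity(matrix: ConnectivityMatrix) -> float:
    """Mean of all distinct links (strict upper triangle) of the network."""
    if matrix.n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    iu = np.triu_indices(matrix.n_parcels, k=1)
    return float(np.nanmean(matrix.weights[iu]))


def cohort_decade_average(
    items: np.ndarray, ages: np.ndarray, bin_start: float | None = None
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Average items (matrices, spectra or scalars) within consecutive age decades.

    Bins are 10-year half-open intervals anchored at the cohort minimum age
    (default [18, 28), [28, 38), …); a subject whose age equals the top edge
    of the last bin is included in it.  Empty decades are omitted with a
    warning.

    Returns the stacked per-decade means and the decade (low, high) edges.
    """
    items = np.asarray(items, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if items.shape[0] != ages.size:
        raise ValueError("items and ages must align on the first axis")
    start = float(np.floor(ages.min())) if bin_start is None else float(bin_start)
    n_bins = int(np.ceil((ages.max() - start) / 10.0)) or 1
    means, edges = [], []
    for b in range(n_bins):
        lo, hi = start + 10 * b, start + 10 * (b + 1)
        sel = (ages >= lo) & ((ages < hi) | ((b == n_bins - 1) & (ages == hi)))
        if not sel.any():
            warnings.warn(f"empty age decade [{lo:g}, {hi:g}); omitted")
            continue
        means.append(items[sel].mean(axis=0))
        edges.append((lo, hi))
    return np.stack(means), edges
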