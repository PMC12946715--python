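"""Complex Morlet filterbank producing narrowband analytic signals.

Phase-based connectivity metrics operate on narrowband analytic signals
``z(f, t)`` whose modulus is the amplitude envelope and whose argument is the
instantaneous phase.  This module implements a fixed-cycle-count Morlet
filterbank: each wavelet has a Gaussian envelope with temporal standard
deviation ``sigma_t = omega / (2 pi f)`` so that every filter spans the same
number of oscillation cycles (``omega``, default 5) regardless of its center
frequency.  The frequency response is Gaussian with standard deviation
``sigma_f = f / omega``, widening proportionally to the center frequency —
the natural choice for log-spaced frequency grids.

Normalization convention: wavelets are scaled for unit gain at their center
frequency, i.e. the analytic amplitude of a unit-amplitude sinusoid at a
center frequency equals 1.  Power is therefore reported in (signal units)².

Edge handling: each epoch is filtered independently by FFT convolution with
zero padding; samples within half the truncated wavelet support (±5 sigma_t)
of either epoch edge are flagged invalid and excluded from every downstream
average (power, cross-spectral density, WPLI/AEC sample counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft

__all__ = [
    "WaveletBank",
    "AnalyticTensor",
    "PowerSpectrum",
    "make_filterbank",
    "morlet_kernel",
    "wavelet_transform",
    "parcel_power",
    "global_power",
]

#: number of temporal standard deviations at which the wavelet is truncated
TRUNCATION_SD = 5.0


@dataclass(frozen=True)
class WaveletBank:
    """A geometric grid of complex Morlet filters.

    Parameters
    ----------
    center_freqs
        Strictly increasing center frequencies in Hz, geometrically spaced.
    omega
        Morlet parameter (number of cycles); ``sigma_t = omega / (2 pi f)``.
    fs
        Sampling rate in Hz.
    """

    center_freqs: np.ndarray
    omega: float
    fs: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.center_freqs, dtype=float)
        object.__setattr__(self, "center_freqs", freqs)
        if freqs.ndim != 1 or freqs.size < 1:
            raise ValueError("center_freqs must be a non-empty 1-D array")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("center_freqs must be strictly increasing")
        if freqs[-1] >= self.fs / 2:
            raise ValueError(
                f"highest center frequency {freqs[-1]:g} Hz is not below "
                f"the Nyquist frequency {self.fs / 2:g} Hz"
            )

    @property
    def n_freqs(self) -> int:
        return self.center_freqs.size

    def sigma_t(self, f: float) -> float:
        """Temporal standard deviation of the wavelet at frequency ``f``."""
        return self.omega / (2.0 * np.pi * f)

    def half_support(self, f: float) -> int:
        """Half the truncated kernel support at ``f``, in samples."""
        return int(np.ceil(TRUNCATION_SD * self.sigma_t(f) * self.fs))

    def min_epoch_samples(self) -> int:
        """Smallest epoch length (samples) with ≥1 valid sample at every bin."""
        return 2 * self.half_support(self.center_freqs[0]) + 1


@dataclass
class AnalyticTensor:
    """Narrowband analytic signals with an edge-validity mask.

    Attributes
    ----------
    values
        Complex array, shape (n_parcels, n_freqs, n_epochs, n_samples).
    valid_mask
        Boolean, shape (n_freqs, n_samples); True where the sample lies at
        least half a (truncated) wavelet support away from both epoch edges.
    fs
        Sampling rate in Hz.
    freqs
        Center frequencies, shape (n_freqs,).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    fs: float
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (parcels, freqs, epochs, samples)")
        if self.valid_mask.shape != (self.values.shape[1], self.values.shape[3]):
            raise ValueError("valid_mask shape must be (n_freqs, n_samples)")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.values.shape[2]

    def n_valid(self, freq_index: int) -> int:
        """Pooled valid sample count N_t at one frequency bin."""
        return int(self.valid_mask[freq_index].sum()) * self.n_epochs


@dataclass
class PowerSpectrum:
    """Mean squared analytic amplitude per parcel and frequency bin."""

    power: np.ndarray  # (n_parcels, n_freqs), signal-units²
    freqs: np.ndarray
    parcel_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def make_filterbank(
    f_min: float = 1.0,
    f_max: float = 100.0,
    n_freqs: int = 32,
    omega: float = 5.0,
    fs: float = 250.0,
) -> WaveletBank:
    """Build a geometrically spaced Morlet filterbank.

    ``center_freqs[k] = f_min * (f_max / f_min) ** (k / (n_freqs - 1))``,
    endpoints inclusive.  The default grid is 32 log-spaced bins from 1 to
    100 Hz.
    """
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if f_max >= fs / 2:
        raise ValueError(
            f"f_max={f_max:g} Hz must be below the Nyquist frequency {fs / 2:g} Hz"
        )
    if n_freqs < 2:
        raise ValueError("n_freqs must be at least 2")
    k = np.arange(n_freqs)
    freqs = f_min * (f_max / f_min) ** (k / (n_freqs - 1))
    # pin the endpoints exactly; the geometric formula can drift in the last ulp
    freqs[0], freqs[-1] = f_min, f_max
    return WaveletBank(center_freqs=freqs, omega=omega, fs=fs)


def morlet_kernel(f: float, omega: float, fs: float) -> np.ndarray:
    """Sampled complex Morlet wavelet at center frequency ``f``.

    Truncated at ±5 sigma_t and scaled for unit gain: the analytic output for
    a unit-amplitude real sinusoid at ``f`` has modulus 1.  A real sinusoid
    splits its energy between ±f, and the Gaussian transfer function of the
    kernel passes essentially only the +f line, hence the factor-2 rescaling
    of the envelope sum.
    """
    sigma_t = omega / (2.0 * np.pi * f)
    half = int(np.ceil(TRUNCATION_SD * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(2j * np.pi * f * t)
    # gain at the center frequency equals the envelope sum
    return kernel * (2.0 / envelope.sum())


def wavelet_transform(signals: np.ndarray, bank: WaveletBank) -> AnalyticTensor:
    """Convolve epoched signals with the filterbank.

    Parameters
    ----------
    signals
        Real array (n_parcels, n_epochs, n_samples) or (n_parcels, n_samples)
        which is treated as a single epoch.
    bank
        The filterbank to apply.

    Returns
    -------
    AnalyticTensor
        Same-length complex output per frequency with the edge-validity mask.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 2:
        signals = signals[:, None, :]
    if signals.ndim != 3:
        raise ValueError("signals must be (parcels, epochs, samples)")
    n_parcels, n_epochs, n_samples = signals.shape

    min_len = bank.min_epoch_samples()
    if n_samples < min_len:
        raise ValueError(
            f"epoch of {n_samples} samples is too short for the "
            f"{bank.center_freqs[0]:g}-Hz wavelet; at least {min_len} samples "
            f"({min_len / bank.fs:.2f} s at fs={bank.fs:g} Hz) are required"
        )

    values = np.empty(
        (n_parcels, bank.n_freqs, n_epochs, n_samples), dtype=complex
    )
    valid = np.zeros((bank.n_freqs, n_samples), dtype=bool)

    flat = signals.reshape(n_parcels * n_epochs, n_samples)
    for fi, f in enumerate(bank.center_freqs):
        kernel = morlet_kernel(f, bank.omega, bank.fs)
        half = kernel.size // 2
        nfft = spfft.next_fast_len(n_samples + kernel.size - 1)
        spec = spfft.fft(flat, nfft, axis=-1) * spfft.fft(kernel, nfft)
        full = spfft.ifft(spec, axis=-1)
        out = full[:, half : half + n_samples]
        values[:, fi] = out.reshape(n_parcels, n_epochs, n_samples)
        valid[fi, half : n_samples - half] = True

    return AnalyticTensor(
        values=values, valid_mask=valid, fs=bank.fs, freqs=bank.center_freqs.copy()
    )


def parcel_power(analytic: AnalyticTensor, parcel_labels=None) -> PowerSpectrum:
    """Mean |z|² per parcel and frequency, over valid samples pooled across epochs."""
    counts = analytic.valid_mask.sum(axis=1)
    if np.any(counts == 0):
        bad = analytic.freqs[counts == 0]
        raise ValueError(f"no valid samples at frequencies {bad}")
    sq = np.abs(analytic.values) ** 2  # (P, F, E, T)
    masked = sq * analytic.valid_mask[None, :, None, :]
    power = masked.sum(axis=(2, 3)) / (counts[None, :] * analytic.n_epochs)
    return PowerSpectrum(
        power=power,
        freqs=analytic.freqs.copy(),
        parcel_labels=list(parcel_labels) if parcel_labels is not None else [],
    )


def global_power(spectra: np.ndarray, mode: str = "absolute") -> np.ndarray:
    """Cohort-level power summaries.

    Parameters
    ----------
    spectra
        Array (n_subjects, n_freqs) of per-subject parcel-mean power, or a
        single spectrum (n_freqs,) treated as a one-subject cohort.
    mode
        ``"absolute"`` returns the input unchanged (per-subject parcel means);
        ``"relative"`` divides each subject's value by the cohort grand mean
        at that bin, so the cohort mean of relative power is 1 at every bin.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if mode == "absolute":
        return spectra.copy()
    if mode == "relative":
        grand = spectra.mean(axis=0)
        if np.any(grand == 0):
            raise ValueError("zero grand-mean power at some frequency bin")
        return spectra / grand[None, :]
    raise ValueError(f"unknown mode {mode!r}; expected 'absolute' or 'relative'")
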