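"""Synthetic oscillatory cohorts with planted age-dependent coupling.

Each subject is a set of parcel-level time series built from a 1/f^χ
background plus band-limited oscillations.  Pairwise coupling is planted by
injecting a shared narrowband component into one parcel and a phase-lagged
copy into the other; the coupling strength κ ∈ [0, 1] is the amplitude
fraction of the shared component relative to the target parcel's independent
narrowband power, and follows a constant, linear, or quadratic (inverted-U)
profile in subject age.  The default phase lag is π/2, where the weighted
phase-lag index is maximally sensitive (it is blind to 0/π lags).

A behavioral "force overcompensation" variable can be generated as a linear
combination of z-scored age and the z-scored realized coupling of designated
target parcels, plus Gaussian noise — emulating a sensorimotor measure that
couples (typically negatively) to beta-band connectivity.

Narrowband components are synthesized by frequency-domain masking of white
noise with a Gaussian band profile, which directly yields the analytic
representation; the lagged copy is Re(z · e^{−iφ}), giving an exact,
controllable lag at band center.

Reproducibility: per-subject seeds are derived from the master seed by a
counter-based ``numpy.random.SeedSequence`` scheme, so subjects are mutually
independent yet bit-reproducible for a fixed (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "OscillationSpec",
    "CouplingSpec",
    "BehaviorSpec",
    "CohortConfig",
    "ParcelTimeSeries",
    "SourcePatch",
    "GroundTruth",
    "CohortDataset",
    "make_age_grid",
    "age_profile",
    "narrowband_analytic",
    "one_over_f_background",
    "simulate_parcel_signals",
    "simulate_cohort",
    "simulate_source_patch",
    "save_cohort",
    "load_cohort",
]

_AGE_STREAM = 1 << 20  # spawn key reserved for the age draw


@dataclass(frozen=True)
class OscillationSpec:
    """A band-limited oscillation shared by a set of parcels (independently drawn)."""

    parcels: tuple  # parcel indices
    center_freq: float  # Hz
    bandwidth: float  # Hz, FWHM-like width (Gaussian sigma = bandwidth / 2)
    amplitude: float = 1.0  # RMS in simulation units


@dataclass(frozen=True)
class CouplingSpec:
    """Planted phase-lagged coupling between two parcels.

    profile_params are (baseline κ₀, slope-or-curvature, reference age);
    realized κ is clipped to [0, 1].
    """

    parcel_i: int
    parcel_j: int
    band: tuple  # (low, high) Hz
    phase_lag: float = np.pi / 2
    profile_kind: str = "constant"  # constant | linear | quadratic
    profile_params: tuple = (0.5, 0.0, 52.5)
    subject_noise_sd: float = 0.0
    amplitude: float = 1.0  # RMS of the band component in both parcels

    def __post_init__(self) -> None:
        if not (0 < self.phase_lag < 2 * np.pi):
            raise ValueError("phase_lag must lie in (0, 2π)")

    @property
    def center_freq(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])

    @property
    def bandwidth(self) -> float:
        return self.band[1] - self.band[0]


@dataclass(frozen=True)
class BehaviorSpec:
    """Generative model of the behavioral (overcompensation) variable."""

    target_parcels: tuple
    band: tuple  # Hz
    weight_conn: float = -0.5  # negative = attenuation link
    weight_age: float = 0.3
    noise_sd: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The defaults are a desk-scale cohort (96 subjects, 12 parcels, 250 Hz,
    2 × 10-s epochs); the full-scale setting (576 subjects, 448 parcels,
    10 × 30-s epochs) remains configurable.
    """

    n_subjects: int = 96
    age_range: tuple = (18.0, 87.0)
    n_parcels: int = 12
    fs: float = 250.0
    n_epochs: int = 2
    epoch_len: float = 10.0
    background_exponent: float = 1.0
    oscillation_specs: tuple = ()
    coupling_specs: tuple = ()
    behavior_spec: BehaviorSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be ≥ 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy low < high")
        n = self.epoch_len * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_len × fs must be a whole number of samples")
        for spec in self.oscillation_specs:
            if self.fs <= 2 * spec.center_freq:
                raise ValueError(
                    f"fs={self.fs:g} Hz too low for oscillation at "
                    f"{spec.center_freq:g} Hz"
                )
        for spec in self.coupling_specs:
            if self.fs <= 2 * spec.band[1]:
                raise ValueError(
                    f"fs={self.fs:g} Hz too low for coupling band "
                    f"{spec.band[0]:g}-{spec.band[1]:g} Hz"
                )

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_len * self.fs))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        raw["age_range"] = tuple(raw.get("age_range", (18.0, 87.0)))
        raw["oscillation_specs"] = tuple(
            OscillationSpec(
                parcels=tuple(o["parcels"]),
                center_freq=float(o["center_freq"]),
                bandwidth=float(o["bandwidth"]),
                amplitude=float(o.get("amplitude", 1.0)),
            )
            for o in raw.get("oscillation_specs", [])
        )
        raw["coupling_specs"] = tuple(
            CouplingSpec(
                parcel_i=int(c["parcel_i"]),
                parcel_j=int(c["parcel_j"]),
                band=tuple(c["band"]),
                phase_lag=float(c.get("phase_lag", np.pi / 2)),
                profile_kind=c.get("profile_kind", "constant"),
                profile_params=tuple(c.get("profile_params", (0.5, 0.0, 52.5))),
                subject_noise_sd=float(c.get("subject_noise_sd", 0.0)),
                amplitude=float(c.get("amplitude", 1.0)),
            )
            for c in raw.get("coupling_specs", [])
        )
        b = raw.get("behavior_spec")
        if b is not None:
            raw["behavior_spec"] = BehaviorSpec(
                target_parcels=tuple(b["target_parcels"]),
                band=tuple(b["band"]),
                weight_conn=float(b.get("weight_conn", -0.5)),
                weight_age=float(b.get("weight_age", 0.3)),
                noise_sd=float(b.get("noise_sd", 0.5)),
            )
        return cls(**raw)


@dataclass
class ParcelTimeSeries:
    """Per-subject parcel signals: (n_parcels, n_epochs, n_samples) at fs Hz."""

    signals: np.ndarray
    fs: float
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.signals.ndim != 3:
            raise ValueError("signals must be (parcels, epochs, samples)")
        if not self.labels:
            self.labels = [f"parcel{p:03d}" for p in range(self.signals.shape[0])]


@dataclass
class SourcePatch:
    """A patch of source signals with orientations, for sign-flip testing."""

    source_signals: np.ndarray  # (n_sources, n_samples)
    orientations: np.ndarray  # (n_sources, 3), unit norm
    true_parcel_signal: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0):
            raise ValueError("orientations must be unit vectors")


@dataclass
class GroundTruth:
    """Planted generative quantities for one simulated cohort."""

    realized_kappa: dict  # coupling-spec index -> (n_subjects,) array
    ages: np.ndarray
    behavior_coefficients: dict | None
    master_seed: int
    subject_seed_keys: list


@dataclass
class CohortDataset:
    """A simulated cohort: per-subject signals, ages and optional behavior."""

    subjects: list  # of ParcelTimeSeries
    ages: np.ndarray
    overcompensation: np.ndarray | None
    fs: float
    labels: list


def make_age_grid(n_subjects: int, age_range: tuple, seed) -> np.ndarray:
    """Draw subject ages uniformly on ``age_range`` (reproducible per seed)."""
    lo, hi = age_range
    if not (n_subjects >= 1 and lo < hi):
        raise ValueError("need n_subjects ≥ 1 and age_range low < high")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=n_subjects)


def age_profile(profile_kind: str, profile_params: tuple, age) -> np.ndarray:
    """Coupling strength κ(age), clipped to [0, 1].

    constant → κ₀; linear → κ₀ + slope·(age − ref);
    quadratic → κ₀ − curvature·(age − ref)² (curvature > 0 gives an
    inverted-U peaking at the reference age).
    """
    k0, coef, ref = profile_params
    age = np.asarray(age, dtype=float)
    if profile_kind == "constant":
        kappa = np.full_like(age, k0)
    elif profile_kind == "linear":
        kappa = k0 + coef * (age - ref)
    elif profile_kind == "quadratic":
        kappa = k0 - coef * (age - ref) ** 2
    else:
        raise ValueError(f"unknown profile_kind {profile_kind!r}")
    return np.clip(kappa, 0.0, 1.0)


def narrowband_analytic(
    rng: np.random.Generator, n_samples: int, fs: float, f0: float, bandwidth: float
) -> np.ndarray:
    """Unit-RMS narrowband analytic noise centered at f0.

    White Gaussian noise is masked in the frequency domain with a Gaussian
    band profile (sigma = bandwidth / 2) on the positive frequencies only,
    which directly yields the analytic signal z(t); the real part is the
    band-limited waveform, normalized to unit RMS.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.fft(white)
    freqs = np.fft.fftfreq(n_samples, d=1.0 / fs)
    sigma_f = bandwidth / 2.0
    mask = np.where(
        freqs > 0, np.exp(-((freqs - f0) ** 2) / (2.0 * sigma_f**2)), 0.0
    )
    z = np.fft.ifft(spec * mask) * 2.0
    rms = np.sqrt(np.mean(z.real**2))
    if rms == 0:
        raise ValueError("degenerate narrowband draw (zero power)")
    return z / rms


def one_over_f_background(
    rng: np.random.Generator, n_samples: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-RMS real noise with power spectral density ∝ 1/f^exponent."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples)
    return x / np.std(x)


def simulate_parcel_signals(
    config: CohortConfig, age: float, subject_seed
) -> tuple[ParcelTimeSeries, dict]:
    """Simulate one subject's parcel signals.

    Returns the ParcelTimeSeries and the realized κ per coupling-spec index.
    Each parcel carries a 1/f^χ background plus its oscillation components;
    each coupled pair shares a narrowband component whose phase-lagged copy
    is injected into parcel_j with amplitude fraction κ(age).
    """
    rng = np.random.default_rng(subject_seed)
    n_total = config.n_epochs * config.epoch_samples
    signals = np.empty((config.n_parcels, n_total))
    for p in range(config.n_parcels):
        signals[p] = one_over_f_background(
            rng, n_total, config.fs, config.background_exponent
        )
    for spec in config.oscillation_specs:
        for p in spec.parcels:
            z = narrowband_analytic(
                rng, n_total, config.fs, spec.center_freq, spec.bandwidth
            )
            signals[p] += spec.amplitude * z.real

    realized = {}
    for ci, spec in enumerate(config.coupling_specs):
        kappa = float(age_profile(spec.profile_kind, spec.profile_params, age))
        if spec.subject_noise_sd > 0:
            kappa += spec.subject_noise_sd * rng.standard_normal()
        kappa = float(np.clip(kappa, 0.0, 1.0))
        realized[ci] = kappa
        shared = narrowband_analytic(
            rng, n_total, config.fs, spec.center_freq, spec.bandwidth
        )
        indep = narrowband_analytic(
            rng, n_total, config.fs, spec.center_freq, spec.bandwidth
        )
        lagged = (shared * np.exp(-1j * spec.phase_lag)).real
        signals[spec.parcel_i] += spec.amplitude * shared.real
        signals[spec.parcel_j] += spec.amplitude * (
            np.sqrt(max(0.0, 1.0 - kappa**2)) * indep.real + kappa * lagged
        )

    epoched = signals.reshape(
        config.n_parcels, config.n_epochs, config.epoch_samples
    )
    return ParcelTimeSeries(signals=epoched, fs=config.fs), realized


def _subject_seed(master_seed: int, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(k,))


def simulate_cohort(config: CohortConfig) -> tuple[CohortDataset, GroundTruth]:
    """Simulate a full cohort with ages, signals and optional behavior."""
    ages = make_age_grid(
        config.n_subjects,
        config.age_range,
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_AGE_STREAM,)),
    )
    subjects = []
    realized = {ci: np.empty(config.n_subjects) for ci in range(len(config.coupling_specs))}
    seed_keys = []
    for k in range(config.n_subjects):
        ss = _subject_seed(config.seed, k)
        seed_keys.append(k)
        pts, kappas = simulate_parcel_signals(config, ages[k], ss)
        subjects.append(pts)
        for ci, kv in kappas.items():
            realized[ci][k] = kv

    overcomp = None
    behavior_coeffs = None
    if config.behavior_spec is not None:
        b = config.behavior_spec
        targets = [
            ci
            for ci, spec in enumerate(config.coupling_specs)
            if (spec.parcel_i in b.target_parcels or spec.parcel_j in b.target_parcels)
            and spec.band[0] < b.band[1]
            and spec.band[1] > b.band[0]
        ]
        if not targets:
            raise ValueError(
                "behavior_spec targets no coupling spec (check parcels/band)"
            )
        kappa_target = np.mean([realized[ci] for ci in targets], axis=0)
        rng_b = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(_AGE_STREAM + 1,))
        )
        overcomp = (
            b.weight_age * _zscore_safe(ages)
            + b.weight_conn * _zscore_safe(kappa_target)
            + b.noise_sd * rng_b.standard_normal(config.n_subjects)
        )
        behavior_coeffs = {
            "weight_age": b.weight_age,
            "weight_conn": b.weight_conn,
            "noise_sd": b.noise_sd,
            "target_coupling_specs": targets,
        }

    labels = subjects[0].labels if subjects else []
    dataset = CohortDataset(
        subjects=subjects,
        ages=ages,
        overcompensation=overcomp,
        fs=config.fs,
        labels=labels,
    )
    truth = GroundTruth(
        realized_kappa=realized,
        ages=ages.copy(),
        behavior_coefficients=behavior_coeffs,
        master_seed=config.seed,
        subject_seed_keys=seed_keys,
    )
    return dataset, truth


def _zscore_safe(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def simulate_source_patch(
    n_sources: int,
    flip_fraction: float,
    parcel_signal: np.ndarray,
    noise_sd: float,
    seed,
) -> SourcePatch:
    """Build a source patch around one true parcel signal.

    A fraction of the sources is "flipped": their orientation points more
    than 90° away from the dominant direction and their signal is negated —
    the situation sign-flip averaging is designed to undo.
    """
    if not (0 <= flip_fraction < 1):
        raise ValueError("flip_fraction must lie in [0, 1)")
    if flip_fraction >= 0.5:
        warnings.warn(
            "flip_fraction ≥ 0.5: the dominant direction is ill-defined"
        )
    rng = np.random.default_rng(seed)
    parcel_signal = np.asarray(parcel_signal, dtype=float)
    n_flip = int(round(flip_fraction * n_sources))
    base = np.array([0.0, 0.0, 1.0])
    signals = np.empty((n_sources, parcel_signal.size))
    orientations = np.empty((n_sources, 3))
    for s in range(n_sources):
        jitter = 0.3 * rng.standard_normal(3)
        v = base + jitter
        v /= np.linalg.norm(v)
        if v @ base <= 0:  # keep unflipped sources within 90° of the axis
            v = base.copy()
        flipped = s < n_flip
        orientations[s] = -v if flipped else v
        sgn = -1.0 if flipped else 1.0
        signals[s] = sgn * parcel_signal + noise_sd * rng.standard_normal(
            parcel_signal.size
        )
    return SourcePatch(
        source_signals=signals,
        orientations=orientations,
        true_parcel_signal=parcel_signal.copy(),
    )


# ---------------------------------------------------------------------------
# persistence: HDF5 container + TSV manifest
# ---------------------------------------------------------------------------

def save_cohort(path, dataset: CohortDataset, truth: GroundTruth | None = None) -> None:
    """Write a cohort to one HDF5 file, with a sidecar TSV manifest."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["fs"] = dataset.fs
        h5.attrs["labels"] = [str(x) for x in dataset.labels]
        grp = h5.create_group("subjects")
        for k, subj in enumerate(dataset.subjects):
            g = grp.create_group(f"{k:04d}")
            g.create_dataset("signals", data=subj.signals)
            g.create_dataset("age", data=dataset.ages[k])
            if dataset.overcompensation is not None:
                g.create_dataset(
                    "overcompensation", data=dataset.overcompensation[k]
                )
        if truth is not None:
            gt = h5.create_group("ground_truth")
            gt.attrs["master_seed"] = truth.master_seed
            gt.create_dataset("ages", data=truth.ages)
            for ci, arr in truth.realized_kappa.items():
                gt.create_dataset(f"realized_kappa_{ci}", data=arr)

    rows = ["subject_id\tage\tovercompensation"]
    for k in range(len(dataset.subjects)):
        oc = (
            f"{dataset.overcompensation[k]:.6f}"
            if dataset.overcompensation is not None
            else "NA"
        )
        rows.append(f"{k:04d}\t{dataset.ages[k]:.4f}\t{oc}")
    path.with_suffix(path.suffix + ".manifest.tsv").write_text("\n".join(rows) + "\n")


def load_cohort(path) -> CohortDataset:
    """Read a cohort previously written by :func:`save_cohort`."""
    import h5py

    with h5py.File(path, "r") as h5:
        fs = float(h5.attrs["fs"])
        labels = [str(x) for x in h5.attrs["labels"]]
        ids = sorted(h5["subjects"].keys())
        subjects, ages, overcomp = [], [], []
        has_oc = True
        for sid in ids:
            g = h5["subjects"][sid]
            subjects.append(
                ParcelTimeSeries(signals=g["signals"][()], fs=fs, labels=labels)
            )
            ages.append(float(g["age"][()]))
            if "overcompensation" in g:
                overcomp.append(float(g["overcompensation"][()]))
            else:
                has_oc = False
    return CohortDataset(
        subjects=subjects,
        ages=np.array(ages),
        overcompensation=np.array(overcomp) if has_oc and overcomp else None,
        fs=fs,
        labels=labels,
    )
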