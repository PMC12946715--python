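"""Frozen study conditions for planted-effect recovery experiments.

These factory functions define the reference synthetic-cohort conditions the
package's validation experiments run under: desk-scale cohorts (120 subjects,
12 parcels, 250 Hz, 2 × 10-s epochs) with a known effect planted on six
disjoint parcel pairs.  Planting the same profile on several edges mirrors
the mass-univariate setting the statistics are built for — with a single
true edge in a 66-edge FDR pool, the add-one permutation floor and the
Benjamini–Hochberg rank would make the minimum attainable adjusted p
``m / (n_permutations + 1)``, so several true units must share the pool for
the correction to behave as it does at full scale.

The planted parameter values are fixed here, once, as the generative
conditions of the experiments; they are chosen for detectability at desk
scale (the coupling-to-WPLI mapping attenuates a planted correlation by
roughly 10% under these conditions — see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .cohort import BehaviorSpec, CohortConfig, CouplingSpec
from .connectivity import band_average, wpli
from .filterbank import make_filterbank, wavelet_transform

__all__ = [
    "PLANTED_PAIRS",
    "linear_recovery_config",
    "inverted_u_config",
    "behavior_dissociation_config",
    "null_config",
    "band_bank",
    "band_edge_wpli",
]

#: six disjoint parcel pairs covering all 12 desk-scale parcels
PLANTED_PAIRS: tuple = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11))

#: linear condition — κ(age) = 0.35 + 0.00281·(age − 52.5) plus N(0, 0.128²)
#: subject noise: population corr(age, κ) ≈ 0.40 over a uniform 18–87 cohort
LINEAR_PROFILE = (0.35, 0.00281, 52.5)
LINEAR_NOISE_SD = 0.128
LINEAR_BAND = (8.0, 13.0)  # alpha

#: inverted-U condition — κ(age) = 0.62 − 2.5e-4·(age − 52.5)², peaking at
#: mid-age, planted inside the beta band
QUADRATIC_PROFILE = (0.62, 2.5e-4, 52.5)
QUADRATIC_NOISE_SD = 0.06
QUADRATIC_BAND = (16.0, 26.0)

COUPLING_AMPLITUDE = 1.5


def linear_recovery_config(seed: int, n_subjects: int = 120, n_parcels: int = 12) -> CohortConfig:
    """Cohort with a linearly age-increasing alpha coupling on six edges."""
    specs = tuple(
        CouplingSpec(i, j, LINEAR_BAND, profile_kind="linear",
                     profile_params=LINEAR_PROFILE,
                     subject_noise_sd=LINEAR_NOISE_SD,
                     amplitude=COUPLING_AMPLITUDE)
        for i, j in PLANTED_PAIRS
    )
    return CohortConfig(n_subjects=n_subjects, n_parcels=n_parcels, seed=seed,
                        coupling_specs=specs)


def inverted_u_config(seed: int, n_subjects: int = 120, n_parcels: int = 12) -> CohortConfig:
    """Cohort with an inverted-U (mid-age peak) beta coupling on six edges."""
    specs = tuple(
        CouplingSpec(i, j, QUADRATIC_BAND, profile_kind="quadratic",
                     profile_params=QUADRATIC_PROFILE,
                     subject_noise_sd=QUADRATIC_NOISE_SD,
                     amplitude=COUPLING_AMPLITUDE)
        for i, j in PLANTED_PAIRS
    )
    return CohortConfig(n_subjects=n_subjects, n_parcels=n_parcels, seed=seed,
                        coupling_specs=specs)


def behavior_dissociation_config(seed: int, n_subjects: int = 120) -> CohortConfig:
    """Cohort dissociating behavioral from age effects on beta connectivity.

    Parcels 0–3 carry beta couplings that vary across subjects independently
    of age and drive the overcompensation variable negatively; parcels 6–9
    carry beta couplings with a linear age profile and no behavioral link.
    """
    band = QUADRATIC_BAND
    specs = (
        CouplingSpec(0, 1, band, profile_kind="constant",
                     profile_params=(0.45, 0.0, 52.5),
                     subject_noise_sd=0.14, amplitude=COUPLING_AMPLITUDE),
        CouplingSpec(2, 3, band, profile_kind="constant",
                     profile_params=(0.45, 0.0, 52.5),
                     subject_noise_sd=0.14, amplitude=COUPLING_AMPLITUDE),
        CouplingSpec(6, 7, band, profile_kind="linear",
                     profile_params=LINEAR_PROFILE,
                     subject_noise_sd=0.05, amplitude=COUPLING_AMPLITUDE),
        CouplingSpec(8, 9, band, profile_kind="linear",
                     profile_params=LINEAR_PROFILE,
                     subject_noise_sd=0.05, amplitude=COUPLING_AMPLITUDE),
    )
    behavior = BehaviorSpec(target_parcels=(0, 1, 2, 3), band=band,
                            weight_conn=-0.85, weight_age=0.25, noise_sd=0.3)
    return CohortConfig(n_subjects=n_subjects, n_parcels=12, seed=seed,
                        coupling_specs=specs, behavior_spec=behavior)


def null_config(seed: int, n_subjects: int = 120, n_parcels: int = 12) -> CohortConfig:
    """Cohort with no planted effects (pure 1/f background)."""
    return CohortConfig(n_subjects=n_subjects, n_parcels=n_parcels, seed=seed)


def band_bank(band: tuple, fs: float = 250.0, n_freqs: int = 4):
    """A small analytic bank restricted to one frequency band.

    For single-band recovery experiments a 4-bin bank spanning just the
    analyzed band replaces the full 32-bin 1–100-Hz grid; band membership
    and pooling are unchanged, only unanalyzed bins are dropped.
    """
    return make_filterbank(band[0], band[1], n_freqs, 5.0, fs)


def band_edge_wpli(dataset, band: tuple, bank=None) -> tuple[np.ndarray, list]:
    """Per-subject band-averaged WPLI for every edge.

    Returns an (n_subjects, n_edges) stack in upper-triangle order and the
    corresponding (i, j) edge list.
    """
    if bank is None:
        bank = band_bank(band, dataset.fs)
    n_parcels = dataset.subjects[0].signals.shape[0]
    iu = np.triu_indices(n_parcels, k=1)
    edges = np.empty((len(dataset.subjects), iu[0].size))
    for k, subj in enumerate(dataset.subjects):
        analytic = wavelet_transform(subj.signals, bank)
        mat = band_average(wpli(analytic), band)
        edges[k] = mat.weights[iu]
    return edges, list(zip(iu[0].tolist(), iu[1].tolist()))
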