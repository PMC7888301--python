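"""Synthetic multi-participant EEG data with planted structure.

The generator emulates the statistical situation the stratified
normalization method targets: a modest emotion-dependent shift in a
subset of channel-band features, masked by much larger
participant-and-session-specific nuisance. Nuisance is affine within
each (participant, session) stratum — a per-feature gain and offset held
constant across that stratum's trials — which is exactly the structure
per-stratum normalization can remove, so the method's claimed advantage
becomes a testable property of the generated data.

Two entry points:

* :func:`generate_feature_table` plants the structure directly in
  feature space:  x_ijk = a_ik · (base_k + effect_jk + noise) + b_ik.
* :func:`generate_dataset` produces raw multichannel trials as sums of
  band-limited Gaussian processes whose per-band variances follow the
  same scheme (multiplicatively, in log-variance space, since a signal
  variance cannot be offset additively), so that feature extraction
  approximately recovers the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import BANDS, bandpass, feature_names
from .io import EEGDataset, FeatureTable, TrialRecord

__all__ = ["GenConfig", "GroundTruth", "generate_feature_table", "generate_dataset"]

N_CLASSES = 3


@dataclass(frozen=True)
class GenConfig:
    """Generator settings.

    Defaults mirror the SEED layout: 15 participants x 3 sessions x 15
    trials of 62-channel EEG at 200 Hz, labels balanced across the three
    emotion classes within every session. ``emotion_effect`` is the
    standardized mean shift per adjacent class (in units of the
    trial-to-trial noise SD); the per-stratum gain range and offset SD
    default to nuisance that dominates the emotion signal.
    """

    n_participants: int = 15
    n_sessions: int = 3
    n_trials_per_session: int = 15
    n_channels: int = 62
    fs: float = 200.0
    trial_s: float = 10.0
    emotion_effect: float = 1.0
    affected_fraction: float = 0.25
    participant_gain_range: tuple[float, float] = (0.5, 2.0)
    participant_offset_sd: float = 2.0
    spectral_tilt_sd: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_session % N_CLASSES:
            raise ValueError(
                "n_trials_per_session must be a multiple of 3 so classes "
                "balance within each session"
            )
        lo, hi = self.participant_gain_range
        if not (0 < lo <= hi):
            raise ValueError("gains must be positive with lo <= hi")
        if min(self.participant_offset_sd, self.spectral_tilt_sd, self.noise_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if self.emotion_effect > 0 and self.affected_fraction <= 0:
            raise ValueError(
                "emotion_effect > 0 requires affected_fraction > 0"
            )
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in [0, 1]")


def mini_config(**overrides) -> GenConfig:
    """Small preset (6 participants x 2 sessions x 6 trials, 8 channels)
    for fast end-to-end runs."""
    base = GenConfig(
        n_participants=6,
        n_sessions=2,
        n_trials_per_session=6,
        n_channels=8,
        fs=128.0,
        trial_s=5.0,
    )
    return replace(base, **overrides)


def seed_like_config(**overrides) -> GenConfig:
    """Full-size preset matching the SEED layout."""
    return replace(GenConfig(), **overrides)


@dataclass
class GroundTruth:
    """What was planted: which features carry signal and the nuisance."""

    affected_features: np.ndarray  # column indices
    effect_signs: np.ndarray  # +-1 per affected column
    gains: np.ndarray  # (n_strata, n_features)
    offsets: np.ndarray  # (n_strata, n_features)
    stratum_ids: np.ndarray  # (n_strata, 2) participant, session


def _balanced_labels(rng, n_trials: int) -> np.ndarray:
    labels = np.repeat(np.arange(N_CLASSES), n_trials // N_CLASSES)
    return rng.permutation(labels)


def _layout(g: GenConfig):
    """Row-wise participant/session/trial indices, 1-based."""
    rows = [
        (p + 1, s + 1, t + 1)
        for p in range(g.n_participants)
        for s in range(g.n_sessions)
        for t in range(g.n_trials_per_session)
    ]
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def generate_feature_table(g: GenConfig) -> tuple[FeatureTable, GroundTruth]:
    """Plant emotion effects plus per-stratum affine nuisance in feature space."""
    rng = np.random.default_rng(g.seed)
    n_features = g.n_channels * len(BANDS)
    n_strata = g.n_participants * g.n_sessions
    participants, sessions, trials = _layout(g)

    n_affected = int(round(g.affected_fraction * n_features))
    affected = rng.choice(n_features, size=n_affected, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_affected)
    base = rng.normal(5.0, 1.0, size=n_features)

    lo, hi = g.participant_gain_range
    gains = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=(n_strata, n_features))
    )
    offsets = rng.normal(0.0, g.participant_offset_sd, size=(n_strata, n_features))

    labels = np.concatenate(
        [
            _balanced_labels(rng, g.n_trials_per_session)
            for _ in range(n_strata)
        ]
    )
    shift = np.zeros((len(labels), n_features))
    shift[:, affected] = (
        g.emotion_effect * g.noise_sd * (labels[:, None] - 1.0) * signs[None, :]
    )
    noise = rng.normal(0.0, g.noise_sd, size=(len(labels), n_features))
    clean = base[None, :] + shift + noise

    stratum_row = (participants - 1) * g.n_sessions + (sessions - 1)
    X = gains[stratum_row] * clean + offsets[stratum_row]

    table = FeatureTable(
        X=X,
        participants=participants,
        sessions=sessions,
        trials=trials,
        labels=labels,
        feature_names=feature_names(g.n_channels),
    )
    table.validate()
    truth = GroundTruth(
        affected_features=affected,
        effect_signs=signs,
        gains=gains,
        offsets=offsets,
        stratum_ids=np.stack(
            [np.repeat(np.arange(g.n_participants) + 1, g.n_sessions),
             np.tile(np.arange(g.n_sessions) + 1, g.n_participants)],
            axis=1,
        ),
    )
    return table, truth


def _band_limited_noise(rng, n_samples, fs, band):
    """Unit-variance Gaussian noise confined to one band."""
    white = rng.standard_normal(n_samples)
    filtered = bandpass(white, fs, band)
    sd = filtered.std()
    return filtered / sd if sd > 0 else filtered


def generate_dataset(g: GenConfig) -> EEGDataset:
    """Raw-signal counterpart of :func:`generate_feature_table`.

    Each trial channel is a sum over the four analysis bands of
    band-limited Gaussian noise. Planted log-variances follow
    base + emotion shift + trial noise; nuisance enters as a per-stratum
    per-channel gain, a spectral tilt (per-stratum log-variance slope
    across bands), and a DC offset.
    """
    if g.fs < 128:
        raise ValueError("raw-signal generation needs fs >= 128 Hz")
    n_samples = int(round(g.trial_s * g.fs))
    min_len = int(g.fs)  # >= 1 s so Welch windows and DPSS tapers fit
    if n_samples < min_len:
        raise ValueError(f"trial_s={g.trial_s} too short at fs={g.fs}")
    rng = np.random.default_rng(g.seed)
    n_bands = len(BANDS)
    n_feat = g.n_channels * n_bands

    n_affected = int(round(g.affected_fraction * n_feat))
    affected = rng.choice(n_feat, size=n_affected, replace=False)
    signs = np.zeros(n_feat)
    signs[affected] = rng.choice([-1.0, 1.0], size=n_affected)
    base_logvar = rng.normal(0.0, 0.3, size=(g.n_channels, n_bands))
    band_centers = np.linspace(-1.0, 1.0, n_bands)

    lo, hi = g.participant_gain_range
    trials: list[TrialRecord] = []
    for p in range(1, g.n_participants + 1):
        for s in range(1, g.n_sessions + 1):
            gain_c = np.exp(
                rng.uniform(np.log(lo), np.log(hi), size=g.n_channels)
            )
            dc = rng.normal(0.0, g.participant_offset_sd, size=g.n_channels)
            tilt = rng.normal(0.0, g.spectral_tilt_sd)
            labels = _balanced_labels(rng, g.n_trials_per_session)
            for t, label in enumerate(labels, start=1):
                shift = (
                    g.emotion_effect
                    * (label - 1.0)
                    * signs.reshape(g.n_channels, n_bands)
                )
                jitter = rng.normal(
                    0.0, 0.1 * g.noise_sd, size=(g.n_channels, n_bands)
                )
                logvar = (
                    base_logvar + shift + jitter + tilt * band_centers[None, :]
                )
                sig = np.zeros((g.n_channels, n_samples))
                for c in range(g.n_channels):
                    for b, band in enumerate(BANDS):
                        sig[c] += np.sqrt(np.exp(logvar[c, b])) * _band_limited_noise(
                            rng, n_samples, g.fs, band
                        )
                sig = gain_c[:, None] * sig + dc[:, None]
                trials.append(
                    TrialRecord(
                        participant=p,
                        session=s,
                        trial=t,
                        label=int(label),
                        signal=sig.astype(np.float32),
                    )
                )
    out = EEGDataset(fs=g.fs, n_channels=g.n_channels, trials=trials)
    out.validate()
    return out
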