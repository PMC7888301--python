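"""Dataset and feature-table containers with HDF5/CSV (de)serialization.

Two on-disk formats are defined here:

* an HDF5 container for raw multichannel trials, laid out as
  ``/p<pp>/s<ss>/t<tt>/signal`` (float32, channels x samples) with the
  emotion code stored in a ``label`` attribute and the sampling rate /
  channel count stored as root attributes, and
* a plain CSV feature table with ``participant,session,trial,label``
  metadata columns followed by one column per channel-band feature.

Participant/session/trial indices are 1-based on disk (matching the
conventional s01..s15 participant numbering of multi-session EEG corpora)
and kept 1-based in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "EEGDataset",
    "FeatureTable",
    "FormatError",
    "DataError",
    "read_dataset",
    "write_dataset",
    "read_feature_table",
    "write_feature_table",
]

#: Emotion codes used throughout the package.
LABEL_NEGATIVE, LABEL_NEUTRAL, LABEL_POSITIVE = 0, 1, 2
VALID_LABELS = (LABEL_NEGATIVE, LABEL_NEUTRAL, LABEL_POSITIVE)

#: Upper edge of the highest analysis band (gamma), Hz. The sampling rate
#: must keep this below Nyquist.
_MAX_BAND_HZ = 50.0


class FormatError(ValueError):
    """A file or table does not follow the expected layout."""


class DataError(ValueError):
    """A file follows the layout but its contents violate an invariant."""


@dataclass
class TrialRecord:
    """One trial: a channels-by-samples signal with its emotion label."""

    participant: int
    session: int
    trial: int
    label: int
    signal: np.ndarray  # (n_channels, n_samples)

    def validate(self, fs: float) -> None:
        sig = np.asarray(self.signal)
        if sig.ndim != 2:
            raise DataError(
                f"trial ({self.participant},{self.session},{self.trial}): "
                f"signal must be 2-D, got shape {sig.shape}"
            )
        if sig.shape[1] < fs:
            raise DataError(
                f"trial ({self.participant},{self.session},{self.trial}): "
                f"shorter than 1 s ({sig.shape[1]} samples at fs={fs})"
            )
        if not np.isfinite(sig).all():
            raise DataError(
                f"trial ({self.participant},{self.session},{self.trial}): "
                "non-finite values in signal"
            )
        if self.label not in VALID_LABELS:
            raise DataError(
                f"trial ({self.participant},{self.session},{self.trial}): "
                f"label {self.label} not in {VALID_LABELS}"
            )


@dataclass
class EEGDataset:
    """A collection of trials indexed by (participant, session, trial).

    All trials share the sampling rate ``fs`` and channel count
    ``n_channels``; per-trial durations may differ (film-clip stimuli are
    not equal length).
    """

    fs: float
    n_channels: int
    trials: list[TrialRecord] = field(default_factory=list)

    @property
    def participants(self) -> list[int]:
        return sorted({t.participant for t in self.trials})

    def validate(self) -> None:
        if not self.trials:
            raise DataError("dataset contains no trials")
        if self.fs < 2 * _MAX_BAND_HZ:
            raise DataError(
                f"fs={self.fs} Hz puts the {_MAX_BAND_HZ} Hz gamma edge at or "
                "above Nyquist"
            )
        seen: set[tuple[int, int, int]] = set()
        for t in self.trials:
            key = (t.participant, t.session, t.trial)
            if key in seen:
                raise DataError(f"duplicate trial index {key}")
            seen.add(key)
            if t.signal.shape[0] != self.n_channels:
                raise DataError(
                    f"trial {key}: {t.signal.shape[0]} channels, dataset "
                    f"declares {self.n_channels}"
                )
            t.validate(self.fs)

    def iter_sorted(self):
        return sorted(
            self.trials, key=lambda t: (t.participant, t.session, t.trial)
        )


@dataclass
class FeatureTable:
    """Trials-by-features matrix with stratum metadata.

    A *stratum* is one (participant, session) pair; all normalization
    statistics in stratified mode are computed within strata.
    """

    X: np.ndarray  # (n_rows, n_features) float64
    participants: np.ndarray  # (n_rows,) int
    sessions: np.ndarray  # (n_rows,) int
    trials: np.ndarray  # (n_rows,) int
    labels: np.ndarray  # (n_rows,) int
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def strata(self) -> np.ndarray:
        """Integer stratum id per row (dense encoding of (participant, session))."""
        pairs = np.stack([self.participants, self.sessions], axis=1)
        _, inverse = np.unique(pairs, axis=0, return_inverse=True)
        return inverse

    def validate(self) -> None:
        if self.X.ndim != 2:
            raise FormatError("X must be 2-D")
        n = self.X.shape[0]
        for name, col in (
            ("participants", self.participants),
            ("sessions", self.sessions),
            ("trials", self.trials),
            ("labels", self.labels),
        ):
            if len(col) != n:
                raise FormatError(f"{name} length {len(col)} != {n} rows")
        if len(self.feature_names) != self.X.shape[1]:
            raise FormatError(
                f"{len(self.feature_names)} feature names for "
                f"{self.X.shape[1]} feature columns"
            )
        if not np.isfinite(self.X).all():
            raise DataError("non-finite feature values")
        keys = list(zip(self.participants, self.sessions, self.trials))
        if len(set(keys)) != len(keys):
            raise DataError("duplicate (participant, session, trial) rows")
        _, counts = np.unique(self.strata, return_counts=True)
        if (counts < 2).any():
            raise DataError(
                "every (participant, session) stratum needs >= 2 rows for "
                "its variance to be defined"
            )

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            X=self.X[mask],
            participants=self.participants[mask],
            sessions=self.sessions[mask],
            trials=self.trials[mask],
            labels=self.labels[mask],
            feature_names=list(self.feature_names),
        )


def write_dataset(d: EEGDataset, path) -> None:
    """Write ``d`` to an HDF5 container (signals stored as float32)."""
    d.validate()
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(d.fs)
        f.attrs["n_channels"] = int(d.n_channels)
        for t in d.iter_sorted():
            grp = f.require_group(
                f"p{t.participant:02d}/s{t.session:02d}/t{t.trial:02d}"
            )
            ds = grp.create_dataset(
                "signal", data=np.asarray(t.signal, dtype=np.float32)
            )
            ds.attrs["label"] = int(t.label)


def read_dataset(path) -> EEGDataset:
    """Read and validate an HDF5 container written by :func:`write_dataset`."""
    trials: list[TrialRecord] = []
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs or "n_channels" not in f.attrs:
            raise FormatError("missing root attributes 'fs' / 'n_channels'")
        fs = float(f.attrs["fs"])
        n_channels = int(f.attrs["n_channels"])
        for pname in sorted(f.keys()):
            if not (pname.startswith("p") and pname[1:].isdigit()):
                raise FormatError(f"unexpected root group {pname!r}")
            pgrp = f[pname]
            for sname in sorted(pgrp.keys()):
                if not (sname.startswith("s") and sname[1:].isdigit()):
                    raise FormatError(f"unexpected group {pname}/{sname!r}")
                sgrp = pgrp[sname]
                for tname in sorted(sgrp.keys()):
                    if not (tname.startswith("t") and tname[1:].isdigit()):
                        raise FormatError(
                            f"unexpected group {pname}/{sname}/{tname!r}"
                        )
                    tgrp = sgrp[tname]
                    if "signal" not in tgrp:
                        raise FormatError(
                            f"{pname}/{sname}/{tname} has no 'signal' dataset"
                        )
                    ds = tgrp["signal"]
                    if "label" not in ds.attrs:
                        raise FormatError(
                            f"{pname}/{sname}/{tname}/signal has no 'label'"
                        )
                    trials.append(
                        TrialRecord(
                            participant=int(pname[1:]),
                            session=int(sname[1:]),
                            trial=int(tname[1:]),
                            label=int(ds.attrs["label"]),
                            signal=ds[...],
                        )
                    )
    out = EEGDataset(fs=fs, n_channels=n_channels, trials=trials)
    out.validate()
    return out


_META_COLS = ["participant", "session", "trial", "label"]


def write_feature_table(t: FeatureTable, path) -> None:
    """Write a feature table as CSV (17 significant digits, '.' decimal)."""
    t.validate()
    meta = pd.DataFrame(
        {
            "participant": t.participants,
            "session": t.sessions,
            "trial": t.trials,
            "label": t.labels,
        }
    )
    feats = pd.DataFrame(t.X, columns=t.feature_names, index=meta.index)
    pd.concat([meta, feats], axis=1).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_feature_table(path) -> FeatureTable:
    """Read and validate a feature-table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"missing metadata columns {missing}")
    feature_names = [c for c in df.columns if c not in _META_COLS]
    if not feature_names:
        raise FormatError("no feature columns")
    out = FeatureTable(
        X=df[feature_names].to_numpy(dtype=np.float64),
        participants=df["participant"].to_numpy(dtype=np.int64),
        sessions=df["session"].to_numpy(dtype=np.int64),
        trials=df["trial"].to_numpy(dtype=np.int64),
        labels=df["label"].to_numpy(dtype=np.int64),
        feature_names=feature_names,
    )
    out.validate()
    return out
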