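"""Reading, resampling and montaging of multi-channel scalp EEG recordings.

A :class:`Recording` holds per-channel amplitude series in microvolts plus an
optional annotation marking the end of postictal generalized EEG suppression
(PGES) in seconds from recording start. Raw recordings use 13 scalp
electrodes of the 10-20 system; analysis operates on the 10-channel
longitudinal bipolar montage (FP1-F7, F7-T7, ..., Cz-Pz), where each montage
channel is referred to by its first electrode.

Supported on-disk forms:

* EDF (European Data Format), read through mne; an optional sidecar
  ``<stem>.pges.tsv`` (two columns: patient_id, pges_end_s) carries the
  annotation.
* a plain CSV dialect: one header row of channel names, one column per
  channel, amplitudes in microvolts, with a ``<stem>.meta.json`` sidecar
  holding the sampling rate, patient id and annotation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.signal

from .errors import ArgumentError, FormatError, MontageError, SchemaError

#: Canonical order of the 10 bipolar channels (named by first electrode).
#: Every downstream feature index is defined relative to this order.
CANONICAL_CHANNELS: Tuple[str, ...] = (
    "FP1", "F7", "T7", "P7", "FP2", "F8", "T8", "P8", "Fz", "Cz",
)


@dataclass
class Recording:
    """A multi-channel EEG recording in microvolts.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered electrode (raw) or derivation (montaged) labels; unique.
    patient_id : str
        Opaque identifier.
    pges_end_s : float or None
        End-of-PGES annotation, seconds from recording start; None when the
        recording carries no PGES annotation.
    """

    samples: np.ndarray
    fs: float
    channel_names: Tuple[str, ...]
    patient_id: str = ""
    pges_end_s: Optional[float] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise SchemaError("samples must be a 2-D (channels x time) array")
        if len(self.channel_names) != self.samples.shape[0]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SchemaError("channel names must be unique")
        if not self.fs > 0:
            raise ArgumentError("sampling rate must be positive")
        if self.pges_end_s is not None and not (
            0.0 <= self.pges_end_s <= self.duration_s
        ):
            raise ArgumentError(
                f"pges_end_s={self.pges_end_s} outside [0, {self.duration_s}]"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's series; electrode lookup is case-insensitive."""
        lowered = {c.lower(): i for i, c in enumerate(self.channel_names)}
        try:
            return self.samples[lowered[name.lower()]]
        except KeyError:
            raise MontageError(f"electrode {name!r} not present in recording")


@dataclass(frozen=True)
class BipolarMontage:
    """An ordered set of bipolar derivations (anode minus cathode)."""

    derivations: Tuple[Tuple[str, str], ...]

    @property
    def short_names(self) -> Tuple[str, ...]:
        """First electrode of each pair — the conventional channel alias."""
        return tuple(a for a, _ in self.derivations)


#: The 10-channel longitudinal bipolar montage used throughout.
DEFAULT_MONTAGE = BipolarMontage(derivations=(
    ("FP1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
    ("FP2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
))

assert DEFAULT_MONTAGE.short_names == CANONICAL_CHANNELS


def apply_montage(rec: Recording, montage: BipolarMontage = DEFAULT_MONTAGE) -> Recording:
    """Derive bipolar channels: channel i = anode_i - cathode_i, samplewise.

    The result's channel names are the montage's short names (first
    electrodes) and the annotation is carried over unchanged.
    """
    rows = [rec.channel(a) - rec.channel(b) for a, b in montage.derivations]
    return Recording(
        samples=np.vstack(rows),
        fs=rec.fs,
        channel_names=montage.short_names,
        patient_id=rec.patient_id,
        pges_end_s=rec.pges_end_s,
    )


def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Resample to ``target_fs`` Hz by Fourier-domain (frequency) resampling.

    The output length is round(n_in * target_fs / fs_in); annotation times in
    seconds are unchanged. Frequency content below the smaller Nyquist rate is
    preserved.
    """
    if not target_fs > 0:
        raise ArgumentError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    out = scipy.signal.resample(rec.samples, n_out, axis=1)
    return replace(rec, samples=out, fs=float(target_fs))


# ---------------------------------------------------------------------------
# File I/O


def _csv_sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _edf_sidecar(path: Path) -> Path:
    return path.with_suffix(".pges.tsv")


def read_recording(path, format: Optional[str] = None) -> Recording:
    """Read a recording from ``path`` in EDF or the package's CSV dialect.

    ``format`` defaults to the file extension. Amplitudes are returned in
    microvolts; the annotation is taken from the sidecar when present.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        return _read_edf(path)
    if format == "csv":
        return _read_csv(path)
    raise ArgumentError(f"unknown recording format {format!r}")


def _read_edf(path: Path) -> Recording:
    import mne

    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    if not raw.ch_names or any(not c for c in raw.ch_names):
        raise SchemaError(f"{path}: missing channel labels")
    samples = raw.get_data() * 1e6  # mne returns volts
    patient = (raw.info.get("subject_info") or {}).get("his_id", "") or path.stem
    pges_end = None
    sidecar = _edf_sidecar(path)
    if sidecar.exists():
        ann = pd.read_csv(sidecar, sep="\t")
        if len(ann):
            pges_end = float(ann["pges_end_s"].iloc[0])
            patient = str(ann["patient_id"].iloc[0])
    return Recording(
        samples=samples,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        patient_id=patient,
        pges_end_s=pges_end,
    )


def _read_csv(path: Path) -> Recording:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    if table.columns.str.startswith("Unnamed").any():
        raise SchemaError(f"{path}: missing channel labels in header")
    if table.isna().to_numpy().any():
        raise SchemaError(
            f"{path}: channels of unequal length or missing samples"
        )
    sidecar = _csv_sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pges = meta.get("pges_end_s")
    return Recording(
        samples=table.to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        channel_names=tuple(table.columns),
        patient_id=str(meta.get("patient_id", path.stem)),
        pges_end_s=None if pges is None else float(pges),
    )


def write_recording(rec: Recording, path, format: Optional[str] = None) -> None:
    """Write ``rec`` as EDF or CSV, including the annotation sidecar."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "edf":
        from ._edf import write_edf

        write_edf(path, rec.samples, rec.fs, rec.channel_names, rec.patient_id)
        if rec.pges_end_s is not None:
            pd.DataFrame(
                {"patient_id": [rec.patient_id], "pges_end_s": [rec.pges_end_s]}
            ).to_csv(_edf_sidecar(path), sep="\t", index=False)
    elif format == "csv":
        pd.DataFrame(rec.samples.T, columns=list(rec.channel_names)).to_csv(
            path, index=False, float_format="%.17g"
        )
        meta = {
            "fs": rec.fs,
            "patient_id": rec.patient_id,
            "pges_end_s": rec.pges_end_s,
        }
        _csv_sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ArgumentError(f"unknown recording format {format!r}")
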