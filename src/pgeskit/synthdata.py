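"""Synthetic annotated EEG with a postictal generalized suppression episode.

The clinical recordings the detector targets are protected health
information, so this generator emulates their structure: a suppression
segment in which every channel stays below the 10 microvolt clinical
definition, followed (after a short ramp at the annotated end-of-PGES time)
by higher-amplitude activity — slow-wave (3-8 Hz), broadband (1-47 Hz) or a
mixture — partially coherent across channels, with additive broadband noise
and occasional short single-channel artifact bursts on both sides of the
transition.

The suppression definition is enforced: the composite pre-transition signal
is hard-capped at 9.5 microvolts per channel, so every generated recording
satisfies the < 10 microvolt criterion regardless of noise or artifact
draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .preprocess import FilterSpec, Snippet, extract_snippets, filter_zero_phase
from .signal_io import CANONICAL_CHANNELS, Recording, write_recording  # noqa: F401  (re-export)

#: Hard amplitude cap (microvolts) applied to the pre-transition segment.
SUPPRESSION_CAP_UV = 9.5

#: Electrode order of the raw (un-montaged) 13-electrode output.
RAW_ELECTRODES = ("FP1", "F7", "T7", "P7", "O1",
                  "FP2", "F8", "T8", "P8", "O2",
                  "Fz", "Cz", "Pz")

ACTIVITY_BANDS = ("slow_wave_3_8", "broadband_1_47", "mixed")

#: Published duration statistics of the peri-ictal recordings (seconds).
DURATION_MEAN_S = 46.90
DURATION_SD_S = 33.04
DURATION_MIN_S = 20.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    Amplitudes are in microvolts and scale the standard deviation of the
    corresponding component (by amp/3, so ~3 sigma excursions reach amp).
    """

    n_patients: int = 20
    fs: float = 200.0
    duration_s: Optional[float] = None  # None: draw ~ N(46.90, 33.04), >= 20
    suppression_amp_uv: float = 5.0
    activity_amp_uv: float = 40.0
    activity_band: str = "mixed"
    transition_sharpness_s: float = 0.5
    noise_sd_uv: float = 2.0
    artifact_rate_hz: float = 0.1
    artifact_amp_uv: float = 25.0
    channel_coherence: float = 0.6
    raw_electrodes: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.suppression_amp_uv < 10.0):
            raise ArgumentError("suppression_amp_uv must be in [0, 10) microvolts")
        if not (0.0 <= self.channel_coherence <= 1.0):
            raise ArgumentError("channel_coherence must be in [0, 1]")
        for name in ("activity_amp_uv", "noise_sd_uv", "artifact_rate_hz",
                     "artifact_amp_uv", "transition_sharpness_s"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be non-negative")
        if self.activity_band not in ACTIVITY_BANDS:
            raise ArgumentError(
                f"activity_band must be one of {ACTIVITY_BANDS}"
            )
        if self.n_patients < 1 or self.fs <= 0:
            raise ArgumentError("n_patients must be >= 1 and fs positive")
        if self.duration_s is not None and self.duration_s < DURATION_MIN_S:
            raise ArgumentError(f"duration_s must be >= {DURATION_MIN_S:g} s")


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    spec = FilterSpec(band_low=low, band_high=high, order=4)
    x = filter_zero_phase(rng.standard_normal(n + 400), spec, fs)[200:-200]
    sd = x.std()
    return x / sd if sd > 0 else x


def _activity_component(rng: np.random.Generator, n: int, fs: float,
                        band: str) -> np.ndarray:
    """One unit-variance activity waveform in the configured band."""
    if band == "broadband_1_47":
        return _band_noise(rng, n, fs, 1.0, 47.0)
    t = np.arange(n) / fs
    f = rng.uniform(4.0, 6.0)
    phase = rng.uniform(0, 2 * np.pi)
    sine = np.sqrt(2.0) * np.sin(2 * np.pi * f * t + phase)  # unit variance
    slow = 0.8 * sine + 0.6 * _band_noise(rng, n, fs, 3.0, 8.0)
    if band == "slow_wave_3_8":
        return slow
    return np.sqrt(0.5) * slow + np.sqrt(0.5) * _band_noise(rng, n, fs, 1.0, 47.0)


def generate_recording(cfg: SynthConfig, patient_id: str = "P0") -> Recording:
    """Generate one annotated recording; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    duration = cfg.duration_s
    if duration is None:
        duration = float(rng.normal(DURATION_MEAN_S, DURATION_SD_S))
        while duration < DURATION_MIN_S:
            duration = float(rng.normal(DURATION_MEAN_S, DURATION_SD_S))
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    pges_end = float(rng.uniform(0.25, 0.75) * duration)
    nch = len(CANONICAL_CHANNELS)

    # activity envelope ramps 0 -> 1 over [pges_end - ramp, pges_end]
    ramp = cfg.transition_sharpness_s
    if ramp > 0:
        act_env = np.clip((t - (pges_end - ramp)) / ramp, 0.0, 1.0)
    else:
        act_env = (t >= pges_end).astype(float)
    sup_env = 1.0 - act_env

    shared = _activity_component(rng, n, fs, cfg.activity_band)
    c = cfg.channel_coherence
    x = np.empty((nch, n))
    for i in range(nch):
        suppression = _band_noise(rng, n, fs, 1.0, 47.0) * (cfg.suppression_amp_uv / 3.0)
        indep = _activity_component(rng, n, fs, cfg.activity_band)
        activity = (np.sqrt(c) * shared + np.sqrt(1.0 - c) * indep) * (
            cfg.activity_amp_uv / 3.0
        )
        x[i] = sup_env * suppression + act_env * activity

    # short single-channel artifact bursts on both sides of the transition;
    # EMG-like high-frequency content (35-95 Hz), mostly outside the 1-47 Hz
    # analysis band, mimicking movement/muscle contamination
    n_bursts = rng.poisson(cfg.artifact_rate_hz * duration)
    if n_bursts:
        emg = _band_noise(rng, n, fs, 35.0, min(95.0, 0.49 * fs))
    for _ in range(n_bursts):
        t0 = rng.uniform(0.0, max(duration - 0.5, 0.0))
        dur = rng.uniform(0.1, 0.4)
        ch = rng.integers(nch)
        window = np.exp(-0.5 * ((t - t0 - dur / 2) / (dur / 4)) ** 2)
        x[ch] += cfg.artifact_amp_uv * window * emg

    if cfg.noise_sd_uv > 0:
        x += rng.normal(0.0, cfg.noise_sd_uv, size=x.shape)

    # enforce the clinical suppression definition on the pre-transition segment
    pre = int(np.ceil((pges_end - ramp) * fs))
    np.clip(x[:, :pre], -SUPPRESSION_CAP_UV, SUPPRESSION_CAP_UV, out=x[:, :pre])

    rec = Recording(samples=x, fs=fs, channel_names=CANONICAL_CHANNELS,
                    patient_id=str(patient_id), pges_end_s=pges_end)
    if cfg.raw_electrodes:
        rec = _to_raw_electrodes(rec)
    return rec


def _to_raw_electrodes(rec: Recording) -> Recording:
    """Expand a 10-channel bipolar recording into 13 referential electrodes.

    Electrode potentials are built by back-substitution along the three
    longitudinal chains (O1, O2 and Pz taken as zero), so applying the
    default montage recovers the bipolar channels exactly.
    """
    b = rec.samples
    e = {}
    e["O1"] = np.zeros_like(b[0])
    e["P7"] = b[3]
    e["T7"] = b[2] + e["P7"]
    e["F7"] = b[1] + e["T7"]
    e["FP1"] = b[0] + e["F7"]
    e["O2"] = np.zeros_like(b[0])
    e["P8"] = b[7]
    e["T8"] = b[6] + e["P8"]
    e["F8"] = b[5] + e["T8"]
    e["FP2"] = b[4] + e["F8"]
    e["Pz"] = np.zeros_like(b[0])
    e["Cz"] = b[9]
    e["Fz"] = b[8] + e["Cz"]
    samples = np.vstack([e[name] for name in RAW_ELECTRODES])
    return replace(rec, samples=samples, channel_names=RAW_ELECTRODES)


@dataclass
class SnippetDataset:
    """Patient-disjoint train/test snippet sets with a provenance manifest."""

    train: List[Snippet]
    test: List[Snippet]
    manifest: pd.DataFrame


def generate_dataset(cfg: SynthConfig, snippets_per_patient: int = 10,
                     split: Tuple[float, float] = (0.7, 0.3),
                     seed: int = 0) -> SnippetDataset:
    """Generate recordings for every patient and cut labeled snippets.

    ``split`` gives (train, test) patient fractions; patients never appear
    on both sides. The manifest records every per-patient seed and snippet
    start time, so the dataset is reproducible from (cfg, seed) alone.
    """
    from .signal_io import resample_to

    if cfg.n_patients < 2:
        raise ArgumentError("need at least 2 patients for a patient-disjoint split")
    f_train, f_test = split
    if f_train <= 0 or f_test <= 0 or abs(f_train + f_test - 1.0) > 1e-9:
        raise ArgumentError("split fractions must be positive and sum to 1")
    n_test = max(1, int(round(f_test * cfg.n_patients)))
    n_train = cfg.n_patients - n_test
    if n_train < 1:
        raise ArgumentError("split leaves no training patients")

    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * cfg.n_patients + 1)
    order = np.random.default_rng(states[-1]).permutation(cfg.n_patients)
    train_ids = set(order[:n_train])

    train: List[Snippet] = []
    test: List[Snippet] = []
    rows = []
    for p in range(cfg.n_patients):
        pid = f"P{p:03d}"
        rec_seed = int(states[2 * p] % (2 ** 31))
        snip_seed = int(states[2 * p + 1] % (2 ** 31))
        rec = generate_recording(replace(cfg, seed=rec_seed), patient_id=pid)
        if cfg.raw_electrodes:
            from .signal_io import DEFAULT_MONTAGE, apply_montage

            rec = apply_montage(rec, DEFAULT_MONTAGE)
        if rec.fs != 200.0:
            rec = resample_to(rec, 200.0)
        snips = extract_snippets(rec, n_per_class=snippets_per_patient,
                                 rng_seed=snip_seed)
        n_pos = sum(1 for s in snips if s.label)
        n_neg = len(snips) - n_pos
        if min(n_pos, n_neg) < snippets_per_patient:
            warnings.warn(
                f"patient {pid}: only {n_pos} positive / {n_neg} negative "
                f"snippets available (requested {snippets_per_patient} per class)",
                stacklevel=2,
            )
        side = "train" if p in train_ids else "test"
        (train if side == "train" else test).extend(snips)
        for s in snips:
            rows.append({
                "patient_id": pid, "split": side, "start_s": s.start_s,
                "label": int(bool(s.label)), "fs": s.fs,
                "rec_seed": rec_seed, "snip_seed": snip_seed,
                "duration_s": rec.duration_s, "pges_end_s": rec.pges_end_s,
            })
    manifest = pd.DataFrame(rows)
    return SnippetDataset(train=train, test=test, manifest=manifest)


# ---------------------------------------------------------------------------
# Snippet-set serialization: directory of per-snippet columnar files + manifest


def save_dataset(ds: SnippetDataset, directory) -> None:
    directory = Path(directory)
    (directory / "snippets").mkdir(parents=True, exist_ok=True)
    manifest = ds.manifest.copy()
    files = []
    for i, s in enumerate(ds.train + ds.test):
        fname = f"snippets/s{i:05d}.csv"
        pd.DataFrame(s.samples.T, columns=list(s.channel_names)).to_csv(
            directory / fname, index=False, float_format="%.17g"
        )
        files.append(fname)
    manifest["file"] = files
    manifest.to_csv(directory / "manifest.csv", index=False)


def load_dataset(directory) -> SnippetDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    train: List[Snippet] = []
    test: List[Snippet] = []
    for _, row in manifest.iterrows():
        table = pd.read_csv(directory / row["file"])
        s = Snippet(
            samples=table.to_numpy(dtype=float).T,
            fs=float(row["fs"]),
            label=bool(row["label"]),
            patient_id=str(row["patient_id"]),
            start_s=float(row["start_s"]),
            channel_names=tuple(table.columns),
        )
        (train if row["split"] == "train" else test).append(s)
    return SnippetDataset(train=train, test=test, manifest=manifest)
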