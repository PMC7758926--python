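"""The 127-dimensional time-series feature set for 10-s EEG snippets.

Five feature families characterize a snippet, all computationally cheap
(no spectral estimation beyond two fixed bandpass filters):

========================  =====================  =======================
family                    count (n channels)     count (n = 10)
========================  =====================  =======================
correlation               C(n, 2)                45
temporal_ratio            2n + 4                 24
lowfreq_temporal_ratio    2n + 4                 24
lowfreq_signal            2n + 2                 22
sliding_difference        n + 2                  12
========================  =====================  =======================

Total: C(n, 2) + 7n + 12 = 127 for the default 10-channel montage.

The correlation and temporal-ratio families operate on the 1-47 Hz denoised
snippet; the low-frequency families and the sliding difference operate on
the 3-8 Hz slow-wave band. "Normalized" always means divided by the
population variance of the same (filtered) channel series the feature was
computed from, and the "least-variance channel" — a proxy for the channel
least contaminated by artifacts — is the channel of minimal full-snippet
variance, ties broken by the lowest canonical index.

Any ratio or normalization whose denominator has magnitude below ``EPS``
(1e-12, in microvolt or squared-microvolt units) is defined as 0. This is a
deliberate convention: zero-mean filtered EEG makes first-half means
arbitrarily small, and classifier input must stay finite and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .preprocess import Snippet, denoise_snippet, lowfreq_snippet

#: Denominator guard for ratios and variance normalizations.
EPS = 1e-12

#: Family identifiers in the canonical concatenation order.
FAMILIES: Tuple[str, ...] = (
    "correlation",
    "temporal_ratio",
    "lowfreq_temporal_ratio",
    "lowfreq_signal",
    "sliding_difference",
)

#: Sliding-difference window geometry (samples at 200 Hz): 0.25 s window,
#: 0.05 s step, half-window of 25 samples.
SLIDE_WINDOW = 50
SLIDE_STEP = 10


def _gdiv(num: float, den: float) -> float:
    """Guarded division: 0 whenever the denominator is effectively zero."""
    return num / den if abs(den) >= EPS else 0.0


def least_variance_channel(s: Snippet) -> int:
    """Index of the channel with minimal full-snippet (population) variance.

    Ties break to the lowest canonical index (``np.argmin`` semantics).
    """
    return int(np.argmin(s.samples.var(axis=1)))


# ---------------------------------------------------------------------------
# Per-family fragments. Each works on a plain (channels x time) array plus
# channel names and returns (values, names); the public snippet-level
# functions below wire in the appropriate filtering.


def _correlation(x: np.ndarray, names: Sequence[str]):
    n = x.shape[0]
    if n < 2:
        raise ArgumentError("correlation features need at least 2 channels")
    centered = x - x.mean(axis=1, keepdims=True)
    var = (centered ** 2).mean(axis=1)
    vals, labels = [], []
    for i, j in combinations(range(n), 2):
        if var[i] < EPS or var[j] < EPS:
            r = 0.0  # Pearson undefined for a flat channel
        else:
            r = float((centered[i] * centered[j]).mean() / np.sqrt(var[i] * var[j]))
            r = float(np.clip(r, -1.0, 1.0))
        vals.append(r)
        labels.append(f"corr.{names[i]}_{names[j]}")
    return vals, labels


def _temporal_ratio(x: np.ndarray, names: Sequence[str], prefix: str = ""):
    n_samp = x.shape[1]
    half = n_samp // 2
    first, last = x[:, :half], x[:, half:]
    mean_ratio = np.array([_gdiv(b.mean(), a.mean()) for a, b in zip(first, last)])
    var_ratio = np.array([_gdiv(b.var(), a.var()) for a, b in zip(first, last)])
    full_var = x.var(axis=1)
    norm_mean = np.array([_gdiv(m, v) for m, v in zip(mean_ratio, full_var)])
    norm_var = np.array([_gdiv(r, v) for r, v in zip(var_ratio, full_var)])
    lv = int(np.argmin(full_var))
    vals = (
        list(mean_ratio) + list(var_ratio)
        + [float(norm_mean.sum()), float(norm_mean[lv]),
           float(norm_var.sum()), float(norm_var[lv])]
    )
    labels = (
        [f"{prefix}tmr.{c}" for c in names]
        + [f"{prefix}tvr.{c}" for c in names]
        + [f"{prefix}tmr.sum_norm", f"{prefix}tmr.leastvar",
           f"{prefix}tvr.sum_norm", f"{prefix}tvr.leastvar"]
    )
    return vals, labels


def _lowfreq_signal(x: np.ndarray, names: Sequence[str]):
    means = x.mean(axis=1)
    variances = x.var(axis=1)
    norm_mean = np.array([_gdiv(m, v) for m, v in zip(means, variances)])
    lv = int(np.argmin(variances))
    vals = (
        list(means) + list(variances)
        + [float(norm_mean.sum()), float(norm_mean[lv])]
    )
    labels = (
        [f"lf_mean.{c}" for c in names]
        + [f"lf_var.{c}" for c in names]
        + ["lf_mean.sum_norm", "lf_mean.leastvar"]
    )
    return vals, labels


def _sliding_difference(x: np.ndarray, names: Sequence[str]):
    n_samp = x.shape[1]
    if n_samp < SLIDE_WINDOW:
        raise ArgumentError(
            f"snippet of {n_samp} samples shorter than the {SLIDE_WINDOW}-sample window"
        )
    half = SLIDE_WINDOW // 2
    starts = np.arange(0, n_samp - SLIDE_WINDOW + 1, SLIDE_STEP)
    cums = np.cumsum(np.concatenate([np.zeros((x.shape[0], 1)), x], axis=1), axis=1)
    # difference = sum(second half-window) - sum(first half-window)
    diff = (cums[:, starts + SLIDE_WINDOW] - 2 * cums[:, starts + half]
            + cums[:, starts])
    feat = diff.max(axis=1)
    variances = x.var(axis=1)
    norm = np.array([_gdiv(f, v) for f, v in zip(feat, variances)])
    lv = int(np.argmin(variances))
    vals = list(feat) + [float(norm.sum()), float(norm[lv])]
    labels = [f"sld.{c}" for c in names] + ["sld.sum_norm", "sld.leastvar"]
    return vals, labels


# ---------------------------------------------------------------------------
# Snippet-level API


@dataclass
class PreparedSnippet:
    """A snippet with both filtered variants cached.

    Preparing once lets channel-subset experiments recompute features for
    many subsets without refiltering (filtering is per-channel, so subsets
    share it).
    """

    denoised: np.ndarray
    lowfreq: np.ndarray
    channel_names: Tuple[str, ...]
    label: Optional[bool] = None
    patient_id: str = ""
    start_s: float = 0.0


def prepare_snippet(s: Snippet, denoise: bool = True) -> PreparedSnippet:
    """Filter a snippet into its 1-47 Hz and 3-8 Hz variants.

    With ``denoise=False`` the broadband variant is the raw signal (used by
    the noise-filter ablation); the slow-wave variant is always filtered.
    """
    den = denoise_snippet(s).samples if denoise else s.samples.astype(float)
    low = lowfreq_snippet(s).samples
    return PreparedSnippet(
        denoised=den, lowfreq=low, channel_names=s.channel_names,
        label=s.label, patient_id=s.patient_id, start_s=s.start_s,
    )


def _resolve_channels(all_names: Sequence[str], channels) -> List[int]:
    if channels is None:
        return list(range(len(all_names)))
    lowered = {c.lower(): i for i, c in enumerate(all_names)}
    idx = []
    for c in channels:
        if str(c).lower() not in lowered:
            raise ArgumentError(f"unknown channel {c!r}")
        idx.append(lowered[str(c).lower()])
    if len(set(idx)) != len(idx):
        raise ArgumentError("duplicate channels in selection")
    return idx


def _resolve_families(families) -> List[str]:
    if families is None:
        return list(FAMILIES)
    seen = []
    for f in families:
        if f not in FAMILIES:
            raise ArgumentError(
                f"unknown feature family {f!r}; expected one of {FAMILIES}"
            )
        if f not in seen:
            seen.append(f)
    if not seen:
        raise ArgumentError("feature family selection is empty")
    # keep the canonical concatenation order regardless of selection order
    return [f for f in FAMILIES if f in seen]


def features_from_prepared(p: PreparedSnippet, families=None, channels=None) -> pd.Series:
    """Compute the selected feature families on already-filtered data."""
    fams = _resolve_families(families)
    idx = _resolve_channels(p.channel_names, channels)
    if len(idx) < 2:
        raise ArgumentError("at least 2 channels are required for feature definition")
    names = [p.channel_names[i] for i in idx]
    den = p.denoised[idx]
    low = p.lowfreq[idx]
    vals: List[float] = []
    labels: List[str] = []
    for fam in fams:
        if fam == "correlation":
            v, l = _correlation(den, names)
        elif fam == "temporal_ratio":
            v, l = _temporal_ratio(den, names)
        elif fam == "lowfreq_temporal_ratio":
            v, l = _temporal_ratio(low, names, prefix="lf_")
        elif fam == "lowfreq_signal":
            v, l = _lowfreq_signal(low, names)
        else:
            v, l = _sliding_difference(low, names)
        vals.extend(v)
        labels.extend(l)
    return pd.Series(np.asarray(vals, dtype=float), index=labels)


def feature_names(families=None, channels: Sequence[str] = None,
                  all_channels: Sequence[str] = None) -> List[str]:
    """Enumerate the feature names for a channel/family selection."""
    from .signal_io import CANONICAL_CHANNELS

    all_channels = tuple(all_channels or CANONICAL_CHANNELS)
    idx = _resolve_channels(all_channels, channels)
    names = [all_channels[i] for i in idx]
    labels: List[str] = []
    for fam in _resolve_families(families):
        if fam == "correlation":
            labels += [f"corr.{a}_{b}" for a, b in combinations(names, 2)]
        elif fam == "temporal_ratio":
            labels += ([f"tmr.{c}" for c in names] + [f"tvr.{c}" for c in names]
                       + ["tmr.sum_norm", "tmr.leastvar", "tvr.sum_norm", "tvr.leastvar"])
        elif fam == "lowfreq_temporal_ratio":
            labels += ([f"lf_tmr.{c}" for c in names] + [f"lf_tvr.{c}" for c in names]
                       + ["lf_tmr.sum_norm", "lf_tmr.leastvar",
                          "lf_tvr.sum_norm", "lf_tvr.leastvar"])
        elif fam == "lowfreq_signal":
            labels += ([f"lf_mean.{c}" for c in names] + [f"lf_var.{c}" for c in names]
                       + ["lf_mean.sum_norm", "lf_mean.leastvar"])
        else:
            labels += [f"sld.{c}" for c in names] + ["sld.sum_norm", "sld.leastvar"]
    return labels


def extract_all(s: Snippet, families=None, channels=None) -> pd.Series:
    """Full feature vector of a snippet: filter, then compute every family.

    Returns a named Series of length C(k, 2) + 7k + 12 for k selected
    channels with all families (127 for the default 10-channel montage).
    """
    return features_from_prepared(prepare_snippet(s), families, channels)


# Public aliases for the per-family operations (each filters appropriately).

def correlation_features(s: Snippet) -> pd.Series:
    return extract_all(s, families=["correlation"])


def temporal_ratio_features(s: Snippet) -> pd.Series:
    return extract_all(s, families=["temporal_ratio"])


def lowfreq_temporal_ratio_features(s: Snippet) -> pd.Series:
    return extract_all(s, families=["lowfreq_temporal_ratio"])


def lowfreq_signal_features(s: Snippet) -> pd.Series:
    return extract_all(s, families=["lowfreq_signal"])


def sliding_difference_features(s: Snippet) -> pd.Series:
    return extract_all(s, families=["sliding_difference"])


def featurize_snippets(snippets: Iterable[Snippet], families=None, channels=None,
                       denoise: bool = True):
    """Feature matrix + metadata for a snippet collection.

    Returns ``(X, meta)``: ``X`` one row per snippet with named feature
    columns, ``meta`` with label / patient_id / start_s.
    """
    rows, meta = [], []
    for s in snippets:
        p = prepare_snippet(s, denoise=denoise)
        rows.append(features_from_prepared(p, families, channels))
        meta.append((s.label, s.patient_id, s.start_s))
    X = pd.DataFrame(rows).reset_index(drop=True)
    meta_df = pd.DataFrame(meta, columns=["label", "patient_id", "start_s"])
    return X, meta_df


class SnippetFeaturizer:
    """Scikit-learn style transformer from snippets to feature matrices.

    Parameters
    ----------
    families : sequence of str or None
        Feature families to compute (default: all five).
    channels : sequence of str or None
        Channel subset (canonical short names); default all 10.
    denoise : bool
        Apply the 1-47 Hz broadband filter before the correlation and
        temporal-ratio families (the slow-wave families always filter).
    """

    def __init__(self, families=None, channels=None, denoise: bool = True):
        self.families = families
        self.channels = channels
        self.denoise = denoise

    def get_params(self, deep: bool = True):
        return {"families": self.families, "channels": self.channels,
                "denoise": self.denoise}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("families", "channels", "denoise"):
                raise ArgumentError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[Snippet], y=None):
        self.feature_names_out_ = self.get_feature_names_out(X)
        return self

    def get_feature_names_out(self, X: Optional[Sequence[Snippet]] = None):
        all_ch = X[0].channel_names if X else None
        return np.asarray(
            feature_names(self.families, self.channels, all_channels=all_ch),
            dtype=object,
        )

    def transform(self, X: Sequence[Snippet]) -> pd.DataFrame:
        frame, _ = featurize_snippets(
            X, families=self.families, channels=self.channels, denoise=self.denoise
        )
        return frame

    def fit_transform(self, X: Sequence[Snippet], y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
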