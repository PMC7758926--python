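"""Scoring (ROC/AUC, precision/recall/F1) and ablation experiment runners.

AUC is the primary metric: the area under the ROC curve, equal to the
Mann-Whitney probability that a random positive snippet outscores a random
negative one (ties counting one half). The experiment runners mirror the
published ablations: feature-family subsets, the noise-filter on/off
comparison, scalp-region channel groups, random channel-sequence prefixes,
and exhaustive best-k-channel searches — each condition refit with a seed
derived deterministically from (master seed, condition label).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .errors import ArgumentError, MetricError
from .features import FAMILIES, PreparedSnippet, features_from_prepared, prepare_snippet
from .model import DEFAULT_N_TREES, PgesEndClassifier
from .signal_io import CANONICAL_CHANNELS
from .synthdata import SnippetDataset

#: Scalp-region channel groups used in the region ablation.
REGIONS: Dict[str, Tuple[str, ...]] = {
    "left": ("FP1", "F7", "T7", "P7"),
    "right": ("FP2", "F8", "T8", "P8"),
    "center": ("Fz", "Cz"),
    "diametric": ("FP1", "P8"),
}


@dataclass
class EvalResult:
    """ROC curve with AUC and one thresholded operating point."""

    roc_points: np.ndarray  # (m, 2) array of (FPR, TPR), (0,0) .. (1,1)
    auc: float
    precision: float
    recall: float
    f1: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    precision_defined: bool = True


def _check_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise MetricError("both classes must be present to evaluate")


def roc_auc(scores, labels, threshold: float = 0.5) -> EvalResult:
    """ROC curve and AUC, plus precision/recall/F1 at ``threshold``.

    The curve sweeps every distinct score; the trapezoidal area over tied
    blocks makes the AUC exactly the Mann-Whitney statistic with half-weight
    ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    p, r, f1, defined = prf(scores, labels, threshold)
    return EvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        auc=auc, precision=p, recall=r, f1=f1,
        n_pos=int((labels == 1).sum()), n_neg=int((labels == 0).sum()),
        threshold=threshold, precision_defined=defined,
    )


def prf(scores, labels, threshold: float = 0.5) -> Tuple[float, float, float, bool]:
    """Precision, recall, F1 at ``score >= threshold``; plus a flag that is
    False when precision is undefined (no predicted positives, reported 0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    defined = (tp + fp) > 0
    precision = tp / (tp + fp) if defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return float(precision), float(recall), float(f1), defined


def condition_seed(master_seed: int, label: str) -> int:
    """Deterministic per-condition seed derived from the master seed."""
    return (zlib.crc32(label.encode("utf-8")) ^ (master_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Experiment harness


def _prepare_all(snippets, denoise: bool = True) -> List[PreparedSnippet]:
    return [prepare_snippet(s, denoise=denoise) for s in snippets]


def _matrix(prepared: Sequence[PreparedSnippet], families, channels):
    X = pd.DataFrame([
        features_from_prepared(p, families, channels) for p in prepared
    ]).reset_index(drop=True)
    y = np.array([int(bool(p.label)) for p in prepared])
    return X, y


def _fit_and_auc(train_prep, test_prep, families, channels, seed: int,
                 n_trees: int = DEFAULT_N_TREES) -> EvalResult:
    Xtr, ytr = _matrix(train_prep, families, channels)
    Xte, yte = _matrix(test_prep, families, channels)
    clf = PgesEndClassifier(n_trees=n_trees, random_state=seed).fit(Xtr, ytr)
    return roc_auc(clf.predict_score(Xte), yte)


def run_feature_subset_experiment(dataset: SnippetDataset,
                                  families: Sequence[Sequence[str]],
                                  seed: int = 0,
                                  n_trees: int = DEFAULT_N_TREES) -> pd.DataFrame:
    """One train/score run per feature-family subset, all else identical."""
    import warnings as _warnings

    subsets = []
    for fams in families:
        fams = list(fams)
        if not fams:
            raise ArgumentError("empty feature-family subset")
        if len(set(fams)) != len(fams):
            _warnings.warn("duplicate family in subset; deduplicated", stacklevel=2)
            fams = list(dict.fromkeys(fams))
        for f in fams:
            if f not in FAMILIES:
                raise ArgumentError(f"unknown feature family {f!r}")
        subsets.append([f for f in FAMILIES if f in fams])
    train_prep = _prepare_all(dataset.train)
    test_prep = _prepare_all(dataset.test)
    rows = []
    for fams in subsets:
        label = "+".join(fams)
        res = _fit_and_auc(train_prep, test_prep, fams, None,
                           condition_seed(seed, label), n_trees)
        rows.append({
            "condition": label, "auc": res.auc,
            "n_features": len(features_from_prepared(train_prep[0], fams, None)),
            "seed": condition_seed(seed, label),
        })
    return pd.DataFrame(rows)


def run_filter_ablation(dataset: SnippetDataset, seed: int = 0,
                        n_trees: int = DEFAULT_N_TREES) -> pd.DataFrame:
    """Noise-filter on/off comparison.

    Restricted to the correlation + temporal-ratio families: the
    low-frequency families implicitly filter out-of-band noise, so they
    would mask the effect.
    """
    fams = ["correlation", "temporal_ratio"]
    rows = []
    for label, denoise in (("with_filter", True), ("without_filter", False)):
        train_prep = _prepare_all(dataset.train, denoise=denoise)
        test_prep = _prepare_all(dataset.test, denoise=denoise)
        res = _fit_and_auc(train_prep, test_prep, fams, None,
                           condition_seed(seed, label), n_trees)
        rows.append({
            "condition": label, "auc": res.auc,
            "families": "+".join(fams),
            "seed": condition_seed(seed, label),
        })
    return pd.DataFrame(rows)


def draw_channel_sequences(n_sequences: int, seed: int) -> List[Tuple[str, ...]]:
    """Random orderings of the 10 canonical channels."""
    rng = np.random.default_rng(seed)
    return [
        tuple(np.asarray(CANONICAL_CHANNELS)[rng.permutation(len(CANONICAL_CHANNELS))])
        for _ in range(n_sequences)
    ]


def run_channel_experiments(dataset: SnippetDataset, mode: str,
                            params: Optional[dict] = None, seed: int = 0,
                            n_trees: int = DEFAULT_N_TREES) -> pd.DataFrame:
    """Channel-subset ablations.

    mode="regions"
        One row per named scalp region (default: the four standard groups).
    mode="sequences"
        For each channel ordering, one row per prefix length 2..10.
        params: {"sequences": [orderings]} or {"n_sequences": int}.
    mode="combinations"
        All C(10, k) channel combinations, ranked by AUC (rank 1 best).
        params: {"k": 2 or 3}.
    """
    params = dict(params or {})
    train_prep = _prepare_all(dataset.train)
    test_prep = _prepare_all(dataset.test)

    def run_one(label: str, channels) -> dict:
        s = condition_seed(seed, label)
        res = _fit_and_auc(train_prep, test_prep, None, channels, s, n_trees)
        return {"condition": label, "channels": ",".join(channels),
                "auc": res.auc, "seed": s}

    rows: List[dict] = []
    if mode == "regions":
        regions = params.get("regions", REGIONS)
        for name, channels in regions.items():
            row = run_one(f"region:{name}", channels)
            row["region"] = name
            rows.append(row)
        return pd.DataFrame(rows)

    if mode == "sequences":
        sequences = params.get("sequences")
        if sequences is None:
            sequences = draw_channel_sequences(params.get("n_sequences", 5), seed)
        for si, seq in enumerate(sequences):
            seq = tuple(seq)
            for k in range(2, len(seq) + 1):
                row = run_one(f"seq{si}:{','.join(seq[:k])}", seq[:k])
                row.update({"sequence": si, "prefix_len": k})
                rows.append(row)
        return pd.DataFrame(rows)

    if mode == "combinations":
        k = int(params.get("k", 2))
        if k < 2:
            raise ArgumentError("combinations need k >= 2 channels")
        for combo in combinations(CANONICAL_CHANNELS, k):
            row = run_one(f"comb:{','.join(combo)}", combo)
            row["k"] = k
            rows.append(row)
        table = pd.DataFrame(rows).sort_values(
            "auc", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        return table

    raise ArgumentError(f"unknown channel-experiment mode {mode!r}")


def feature_distribution_report(snippets, anchor_channel: str):
    """Class-conditional summaries of the correlation features touching one
    channel.

    Returns ``(per_feature, pooled)``: per-feature class means and standard
    deviations, and the pooled mean +/- sd per class over those features.
    """
    snippets = list(snippets)
    if anchor_channel not in CANONICAL_CHANNELS:
        raise ArgumentError(f"unknown channel {anchor_channel!r}")
    labels = np.array([int(bool(s.label)) for s in snippets])
    _check_classes(labels)
    prepared = _prepare_all(snippets)
    X, y = _matrix(prepared, ["correlation"], None)
    cols = [c for c in X.columns
            if anchor_channel in c.split(".", 1)[1].split("_")]
    rows = []
    for col in cols:
        rows.append({
            "feature": col,
            "mean_negative": float(X.loc[y == 0, col].mean()),
            "sd_negative": float(X.loc[y == 0, col].std(ddof=0)),
            "mean_positive": float(X.loc[y == 1, col].mean()),
            "sd_positive": float(X.loc[y == 1, col].std(ddof=0)),
        })
    per_feature = pd.DataFrame(rows)
    pooled_rows = []
    for cls, name in ((0, "negative"), (1, "positive")):
        vals = X.loc[y == cls, cols].to_numpy().ravel()
        pooled_rows.append({"class": name, "mean": float(vals.mean()),
                            "sd": float(vals.std(ddof=0)), "n": int(vals.size)})
    pooled = pd.DataFrame(pooled_rows)
    return per_feature, pooled


def plot_roc(result: EvalResult, path) -> None:
    """Optional ROC figure (tables are the canonical output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result.roc_points[:, 0], result.roc_points[:, 1],
            label=f"AUC = {result.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
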