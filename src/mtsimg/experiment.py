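"""Evaluation protocol: repeated stratified k-fold CV and rank-based tests.

A *condition* is one (encoder, concatenation order, architecture, image
size, bin count) combination.  ``run_condition`` encodes the dataset once,
then runs ``repeats`` independent rounds of stratified k-fold
cross-validation (default 5 folds, matching an 80/20 train/test split),
training a fresh network per fold and scoring the held-out fold's error
rate.

Three comparisons mirror the framework's evaluation questions:

* encoders (GASF vs GADF vs MTF) — Dunn post-hoc pairwise tests on the
  per-repeat mean errors, reported raw and Holm-adjusted;
* concatenation orders — pairwise Wilcoxon signed-rank tests on errors
  paired by (repeat, fold);
* architectures — Kruskal–Wallis H test across groups of per-repeat means.

The per-run sample unit for the unpaired tests is the per-repeat mean error
over folds; switch to per-fold granularity by passing
``unit="fold"`` where offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from . import encoding, imaging, model
from .data import MTSDataset
from .errors import InvalidArgumentError, InvalidInputError, StratificationError

__all__ = [
    "Condition",
    "ExperimentResult",
    "kfold_split",
    "encode_instance",
    "encode_dataset",
    "run_condition",
    "dunn_test",
    "compare_encoders",
    "compare_orders",
    "compare_architectures",
    "report",
]

_ENCODERS = {"GASF": encoding.gasf, "GADF": encoding.gadf}


@dataclass(frozen=True)
class Condition:
    """One cell of the experimental design."""

    encoder: str  # "GASF" | "GADF" | "MTF"
    architecture: str = "simple"  # "simple" | "vgg16"
    image_size: int = 128
    bins: int = encoding.DEFAULT_BINS
    order: tuple[int, ...] | None = None  # None = natural channel order

    def __post_init__(self):
        if self.encoder not in ("GASF", "GADF", "MTF"):
            raise InvalidArgumentError(f"unknown encoder {self.encoder!r}")
        if self.architecture not in ("simple", "vgg16"):
            raise InvalidArgumentError(f"unknown architecture {self.architecture!r}")

    def label(self) -> str:
        order = "natural" if self.order is None else "-".join(map(str, self.order))
        return f"{self.encoder}/{self.architecture}/n{self.image_size}/order={order}"


@dataclass(frozen=True)
class ExperimentResult:
    """Error rates (percent) over repeats x folds for one condition."""

    condition: Condition
    error_rates: np.ndarray  # (repeats, folds)
    base_seed: int

    @property
    def repeat_means(self) -> np.ndarray:
        return self.error_rates.mean(axis=1)

    @property
    def mean_error(self) -> float:
        return float(self.repeat_means.mean())

    def samples(self, unit: str = "repeat") -> np.ndarray:
        if unit == "repeat":
            return self.repeat_means
        if unit == "fold":
            return self.error_rates.ravel()
        raise InvalidArgumentError(f"unit must be 'repeat' or 'fold', got {unit!r}")


def kfold_split(labels, k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold partition of ``range(len(labels))``.

    Returns k disjoint test-index arrays covering all indices, with fold
    sizes differing by at most one; deterministic for a given seed.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if not 2 <= k <= n:
        raise InvalidArgumentError(f"need 2 <= k <= n={n}, got k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [test for _, test in skf.split(np.zeros(n), y)]


def encode_instance(
    instance, encoder: str, image_size: int, bins: int, order=None
) -> np.ndarray:
    """One instance -> (3, n*m, n) concatenated image.

    Pipeline per channel: min-max rescale -> length-normalise to
    ``image_size`` (PAA or interpolation) -> field encoding -> rainbow
    colormap; the per-channel RGB images are then channel-split concatenated
    in ``order``.
    """
    rgbs = []
    for chan in instance.channels:
        x = encoding.resample_to(encoding.rescale_01(chan), image_size)
        if encoder == "MTF":
            fieldm = encoding.mtf(x, bins)
        else:
            fieldm = _ENCODERS[encoder](x)
        rgbs.append(imaging.colormap_rainbow(fieldm))
    return imaging.concat_rgb(rgbs, order)


def encode_dataset(
    dataset: MTSDataset, encoder: str, image_size: int, bins: int, order=None
) -> np.ndarray:
    """Encode every instance; returns a float32 (N, 3, n*m, n) batch."""
    return np.stack(
        [
            encode_instance(inst, encoder, image_size, bins, order)
            for inst in dataset
        ]
    ).astype(np.float32)


def run_condition(
    dataset: MTSDataset,
    condition: Condition,
    train_config: model.TrainConfig | None = None,
    repeats: int = 20,
    folds: int = 5,
    base_seed: int = 0,
) -> ExperimentResult:
    """Repeated stratified k-fold evaluation of one condition.

    Seed lineage: repeat r splits with ``base_seed + r`` and trains fold f
    with ``base_seed + 97 * r + f``, so the whole run is replayable from
    ``base_seed``.  Images are encoded once and shared across repeats.
    """
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("dataset must contain both classes")
    train_config = train_config or model.TrainConfig()
    images = encode_dataset(
        dataset, condition.encoder, condition.image_size, condition.bins,
        condition.order,
    )
    spec = model.build_architecture(condition.architecture, images.shape[1:])

    errors = np.empty((repeats, folds))
    for r in range(repeats):
        for f, test_idx in enumerate(kfold_split(labels, folds, base_seed + r)):
            train_mask = np.ones(len(labels), dtype=bool)
            train_mask[test_idx] = False
            y_train = labels[train_mask]
            if len(np.unique(y_train)) < 2:
                raise StratificationError(
                    f"repeat {r} fold {f}: single-class training data"
                )
            cfg = replace(train_config, seed=base_seed + 97 * r + f)
            fitted = model.train(spec, images[train_mask], y_train, cfg)
            pred = model.predict(fitted, images[test_idx])
            errors[r, f] = model.error_rate(pred, labels[test_idx])
    return ExperimentResult(condition, errors, base_seed)


# ---------------------------------------------------------------------------
# Rank-based comparisons


def dunn_test(samples: list) -> dict:
    """Dunn post-hoc pairwise comparisons after a Kruskal–Wallis ranking.

    All observations are ranked jointly (average ranks on ties); the pairwise
    statistic is ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - C_ties)
    (1/n_i + 1/n_j))`` with the usual tie correction
    ``C_ties = sum(t^3 - t) / (12 (N - 1))``, and two-sided normal p-values.
    Returns raw and Holm-adjusted p matrices (diagonal 1) plus z.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise InvalidInputError("need >= 2 non-empty samples")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_corr

    k = len(groups)
    z = np.zeros((k, k))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
            z[i, j], z[j, i] = zij, -zij
            p[i, j] = p[j, i] = min(1.0, 2.0 * scipy.stats.norm.sf(abs(zij)))

    iu = np.triu_indices(k, 1)
    raw = p[iu]
    order = np.argsort(raw)
    adj = np.empty_like(raw)
    running = 0.0
    for rank_pos, idx in enumerate(order):
        running = max(running, (len(raw) - rank_pos) * raw[idx])
        adj[idx] = min(1.0, running)
    p_holm = np.ones((k, k))
    p_holm[iu] = adj
    p_holm.T[iu] = adj
    return {"z": z, "p": p, "p_holm": p_holm, "mean_ranks": np.array(mean_ranks)}


def compare_encoders(results: list, unit: str = "repeat") -> dict:
    """Dunn pairwise p-values across encoder conditions.

    ``results`` are ExperimentResults for the same dataset/architecture/order
    differing only in encoder.  Unequal sample counts are flagged (not fatal).
    """
    samples = [r.samples(unit) for r in results]
    out = dunn_test(samples)
    out["encoders"] = [r.condition.encoder for r in results]
    out["unequal_sizes"] = len({s.size for s in samples}) > 1
    return out


def compare_orders(results: list) -> dict:
    """Pairwise Wilcoxon signed-rank tests between concatenation orders.

    Errors are paired by (repeat, fold).  A pair whose differences are all
    zero has no signed ranks; it is reported as p = 1 with ``degenerate``
    set, mirroring "no detectable difference".
    """
    if len(results) < 2:
        raise InvalidInputError("need >= 2 order conditions")
    k = len(results)
    shape = results[0].error_rates.shape
    for r in results:
        if r.error_rates.shape != shape:
            raise InvalidInputError("results must be paired: same repeats x folds")
    p = np.ones((k, k))
    degenerate = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            a = results[i].error_rates.ravel()
            b = results[j].error_rates.ravel()
            if np.all(a == b):
                degenerate[i, j] = degenerate[j, i] = True
                continue
            stat = scipy.stats.wilcoxon(a, b, zero_method="wilcox")
            p[i, j] = p[j, i] = float(stat.pvalue)
    return {
        "p": p,
        "degenerate": degenerate,
        "orders": [r.condition.order for r in results],
    }


def compare_architectures(*groups, unit: str = "repeat") -> dict:
    """Kruskal–Wallis H test across architecture (or any) groups.

    Accepts ExperimentResults or plain samples; two groups is the usual
    simple-vs-vgg16 comparison but more are accepted.  Identical data across
    all groups gives H = 0, p = 1.
    """
    arrays = [
        g.samples(unit) if isinstance(g, ExperimentResult) else np.asarray(g, float)
        for g in groups
    ]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InvalidInputError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0}
    stat = scipy.stats.kruskal(*arrays)
    return {"H": float(stat.statistic), "p": float(stat.pvalue)}


# ---------------------------------------------------------------------------
# Reporting


def report(results: list, comparisons: dict | None, outdir) -> dict:
    """Write a machine-readable CSV and a human-readable summary.

    ``results.csv`` has one row per (condition, repeat, fold) with the error
    rate; ``summary.txt`` lists per-condition means, five-number summaries,
    and any p-value tables passed in ``comparisons``.  Output is byte-stable
    for identical inputs.  Returns the file paths.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for res in results:
        c = res.condition
        order = "natural" if c.order is None else "-".join(map(str, c.order))
        for r in range(res.error_rates.shape[0]):
            for f in range(res.error_rates.shape[1]):
                rows.append(
                    (c.encoder, order, c.architecture, c.image_size, c.bins,
                     r, f, res.error_rates[r, f])
                )
    df = pd.DataFrame(
        rows,
        columns=["encoder", "order", "architecture", "image_size", "bins",
                 "repeat", "fold", "error_rate"],
    )
    csv_path = os.path.join(outdir, "results.csv")
    df.to_csv(csv_path, index=False, float_format="%.10g")

    lines = ["condition summaries (error rate, %)", "=" * 40]
    for res in results:
        s = res.samples("fold")
        q = np.percentile(s, [0, 25, 50, 75, 100])
        lines.append(
            f"{res.condition.label()}: mean={res.mean_error:.4f}  "
            f"five-num=[{', '.join(f'{v:.4f}' for v in q)}]"
        )
    if comparisons:
        for name, table in comparisons.items():
            lines.append("")
            lines.append(f"{name}:")
            if isinstance(table, dict) and "p" in table:
                p = np.atleast_2d(table["p"])
                for row in p:
                    lines.append("  " + "  ".join(f"{v:.6f}" for v in row))
            else:
                lines.append(f"  {table}")
    txt_path = os.path.join(outdir, "summary.txt")
    with open(txt_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return {"csv": csv_path, "summary": txt_path}
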