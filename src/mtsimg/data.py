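"""Dataset containers, file formats, and the synthetic generator.

An instance is a batch of m aligned sensor channels sharing one length (the
length may vary across instances but never within one) plus a binary label
(0 = normal, 1 = abnormal).  Two on-disk formats are supported:

* the canonical long CSV (``instance_id,channel,t,value,label``), explicit
  and diff-friendly;
* per-instance whitespace-delimited matrices (one file per instance, T rows
  by m columns, label in the filename suffix ``_normal`` / ``_abnormal``),
  matching how classic sensor benchmarks are distributed.

The synthetic generator emulates wafer-chamber-style data: smooth
low-frequency baselines per channel, Gaussian noise, and an abnormal class
marked by a downward level shift plus a small number of transient spikes
shared across channels (a process event seen by every sensor).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    EmptyDatasetError,
    FormatError,
    InvalidArgumentError,
    InvalidInputError,
)

__all__ = [
    "MTSInstance",
    "MTSDataset",
    "SynthConfig",
    "read_long_csv",
    "write_long_csv",
    "read_instance_matrices",
    "write_instance_matrices",
    "generate_synthetic",
]


@dataclass(frozen=True)
class MTSInstance:
    """One multivariate instance: m channels of common length plus a label."""

    instance_id: str
    channels: np.ndarray  # (m, T)
    label: int  # 0 = normal, 1 = abnormal

    def __post_init__(self):
        arr = np.asarray(self.channels, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InvalidInputError(
                f"channels must be a (m, T) array, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"instance {self.instance_id}: non-finite values")
        if self.label not in (0, 1):
            raise InvalidInputError(
                f"instance {self.instance_id}: label must be 0 or 1, got {self.label}"
            )
        object.__setattr__(self, "channels", arr)

    @property
    def m(self) -> int:
        return self.channels.shape[0]

    @property
    def length(self) -> int:
        return self.channels.shape[1]


@dataclass(frozen=True)
class MTSDataset:
    """A list of instances sharing one channel count m."""

    instances: tuple[MTSInstance, ...]
    name: str = ""

    def __post_init__(self):
        inst = tuple(self.instances)
        if not inst:
            raise EmptyDatasetError(f"dataset {self.name!r} has no instances")
        m = inst[0].m
        for i in inst:
            if i.m != m:
                raise FormatError(
                    f"instance {i.instance_id} has {i.m} channels, expected {m}"
                )
        object.__setattr__(self, "instances", inst)

    @property
    def m(self) -> int:
        return self.instances[0].m

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def labels(self) -> np.ndarray:
        return np.array([i.label for i in self.instances], dtype=int)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([i.length for i in self.instances], dtype=int)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a six-sensor wafer-style benchmark: instance lengths
    drawn uniformly from 104..198, half the instances abnormal, and the
    abnormal signature a level shift of -1 plus two spikes of height 2 over
    a unit-amplitude baseline with noise sd 0.1.
    """

    n_instances: int = 120
    m: int = 6
    length_range: tuple[int, int] = (104, 198)
    spike_amplitude: float = 2.0
    level_shift: float = 1.0
    noise_sd: float = 0.1
    n_spikes: int = 2
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        tmin, tmax = self.length_range
        if tmin < 8 or tmax < tmin:
            raise InvalidArgumentError(
                f"length_range must satisfy 8 <= Tmin <= Tmax, got {self.length_range}"
            )
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidArgumentError(
                f"class_balance must be in (0, 1), got {self.class_balance}"
            )
        if self.noise_sd < 0:
            raise InvalidArgumentError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_instances < 2 or self.m < 1 or self.n_spikes < 0:
            raise InvalidArgumentError("n_instances >= 2, m >= 1, n_spikes >= 0 required")


def generate_synthetic(config: SynthConfig) -> MTSDataset:
    """Generate a seeded wafer/ECG-like dataset.

    Each channel is a random-phase low-frequency sinusoid (1-3 cycles,
    amplitude ~1) plus Gaussian noise.  Abnormal instances are shifted down
    by ``level_shift`` and receive ``n_spikes`` short triangular spikes of
    height ``spike_amplitude`` at random positions shared across channels.
    One seed -> one dataset, bit-stable across calls.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_instances
    n_abnormal = int(round(n * config.class_balance))
    labels = np.zeros(n, dtype=int)
    labels[:n_abnormal] = 1
    labels = rng.permutation(labels)

    tmin, tmax = config.length_range
    width = len(str(n - 1))
    instances = []
    for i in range(n):
        T = int(rng.integers(tmin, tmax + 1))
        t = np.arange(T, dtype=float)
        chans = np.empty((config.m, T))
        for c in range(config.m):
            cycles = rng.uniform(1.0, 3.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            amp = rng.uniform(0.8, 1.2)
            offset = rng.uniform(-0.5, 0.5)
            chans[c] = offset + amp * np.sin(2.0 * np.pi * cycles * t / T + phase)
            chans[c] += rng.normal(0.0, config.noise_sd, T)
        if labels[i] == 1:
            chans -= config.level_shift
            if config.n_spikes > 0:
                pos = rng.choice(np.arange(2, T - 2), config.n_spikes, replace=False)
                for p in pos:
                    half = int(rng.integers(1, 3))
                    for d in range(-half, half + 1):
                        j = p + d
                        if 0 <= j < T:
                            chans[:, j] += config.spike_amplitude * (
                                1.0 - abs(d) / (half + 1)
                            )
        instances.append(
            MTSInstance(f"inst{str(i).zfill(width)}", chans, int(labels[i]))
        )
    return MTSDataset(tuple(instances), name=f"synthetic-seed{config.seed}")


# ---------------------------------------------------------------------------
# Long CSV format


def write_long_csv(dataset: MTSDataset, path) -> None:
    """Write a dataset as the canonical long CSV.

    Header ``instance_id,channel,t,value,label``; ``channel`` and ``t`` are
    1-based; values are printed with 17 significant digits so a read-back is
    exact to double precision.
    """
    rows = []
    for inst in dataset:
        for c in range(inst.m):
            for t in range(inst.length):
                rows.append(
                    (inst.instance_id, c + 1, t + 1, inst.channels[c, t], inst.label)
                )
    df = pd.DataFrame(rows, columns=["instance_id", "channel", "t", "value", "label"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_long_csv(path, name: str | None = None) -> MTSDataset:
    """Read the long CSV format back into a validated dataset."""
    df = pd.read_csv(path)
    required = ["instance_id", "channel", "t", "value", "label"]
    if list(df.columns) != required:
        raise FormatError(
            f"expected header {','.join(required)}, got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise EmptyDatasetError(f"{path}: no data rows")
    if df["label"].isna().any():
        raise FormatError(f"{path}: missing label values")

    instances = []
    for inst_id, g in df.groupby("instance_id", sort=False):
        labels = g["label"].unique()
        if len(labels) != 1:
            raise FormatError(f"instance {inst_id}: conflicting labels {labels}")
        chan_ids = np.sort(g["channel"].unique())
        if not np.array_equal(chan_ids, np.arange(1, len(chan_ids) + 1)):
            raise FormatError(f"instance {inst_id}: channels must be 1..m consecutive")
        lengths = g.groupby("channel")["t"].count()
        if lengths.nunique() != 1:
            raise FormatError(
                f"instance {inst_id}: ragged channels, lengths {sorted(lengths)}"
            )
        T = int(lengths.iloc[0])
        chans = np.empty((len(chan_ids), T))
        for c, gc in g.groupby("channel"):
            gc = gc.sort_values("t")
            if not np.array_equal(gc["t"].to_numpy(), np.arange(1, T + 1)):
                raise FormatError(
                    f"instance {inst_id} channel {c}: t must be 1..T consecutive"
                )
            chans[int(c) - 1] = gc["value"].to_numpy()
        instances.append(MTSInstance(str(inst_id), chans, int(labels[0])))
    return MTSDataset(tuple(instances), name=name or os.path.basename(str(path)))


# ---------------------------------------------------------------------------
# Per-instance matrix format (one whitespace-delimited file per instance)

_MATRIX_NAME = re.compile(r"^(?P<id>.+)_(?P<label>normal|abnormal)\.txt$")


def write_instance_matrices(dataset: MTSDataset, directory) -> None:
    """Write one ``<id>_<normal|abnormal>.txt`` matrix (T rows, m cols) per instance."""
    os.makedirs(directory, exist_ok=True)
    for inst in dataset:
        label = "abnormal" if inst.label == 1 else "normal"
        path = os.path.join(directory, f"{inst.instance_id}_{label}.txt")
        np.savetxt(path, inst.channels.T, fmt="%.17g")


def read_instance_matrices(directory, name: str | None = None) -> MTSDataset:
    """Read a directory of per-instance matrices into a validated dataset."""
    files = sorted(f for f in os.listdir(directory) if f.endswith(".txt"))
    if not files:
        raise EmptyDatasetError(f"no .txt instance files in {directory}")
    instances = []
    m = None
    for fname in files:
        match = _MATRIX_NAME.match(fname)
        if match is None:
            raise FormatError(
                f"{fname}: filename must be <id>_<normal|abnormal>.txt"
            )
        mat = np.loadtxt(os.path.join(directory, fname), ndmin=2)
        if m is None:
            m = mat.shape[1]
        elif mat.shape[1] != m:
            raise FormatError(
                f"{fname}: {mat.shape[1]} columns, other files have {m}"
            )
        instances.append(
            MTSInstance(
                match["id"], mat.T, 1 if match["label"] == "abnormal" else 0
            )
        )
    return MTSDataset(tuple(instances), name=name or os.path.basename(str(directory)))
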