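"""Univariate series -> 2-D field matrices.

A univariate sensor trace is rescaled to [0, 1], length-normalised (PAA for
reduction, linear interpolation for the rare upsampling case), and encoded as
one of three n x n field matrices:

* GASF — Gramian angular summation field, ``cos(phi_i + phi_j)`` with
  ``phi = arccos`` of the rescaled values; symmetric, and invertible from its
  diagonal (``x = sqrt((diag + 1) / 2)``).
* GADF — Gramian angular difference field, ``sin(phi_i - phi_j)``;
  antisymmetric with a zero diagonal.
* MTF — Markov transition field: entry (i, j) is the first-order transition
  probability between the quantile bins of x(i) and x(j), estimated from the
  series' own consecutive-pair transitions.

All matrices are row-major with index (i, j) = (time i, time j), 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateBinningError, InvalidArgumentError, InvalidInputError

__all__ = [
    "FieldMatrix",
    "MarkovModel",
    "rescale_01",
    "paa",
    "resample_to",
    "gasf",
    "gadf",
    "fit_markov",
    "mtf",
]

#: Default number of quantile bins for the Markov transition field.
DEFAULT_BINS = 8

# Rounding slack absorbed before arccos/sqrt and range checks.
_EPS = 1e-12


@dataclass(frozen=True)
class FieldMatrix:
    """An n x n field produced by one encoder.

    Attributes
    ----------
    method : str
        One of ``"GASF"``, ``"GADF"``, ``"MTF"``.
    values : numpy.ndarray
        Square matrix of field entries.
    theoretical_range : tuple of float
        The encoder's full output range, ``(-1, 1)`` for the Gramian fields
        and ``(0, 1)`` for MTF.  Colour mapping uses this range (not the
        per-image min/max) so colours are comparable across instances.
    """

    method: str
    values: np.ndarray
    theoretical_range: tuple[float, float]

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MarkovModel:
    """First-order Markov chain over quantile bins of a series.

    ``transitions[i, j]`` is the probability that a value in bin ``i`` is
    followed by a value in bin ``j``; rows with at least one observed outgoing
    transition sum to 1, rows never visited (or only visited at the final
    time step) are all zero.
    """

    bin_edges: np.ndarray  # (n_bins - 1,) increasing interior edges
    transitions: np.ndarray  # (n_bins, n_bins) row-stochastic where observed
    n_bins: int

    def assign_bins(self, values: np.ndarray) -> np.ndarray:
        """Right-closed quantile bin index for each value.

        Bin ``i`` covers ``(edge[i-1], edge[i]]``; the lowest bin is closed on
        both ends.  Values equal to an edge fall in the lower bin.
        """
        return np.searchsorted(self.bin_edges, values, side="left")


def _validate_series(values, min_len: int = 2) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"expected a 1-D series, got shape {x.shape}")
    if x.size < min_len:
        raise InvalidInputError(f"series length {x.size} < required minimum {min_len}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("series contains NaN or infinite values")
    return x


def _validate_rescaled(values) -> np.ndarray:
    x = _validate_series(values)
    if x.min() < -_EPS or x.max() > 1 + _EPS:
        raise InvalidInputError(
            f"rescaled series must lie in [0, 1]; got range [{x.min()}, {x.max()}]"
        )
    # absorb rounding noise before arccos/sqrt
    return np.clip(x, 0.0, 1.0)


def rescale_01(series) -> np.ndarray:
    """Min-max rescale a series to [0, 1].

    Non-constant input maps linearly so that min -> 0 and max -> 1 exactly.
    A constant series has no scale; it maps to all 0.5 (mid-range) so a flat
    sensor channel does not abort a batch.
    """
    x = _validate_series(series)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def paa(series, n_segments: int) -> np.ndarray:
    """Piecewise aggregate approximation: contiguous segment means.

    The series is cut into ``n_segments`` contiguous segments with 1-based
    boundaries ``floor(l * T / N)`` whose sizes differ by at most one; each
    segment is replaced by its mean.  ``n_segments == T`` returns the input
    unchanged and ``n_segments == 1`` returns the global mean.
    """
    x = _validate_series(series, min_len=1)
    T = x.size
    if not 1 <= n_segments <= T:
        raise InvalidArgumentError(
            f"n_segments must be in [1, {T}], got {n_segments}"
        )
    if n_segments == T:
        return x.copy()
    bounds = (np.arange(n_segments + 1) * T) // n_segments
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[bounds[1:]] - csum[bounds[:-1]]) / np.diff(bounds)


def resample_to(series, n: int) -> np.ndarray:
    """Normalise a series to length exactly ``n``.

    Longer series are reduced with :func:`paa`; shorter series are linearly
    interpolated onto ``n`` equally spaced points over the original time
    span, which preserves shape without inventing structure.
    """
    x = _validate_series(series)
    if n < 1:
        raise InvalidArgumentError(f"target length must be >= 1, got {n}")
    T = x.size
    if T >= n:
        return paa(x, n)
    return np.interp(np.linspace(0.0, T - 1.0, n), np.arange(T, dtype=float), x)


def gasf(rescaled) -> FieldMatrix:
    """Gramian angular summation field of a [0, 1]-rescaled series.

    Entry (i, j) is ``cos(phi_i + phi_j)`` with ``phi = arccos(x)``, computed
    in the equivalent algebraic outer-product form
    ``x x' - sqrt(1 - x^2) sqrt(1 - x^2)'``.  Symmetric; the diagonal is
    ``2 x_i^2 - 1``, so the rescaled series is recoverable from it.
    """
    x = _validate_rescaled(rescaled)
    root = np.sqrt(np.clip(1.0 - x * x, 0.0, 1.0))
    m = np.outer(x, x) - np.outer(root, root)
    return FieldMatrix("GASF", np.clip(m, -1.0, 1.0), (-1.0, 1.0))


def gadf(rescaled) -> FieldMatrix:
    """Gramian angular difference field of a [0, 1]-rescaled series.

    Entry (i, j) is ``sin(phi_i - phi_j) = sqrt(1-x_i^2) x_j - x_i
    sqrt(1-x_j^2)``.  Antisymmetric with an exactly zero diagonal.
    """
    x = _validate_rescaled(rescaled)
    root = np.sqrt(np.clip(1.0 - x * x, 0.0, 1.0))
    m = np.outer(root, x) - np.outer(x, root)
    return FieldMatrix("GADF", np.clip(m, -1.0, 1.0), (-1.0, 1.0))


def fit_markov(rescaled, n_bins: int = DEFAULT_BINS) -> MarkovModel:
    """Fit a first-order Markov chain over quantile bins of a series.

    Interior bin edges are the empirical ``i / n_bins`` quantiles.  The
    transition probability from bin i to bin j is the count of consecutive
    pairs moving i -> j divided by the count of pairs leaving i; rows with no
    outgoing transition stay all-zero.
    """
    x = _validate_rescaled(rescaled)
    if n_bins < 2:
        raise InvalidArgumentError(f"n_bins must be >= 2, got {n_bins}")
    n_distinct = np.unique(x).size
    if n_bins > n_distinct:
        raise DegenerateBinningError(
            f"{n_bins} quantile bins requested but the series has only "
            f"{n_distinct} distinct value(s)"
        )
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    bins = np.searchsorted(edges, x, side="left")
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (bins[:-1], bins[1:]), 1.0)
    out = counts.sum(axis=1, keepdims=True)
    w = np.divide(counts, out, out=np.zeros_like(counts), where=out > 0)
    return MarkovModel(bin_edges=edges, transitions=w, n_bins=n_bins)


def mtf(rescaled, n_bins: int = DEFAULT_BINS) -> FieldMatrix:
    """Markov transition field of a [0, 1]-rescaled series.

    Entry (i, j) is the fitted transition probability from the quantile bin
    of x(i) to the quantile bin of x(j).  Entries are probabilities in
    [0, 1]; unlike the Gramian fields the matrix is generally not symmetric.
    """
    x = _validate_rescaled(rescaled)
    model = fit_markov(x, n_bins)
    bins = model.assign_bins(x)
    m = model.transitions[bins[:, None], bins[None, :]]
    return FieldMatrix("MTF", m, (0.0, 1.0))
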