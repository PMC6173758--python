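"""Serial-dependence statistics for ISI sequences.

A renewal process has independent ISIs; these statistics quantify the ways
real afferent spike trains depart from that assumption:

* ``serial_correlation`` — the serial correlation coefficient SRC(n)
  between ISIs separated by n intermediate spikes, computed with the global
  sample mean and population variance, with a Pearson p-value against the
  null SRC(n) = 0;
* ``recurrence_matrix`` — the 4x4 matrix ``q_ij`` of frequencies with which
  an ISI in quartile i is followed by an ISI in quartile j (1/16 everywhere
  under independence);
* ``detect_sequences`` — maximal runs of consecutive short (below the
  global mean) or long ISIs whose within-run mean is more extreme than the
  mean of all short (or all long) ISIs, an adaptation of burst detection;
* ``fano_factor`` — variance/mean of spike counts in sliding windows of
  length dt (1 for a homogeneous Poisson process at every dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .shape import quartile_boundaries
from .spiketrain import ISISequence, SpikeTrain

__all__ = [
    "SerialCorrelation",
    "RecurrenceQuartileMatrix",
    "SequencePartition",
    "FanoCurve",
    "serial_correlation",
    "shuffle_isis",
    "recurrence_matrix",
    "detect_sequences",
    "fano_factor",
    "serial_stats_table",
]


@dataclass(frozen=True)
class SerialCorrelation:
    lag: int
    src: float
    p_value: float


def serial_correlation(isis: ISISequence, lag: int = 1) -> SerialCorrelation:
    """SRC(n): mean cross-product of deviations from the global mean of
    ISI pairs separated by ``lag`` intermediate spikes, normalized by the
    global (population) variance.

    The p-value is the Pearson-correlation significance computed on the
    lagged pair set under the null SRC(n) = 0.
    """
    x = isis.isis
    M = x.size
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if M <= lag + 1:
        raise ValueError(f"need more than lag+1={lag + 1} ISIs")
    mu = float(np.mean(x))
    var = float(np.mean((x - mu) ** 2))
    if var == 0.0:
        raise ValueError("SRC undefined: ISI variance is zero")
    src = float(np.mean((x[lag:] - mu) * (x[:-lag] - mu)) / var)
    p = float(sp_stats.pearsonr(x[:-lag], x[lag:]).pvalue)
    return SerialCorrelation(lag=lag, src=src, p_value=p)


def shuffle_isis(isis: ISISequence, seed) -> ISISequence:
    """Seed-reproducible uniform random permutation (multiset preserved)."""
    if isis.M < 2:
        raise ValueError("need at least 2 ISIs to shuffle")
    rng = np.random.default_rng(seed)
    return ISISequence(rng.permutation(isis.isis))


@dataclass(frozen=True)
class RecurrenceQuartileMatrix:
    """Fractions ``q[i, j]`` of consecutive ISI pairs with the previous ISI
    in quartile i and the next in quartile j (0-based indices; entries sum
    to 1)."""

    q: np.ndarray


def _quartile_index(values: np.ndarray, T: np.ndarray) -> np.ndarray:
    # T are boundaries T_0..T_4; an ISI exactly on a boundary belongs to
    # the lower quartile (type-1 quantile convention)
    inner = T[1:4]
    if not (inner[0] < inner[1] < inner[2]):
        k = 1 if inner[0] >= inner[1] else 2
        raise ValueError(
            f"degenerate quartiles: boundaries T_{k} and T_{k + 1} coincide "
            f"at {inner[k - 1]:g} ms (heavy ties in the data)"
        )
    return np.searchsorted(inner, values, side="left")


def recurrence_matrix(isis: ISISequence) -> RecurrenceQuartileMatrix:
    """Tally quartile transitions over the M-1 consecutive ISI pairs."""
    if isis.M < 20:
        raise ValueError("recurrence matrix requires at least 20 ISIs")
    T = quartile_boundaries(isis)
    idx = _quartile_index(isis.isis, T)
    q = np.zeros((4, 4))
    np.add.at(q, (idx[:-1], idx[1:]), 1.0)
    q /= isis.M - 1
    return RecurrenceQuartileMatrix(q=q)


@dataclass(frozen=True)
class SequencePartition:
    """Detected short/long ISI sequences.

    ``runs`` holds (start, end, label) index triples (inclusive ends) of the
    accepted sequences; ``frac_in_short``/``frac_in_long`` are the fractions
    of all ISIs inside accepted short/long sequences.
    """

    runs: list
    mu_short: float
    mu_long: float
    frac_in_short: float
    frac_in_long: float


def detect_sequences(
    isis: ISISequence, min_run_length: int = 2
) -> SequencePartition:
    """Partition an ISI sequence into short/long sequences.

    Each ISI is classed short (< global mean) or long (>= global mean).
    Maximal same-class runs of at least ``min_run_length`` ISIs are accepted
    as sequences when the within-run mean is at or below the mean of all
    short ISIs (for short runs) or at or above the mean of all long ISIs
    (for long runs); scanning is greedy left-to-right with no overlap.
    Ties at the acceptance threshold are a measure-zero event for
    continuous data; they are included so perfectly separated blocks
    qualify.
    """
    x = isis.isis
    M = x.size
    if M < 10:
        raise ValueError("sequence detection requires at least 10 ISIs")
    mu = float(np.mean(x))
    short_mask = x < mu
    if not short_mask.any() or short_mask.all():
        raise ValueError("both short and long ISI classes must be non-empty")
    mu_short = float(np.mean(x[short_mask]))
    mu_long = float(np.mean(x[~short_mask]))

    runs = []
    n_short = n_long = 0
    i = 0
    while i < M:
        j = i
        while j + 1 < M and short_mask[j + 1] == short_mask[i]:
            j += 1
        length = j - i + 1
        if length >= min_run_length:
            run_mean = float(np.mean(x[i : j + 1]))
            if short_mask[i] and run_mean <= mu_short:
                runs.append((i, j, "short"))
                n_short += length
            elif not short_mask[i] and run_mean >= mu_long:
                runs.append((i, j, "long"))
                n_long += length
        i = j + 1
    return SequencePartition(
        runs=runs,
        mu_short=mu_short,
        mu_long=mu_long,
        frac_in_short=n_short / M,
        frac_in_long=n_long / M,
    )


@dataclass(frozen=True)
class FanoCurve:
    """Fano factors F(dt) over a grid of counting-window lengths (ms).

    Entries are NaN where the statistic is undefined (mean count zero or
    the recording shorter than the window)."""

    dt: np.ndarray
    F: np.ndarray


def fano_factor(
    train: SpikeTrain, dt_list, stride_fraction: float = 0.1
) -> FanoCurve:
    """Variance-to-mean ratio of spike counts in sliding windows.

    For each window length ``dt`` the recording is covered by overlapping
    windows advancing by ``stride_fraction * dt`` (windows fully inside the
    recording).  The recording must span at least 10x the largest window.
    """
    dt_arr = np.sort(np.asarray(dt_list, dtype=float))
    if np.any(dt_arr <= 0):
        raise ValueError("window lengths must be positive")
    times = train.times
    total = times[-1] - times[0]
    if total < 10 * dt_arr[-1]:
        raise ValueError(
            "recording must span at least 10x the largest counting window"
        )
    F = np.full(dt_arr.size, math.nan)
    for k, dt in enumerate(dt_arr):
        stride = stride_fraction * dt
        starts = np.arange(times[0], times[-1] - dt + 1e-12, stride)
        counts = np.searchsorted(times, starts + dt, side="right") - np.searchsorted(
            times, starts, side="left"
        )
        mean = counts.mean()
        if mean > 0:
            F[k] = counts.var() / mean
    return FanoCurve(dt=dt_arr, F=F)


def serial_stats_table(
    isis: ISISequence,
    lags=(1, 5, 10, 50),
    train: SpikeTrain | None = None,
    fano_dt=None,
) -> dict:
    """Bundle SRC-by-lag, recurrence matrix, sequence fractions, and an
    optional Fano curve into plain dict/DataFrame report pieces."""
    src_rows = []
    for n in lags:
        if isis.M > n + 1:
            sc = serial_correlation(isis, n)
            src_rows.append(dict(lag=n, src=sc.src, p_value=sc.p_value))
    out = {"src": pd.DataFrame(src_rows)}
    out["recurrence_q"] = recurrence_matrix(isis).q
    seq = detect_sequences(isis)
    out["frac_in_short"] = seq.frac_in_short
    out["frac_in_long"] = seq.frac_in_long
    if train is not None and fano_dt is not None:
        fc = fano_factor(train, fano_dt)
        out["fano"] = pd.DataFrame({"dt_ms": fc.dt, "fano": fc.F})
    return out
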