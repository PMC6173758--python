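"""Spike-train and interspike-interval containers, empirical CDF, and text I/O.

All times in this package are in milliseconds.  A :class:`SpikeTrain` is an
ordered vector of spike timestamps; an :class:`ISISequence` is the ordered
vector of successive differences, which is the unit of analysis everywhere
else in the package.  Temporal order is preserved — sorting happens only
inside CDF and quantile computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SpikeTrain",
    "ISISequence",
    "EmpiricalCDF",
    "SummaryStats",
    "isis_from_spikes",
    "empirical_cdf",
    "summary_stats",
    "read_spike_file",
    "write_spike_file",
    "read_isi_file",
    "write_isi_file",
]


class InvalidSpikeDataError(ValueError):
    """Raised when spike or ISI input violates a structural requirement."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike timestamps in milliseconds.

    Timestamps must be strictly increasing.
    """

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise InvalidSpikeDataError("spike times must be a 1-D sequence")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise InvalidSpikeDataError(
                f"spike times must be strictly increasing (violation at index {bad})"
            )
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Span from first to last spike, ms."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class ISISequence:
    """Ordered interspike intervals in milliseconds; all values must be > 0."""

    isis: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.isis, dtype=float)
        if x.ndim != 1:
            raise InvalidSpikeDataError("ISIs must be a 1-D sequence")
        if x.size and not np.all(x > 0):
            raise InvalidSpikeDataError("all ISIs must be strictly positive")
        object.__setattr__(self, "isis", x)

    def __len__(self) -> int:
        return self.isis.size

    @property
    def M(self) -> int:
        """Number of ISIs."""
        return self.isis.size

    def sorted(self) -> np.ndarray:
        return np.sort(self.isis)

    def to_spike_train(self, t0: float = 0.0) -> SpikeTrain:
        """Reconstruct a spike train by cumulative summation from ``t0``."""
        return SpikeTrain(t0 + np.concatenate([[0.0], np.cumsum(self.isis)]))


def isis_from_spikes(train: SpikeTrain) -> ISISequence:
    """Successive differences of spike times, in original temporal order."""
    if len(train) < 2:
        raise InvalidSpikeDataError("need at least 2 spikes to form ISIs")
    return ISISequence(np.diff(train.times))


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous empirical step CDF of an ISI sample.

    ``F(t)`` is 0 below the smallest value, steps by 1/M at each sorted value
    (by multiplicity at ties), and is 1 at and above the largest value.
    """

    sorted_values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.sorted_values, dtype=float)
        object.__setattr__(self, "sorted_values", np.sort(v))

    @property
    def M(self) -> int:
        return self.sorted_values.size

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.searchsorted(self.sorted_values, t, side="right") / self.M
        return out if out.ndim else float(out)


def empirical_cdf(isis: ISISequence) -> EmpiricalCDF:
    """Empirical CDF of an ISI sample as a piecewise step function."""
    if isis.M < 1:
        raise InvalidSpikeDataError("empirical CDF requires at least one ISI")
    return EmpiricalCDF(isis.isis.copy())


@dataclass(frozen=True)
class SummaryStats:
    """Mean (ms), coefficient of variation, and raw kurtosis of an ISI sample.

    Kurtosis is the raw fourth standardized moment (population formula, not
    excess and not bias-corrected), so an exponential sample converges to 9
    and a normal one to 3.  ``kurtosis`` is NaN for a zero-variance sample.
    """

    mean: float
    cv: float
    kurtosis: float


def summary_stats(isis: ISISequence) -> SummaryStats:
    if isis.M < 4:
        raise InvalidSpikeDataError("summary statistics require at least 4 ISIs")
    x = isis.isis
    mu = float(np.mean(x))
    d = x - mu
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        return SummaryStats(mean=mu, cv=0.0, kurtosis=math.nan)
    m4 = float(np.mean(d**4))
    return SummaryStats(mean=mu, cv=math.sqrt(m2) / mu, kurtosis=m4 / (m2 * m2))


# ---------------------------------------------------------------------------
# text I/O: one timestamp per line, '#' comments, optional single header,
# or a CSV with a time_ms / isi_ms column.


def _read_numeric_column(path, column: str) -> list[tuple[int, float]]:
    """Return (line number, value) pairs from a one-column or CSV text file."""
    path = Path(path)
    rows: list[tuple[int, float]] = []
    col = 0
    header_allowed = True
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(",")]
            if header_allowed and column in fields:
                col = fields.index(column)
                header_allowed = False
                continue
            try:
                rows.append((lineno, float(fields[col])))
            except (ValueError, IndexError):
                if header_allowed:
                    header_allowed = False  # tolerate one non-numeric header
                    continue
                raise InvalidSpikeDataError(
                    f"{path}: unparseable value on line {lineno}: {line!r}"
                )
            header_allowed = False
    if not rows:
        raise InvalidSpikeDataError(f"{path}: no numeric data found")
    return rows


def read_spike_file(path) -> SpikeTrain:
    """Read spike times (ms) from a text or CSV file.

    Accepts one float per line with optional ``#`` comments and a single
    optional header, or a CSV with a ``time_ms`` column.  Non-monotone input
    raises an error naming the offending line.
    """
    rows = _read_numeric_column(path, "time_ms")
    for (ln_prev, v_prev), (ln, v) in zip(rows, rows[1:]):
        if v <= v_prev:
            raise InvalidSpikeDataError(
                f"{path}: spike times not strictly increasing at line {ln} "
                f"({v} after {v_prev})"
            )
    return SpikeTrain(np.array([v for _, v in rows]))


def write_spike_file(train: SpikeTrain, path, fmt: str = "%.6f") -> None:
    """Write spike times, one per line (ms)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spike times, ms\n")
        for t in train.times:
            fh.write((fmt % t) + "\n")


def read_isi_file(path) -> ISISequence:
    """Read an ISI series (ms): one value per line or CSV with ``isi_ms``."""
    rows = _read_numeric_column(path, "isi_ms")
    return ISISequence(np.array([v for _, v in rows]))


def write_isi_file(isis: ISISequence, path, fmt: str = "%.6f") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# interspike intervals, ms\n")
        for t in isis.isis:
            fh.write((fmt % t) + "\n")
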