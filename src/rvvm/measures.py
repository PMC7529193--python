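"""Measure-valued sample data.

A *measurement protocol* records, for each sample unit, not a number but a
finitely supported probability measure over the possible values of the target
variable.  A point mass recovers ordinary fixed data; a Bernoulli measure
``Ber(theta)`` encodes an assessor's confidence ``theta`` that a binary trait
is present; a categorical measure spreads confidence over an ordinal scale.
This module provides the measure type, per-unit records, whole-sample
containers, moments, information content, and a plain-text CSV dialect in
which measure cells are written as literals (``0.4``, ``ber:0.9``,
``cat:0:0.1,2:0.9``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiscreteMeasure",
    "MeasurementRecord",
    "ProtocolSample",
    "MeasureParseError",
    "InfiniteDivergenceError",
    "make_point_mass",
    "make_bernoulli",
    "make_categorical",
    "expectation",
    "variance",
    "information_content",
    "parse_measure",
    "serialize_measure",
    "read_protocol_csv",
    "write_protocol_csv",
]

#: probs must sum to 1 within this after renormalization
_SUM_TOL = 1e-9
#: tolerance used when testing measures for exact equality (grouping)
_EQ_TOL = 1e-12


class MeasureParseError(ValueError):
    """A measure literal does not conform to the grammar."""


class InfiniteDivergenceError(ValueError):
    """The measure assigns zero mass to the true value: infinite KL divergence."""


@dataclass(frozen=True)
class DiscreteMeasure:
    """A finitely supported Borel probability measure on the real line.

    Atoms carrying exactly zero probability are dropped at construction, so
    every instance is in canonical form: ``support`` strictly increasing,
    ``probs`` positive and summing to one.
    """

    support: tuple
    probs: tuple

    def __init__(self, support: Sequence[float], probs: Sequence[float]):
        support = [float(x) for x in support]
        probs = [float(p) for p in probs]
        if len(support) != len(probs):
            raise ValueError("support and probs must have equal length")
        if len(support) == 0:
            raise ValueError("a probability measure needs at least one atom")
        for x in support:
            if not math.isfinite(x):
                raise ValueError(f"non-finite support value {x!r}")
        for p in probs:
            if not (0.0 <= p <= 1.0 + _SUM_TOL):
                raise ValueError(f"probability {p!r} outside [0, 1]")
        total = math.fsum(probs)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        # renormalize away decimal rounding, then drop uncharged atoms
        pairs = [(x, p / total) for x, p in zip(support, probs) if p > 0.0]
        pairs.sort(key=lambda t: t[0])
        xs = [x for x, _ in pairs]
        if len(set(xs)) != len(xs):
            raise ValueError("support values must be distinct")
        object.__setattr__(self, "support", tuple(xs))
        object.__setattr__(self, "probs", tuple(p for _, p in pairs))

    @property
    def is_point_mass(self) -> bool:
        return len(self.support) == 1

    def prob_of(self, x: float) -> float:
        """Mass assigned to the single point ``x`` (0.0 if uncharged)."""
        for xi, pi in zip(self.support, self.probs):
            if xi == x:
                return pi
        return 0.0

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def var(self) -> float:
        m = self.mean()
        return max(0.0, float(np.dot(np.square(self.support), self.probs)) - m * m)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        return rng.choice(np.asarray(self.support), size=size, p=np.asarray(self.probs))

    def equality_key(self) -> tuple:
        """Hashable key identifying this measure up to float tolerance."""
        return (
            tuple(round(x, 12) for x in self.support),
            tuple(round(p, 12) for p in self.probs),
        )

    def isclose(self, other: "DiscreteMeasure", tol: float = _EQ_TOL) -> bool:
        return (
            len(self.support) == len(other.support)
            and all(abs(a - b) <= tol for a, b in zip(self.support, other.support))
            and all(abs(a - b) <= tol for a, b in zip(self.probs, other.probs))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DiscreteMeasure({serialize_measure(self)!r})"


def make_point_mass(x: float) -> DiscreteMeasure:
    """The trivial measure concentrated at ``x`` — classical fixed data."""
    if not math.isfinite(float(x)):
        raise ValueError(f"point mass location must be finite, got {x!r}")
    return DiscreteMeasure([float(x)], [1.0])


def make_bernoulli(theta: float) -> DiscreteMeasure:
    """``Ber(theta)`` on {0, 1}; theta in {0, 1} collapses to a point mass."""
    theta = float(theta)
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"Bernoulli parameter {theta!r} outside [0, 1]")
    return DiscreteMeasure([0.0, 1.0], [1.0 - theta, theta])


def make_categorical(values: Sequence[float], probs: Sequence[float]) -> DiscreteMeasure:
    """A categorical measure over arbitrary (ordered) real category values."""
    return DiscreteMeasure(values, probs)


def expectation(m: DiscreteMeasure) -> float:
    """First moment of the measure: the per-unit contribution to the generalized mean."""
    return m.mean()


def variance(m: DiscreteMeasure) -> float:
    """Second central moment; zero exactly for point masses."""
    return m.var()


def information_content(m: DiscreteMeasure, y_true: float) -> float:
    """Information content ``-log mu({y_true})`` in nats.

    Equals the KL divergence from the measure to the point mass at the true
    value; zero iff the measure is a point mass at the truth.  A measure that
    excludes the truth has infinite divergence and raises.
    """
    p = m.prob_of(float(y_true))
    if p <= 0.0:
        raise InfiniteDivergenceError(
            f"measure assigns zero mass to y={y_true!r}; the protocol excludes the truth"
        )
    return -math.log(p)


# ---------------------------------------------------------------------------
# measure-literal grammar

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_measure(text: str) -> DiscreteMeasure:
    """Parse one measure literal: ``<number>`` | ``ber:<p>`` | ``cat:v:p,v:p,...``.

    A bare numeral is a point mass, so classical numeric datasets are valid
    measure-valued datasets unchanged.
    """
    if not isinstance(text, str):
        raise MeasureParseError(f"expected a string literal, got {text!r}")
    text = text.strip()
    if _NUMBER_RE.match(text):
        return make_point_mass(float(text))
    if text.lower().startswith("ber:"):
        body = text[4:]
        if not _NUMBER_RE.match(body):
            raise MeasureParseError(f"malformed Bernoulli literal {text!r}")
        theta = float(body)
        if not (0.0 <= theta <= 1.0):
            raise MeasureParseError(f"Bernoulli parameter out of range in {text!r}")
        return make_bernoulli(theta)
    if text.lower().startswith("cat:"):
        body = text[4:]
        values, probs = [], []
        for token in body.split(","):
            parts = token.split(":")
            if len(parts) != 2 or not _NUMBER_RE.match(parts[0]) or not _NUMBER_RE.match(parts[1]):
                raise MeasureParseError(f"malformed categorical atom {token!r} in {text!r}")
            values.append(float(parts[0]))
            probs.append(float(parts[1]))
        total = math.fsum(probs)
        if abs(total - 1.0) > _SUM_TOL:
            raise MeasureParseError(
                f"categorical probabilities sum to {total} in {text!r}"
            )
        try:
            return make_categorical(values, probs)
        except ValueError as exc:
            raise MeasureParseError(f"invalid categorical literal {text!r}: {exc}") from exc
    raise MeasureParseError(f"unrecognized measure literal {text!r}")


def _fmt(x: float) -> str:
    """Shortest plain decimal that round-trips through float()."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def serialize_measure(m: DiscreteMeasure) -> str:
    """Canonical literal for a measure; inverse of :func:`parse_measure`."""
    if m.is_point_mass:
        return _fmt(m.support[0])
    if m.support == (0.0, 1.0):
        return f"ber:{_fmt(m.probs[1])}"
    return "cat:" + ",".join(f"{_fmt(x)}:{_fmt(p)}" for x, p in zip(m.support, m.probs))


# ---------------------------------------------------------------------------
# sample containers


@dataclass
class MeasurementRecord:
    """One sample unit: its measure, ordinary covariates, optional gold truth.

    If a gold-standard truth is supplied it must lie in the measure's support
    unless the record is explicitly flagged as carrying classical measurement
    error (a point mass not supported on the truth).
    """

    unit_id: object
    measure: DiscreteMeasure
    covariates: Mapping[str, float] = field(default_factory=dict)
    truth: Optional[float] = None
    measurement_error: bool = False

    def __post_init__(self):
        if self.truth is not None and not self.measurement_error:
            if self.measure.prob_of(float(self.truth)) == 0.0:
                raise ValueError(
                    f"unit {self.unit_id!r}: truth {self.truth!r} outside the "
                    "measure's support (flag measurement_error to allow)"
                )


@dataclass
class ProtocolSample:
    """An ordered simple random sample of independent measurements.

    Independence of the per-unit measures is a modelling contract; nothing in
    the container can or does verify it.
    """

    records: list
    range_y: Optional[frozenset] = None

    def __post_init__(self):
        if self.range_y is not None:
            bad = [
                r.unit_id
                for r in self.records
                if not set(r.measure.support) <= set(self.range_y)
            ]
            if bad:
                raise ValueError(
                    f"records {bad!r} have support outside the declared range of Y"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.records)

    def measures(self) -> list:
        return [r.measure for r in self.records]

    def is_all_point_mass(self) -> bool:
        return all(r.measure.is_point_mass for r in self.records)

    def subset(self, predicate) -> "ProtocolSample":
        return ProtocolSample([r for r in self.records if predicate(r)], self.range_y)


# ---------------------------------------------------------------------------
# CSV dialect


def read_protocol_csv(
    path,
    column: str,
    truth_column: Optional[str] = None,
    covariate_columns: Optional[Iterable[str]] = None,
    id_column: Optional[str] = None,
) -> ProtocolSample:
    """Read a measure-valued sample from CSV.

    ``column`` holds measure literals; ``truth_column`` defaults to
    ``<column>__truth`` when such a column exists.  Cells that are empty / NA
    are dropped (the unit was discarded by the protocol).
    """
    df = pd.read_csv(path, dtype=str)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not in {list(df.columns)}")
    if truth_column is None and f"{column}__truth" in df.columns:
        truth_column = f"{column}__truth"
    if covariate_columns is None:
        covariate_columns = []
    records = []
    for idx, row in df.iterrows():
        cell = row[column]
        if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() in ("", "NA", "NaN"):
            continue
        measure = parse_measure(str(cell))
        truth = None
        if truth_column is not None:
            t = row[truth_column]
            if t is not None and str(t).strip() not in ("", "NA", "NaN", "nan"):
                truth = float(t)
        covs = {c: float(row[c]) for c in covariate_columns}
        unit = row[id_column] if id_column else idx
        records.append(
            MeasurementRecord(unit_id=unit, measure=measure, covariates=covs, truth=truth)
        )
    return ProtocolSample(records)


def write_protocol_csv(sample: ProtocolSample, path, column: str = "y") -> None:
    """Write a sample in the CSV dialect (measure literals, ``__truth`` column)."""
    cov_names: list = []
    for r in sample.records:
        for k in r.covariates:
            if k not in cov_names:
                cov_names.append(k)
    rows = []
    for r in sample.records:
        row = {"unit_id": r.unit_id, column: serialize_measure(r.measure)}
        row.update({k: r.covariates.get(k) for k in cov_names})
        if r.truth is not None:
            row[f"{column}__truth"] = r.truth
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
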