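"""Empirical calibration checks against gold-standard truths.

A measurement protocol is *calibrated* when, among all units assigned the
same measure, the mean of the true values equals that measure's expectation —
e.g. of all birds sexed "female with 90% confidence", 90% really are female.
Given a sample with a truth column, we partition records by exact measure
equality, compare each group's empirical truth mean with the measure
expectation, and (for binary traits) attach exact binomial p-values with a
Holm adjustment.  No accept/reject decision is made here: the report is a
diagnostic, and the threshold for declaring a protocol calibrated is the
analyst's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .measures import DiscreteMeasure, ProtocolSample, make_bernoulli

__all__ = ["CalibrationGroup", "CalibrationReport", "group_by_measure", "calibration_report"]


@dataclass
class CalibrationGroup:
    """All records sharing one measure, with the group's empirical truth mean."""

    measure: DiscreteMeasure
    unit_ids: list
    truths: list
    measure_expectation: float
    empirical_mean: float

    @property
    def count(self) -> int:
        return len(self.unit_ids)

    @property
    def discrepancy(self) -> float:
        return abs(self.measure_expectation - self.empirical_mean)


@dataclass
class CalibrationReport:
    groups: list
    max_abs_discrepancy: float
    weighted_mean_discrepancy: float
    #: exact two-sided binomial p-values, aligned with groups (None if not binary)
    binomial_pvalues: list = field(default_factory=list)
    holm_pvalues: list = field(default_factory=list)
    binned: bool = False

    def to_dict(self) -> dict:
        return {
            "max_abs_discrepancy": self.max_abs_discrepancy,
            "weighted_mean_discrepancy": self.weighted_mean_discrepancy,
            "binned": self.binned,
            "groups": [
                {
                    "measure_expectation": g.measure_expectation,
                    "empirical_mean": g.empirical_mean,
                    "count": g.count,
                    "discrepancy": g.discrepancy,
                    "binomial_p": p,
                    "holm_p": hp,
                }
                for g, p, hp in zip(self.groups, self.binomial_pvalues, self.holm_pvalues)
            ],
        }

    def to_text(self) -> str:
        lines = [
            f"{'E[mu]':>8} {'mean(Y)':>8} {'n':>6} {'|diff|':>8} {'p':>8}",
        ]
        for g, p in zip(self.groups, self.binomial_pvalues):
            ptxt = f"{p:8.4f}" if p is not None else "       -"
            lines.append(
                f"{g.measure_expectation:8.4f} {g.empirical_mean:8.4f} "
                f"{g.count:6d} {g.discrepancy:8.4f} {ptxt}"
            )
        lines.append(
            f"max |discrepancy| = {self.max_abs_discrepancy:.4f}; "
            f"count-weighted mean = {self.weighted_mean_discrepancy:.4f}"
        )
        return "\n".join(lines)


def group_by_measure(
    sample: ProtocolSample, bin_width: Optional[float] = None
) -> list:
    """Partition records by exact measure equality (optionally binned confidences).

    Every record must carry a truth.  ``bin_width`` is a pragmatic extension
    for sparse real data: Bernoulli confidences are rounded to multiples of
    the width before grouping, and the group's measure is the bin-average
    confidence.  Groups are returned ordered by measure expectation.
    """
    missing = [r.unit_id for r in sample.records if r.truth is None]
    if missing:
        raise ValueError(f"records missing gold-standard truth: {missing!r}")
    buckets: dict = {}
    for r in sample.records:
        m = r.measure
        if bin_width is not None and set(m.support) <= {0.0, 1.0}:
            key = ("ber-bin", round(m.prob_of(1.0) / bin_width))
        else:
            key = m.equality_key()
        buckets.setdefault(key, []).append(r)
    groups = []
    for key, recs in buckets.items():
        if bin_width is not None and isinstance(key, tuple) and key[0] == "ber-bin":
            measure = make_bernoulli(float(np.mean([r.measure.prob_of(1.0) for r in recs])))
        else:
            measure = recs[0].measure
        truths = [float(r.truth) for r in recs]
        groups.append(
            CalibrationGroup(
                measure=measure,
                unit_ids=[r.unit_id for r in recs],
                truths=truths,
                measure_expectation=measure.mean(),
                empirical_mean=float(np.mean(truths)),
            )
        )
    groups.sort(key=lambda g: g.measure_expectation)
    return groups


def calibration_report(groups: list, binned: bool = False) -> CalibrationReport:
    """Summarize per-group discrepancies; exact binomial tests for binary groups."""
    if not groups:
        raise ValueError("calibration report requires at least one group")
    counts = np.array([g.count for g in groups], dtype=float)
    discrepancies = np.array([g.discrepancy for g in groups])
    pvals: list = []
    for g in groups:
        if set(g.measure.support) <= {0.0, 1.0} and set(map(float, g.truths)) <= {0.0, 1.0}:
            successes = int(round(sum(g.truths)))
            p0 = g.measure.prob_of(1.0)
            if 0.0 < p0 < 1.0:
                pvals.append(float(stats.binomtest(successes, g.count, p0).pvalue))
            else:
                # degenerate null: p-value 1 if all truths agree, else 0
                pvals.append(1.0 if g.discrepancy == 0.0 else 0.0)
        else:
            pvals.append(None)
    tested = [p for p in pvals if p is not None]
    holm_map: dict = {}
    if tested:
        adj = multipletests(tested, method="holm")[1]
        holm_map = dict(zip(range(len(tested)), adj))
    holm: list = []
    ti = 0
    for p in pvals:
        if p is None:
            holm.append(None)
        else:
            holm.append(float(holm_map[ti]))
            ti += 1
    return CalibrationReport(
        groups=groups,
        max_abs_discrepancy=float(discrepancies.max()),
        weighted_mean_discrepancy=float(np.average(discrepancies, weights=counts)),
        binomial_pvalues=pvals,
        holm_pvalues=holm,
        binned=binned,
    )
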