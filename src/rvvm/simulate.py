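"""Synthetic data generators: a bird-banding survey and a clinical rating scale.

Two study designs are emulated.  The first is a songbird banding operation
where adults are sexed definitively by plumage but juveniles often admit only
a confidence ("female with probability 0.9"): three protocols are recorded —
``rho1`` the idealized full-truth data, ``rho2`` the current field practice
of discarding uncertain birds, and ``rho3`` keeping uncertain birds as
Bernoulli confidence measures.  The second is a 17-item depression rating
scale (HAM-D-style, items scored 0-4) where the assessor spreads confidence
over categories instead of forcing a single score.

The stochastic bird generator is *calibrated by construction*: each
partially sexed juvenile first receives a confidence ``c`` drawn from a Beta
distribution, and its true sex is then drawn as Bernoulli(c) — so among all
birds assigned confidence c, a fraction c really are female, exactly the
calibration condition.  Strata frequencies and the per-stratum Normal weight
and wing-chord distributions follow the worked survey: 50% of adults and 75%
of juveniles female, adult weights N(50, 5) (female) / N(60, 5) (male),
definitively sexed juveniles N(30, 5) (F) / N(40, 5) (M), partially sexed
juveniles N(20, 5) (F) / N(30, 5) (M); wing chord N(11, 1) everywhere except
juvenile males at N(8, 1).  The Normal second parameter is read as a
standard deviation throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .measures import (
    MeasurementRecord,
    ProtocolSample,
    make_bernoulli,
    make_categorical,
    make_point_mass,
    parse_measure,
    serialize_measure,
)

__all__ = [
    "BirdSimConfig",
    "BirdDataset",
    "generate_birds",
    "paper_bird_fixture",
    "generate_ratings",
    "ratings_item_sample",
    "hamd_item1_fixture",
]

# weight strata keyed by (adult, female, partial); values are (mean, sd) in grams
_WEIGHT_STRATA: Dict[Tuple[int, int, bool], Tuple[float, float]] = {
    (1, 1, False): (50.0, 5.0),
    (1, 0, False): (60.0, 5.0),
    (0, 1, False): (30.0, 5.0),
    (0, 1, True): (20.0, 5.0),
    (0, 0, False): (40.0, 5.0),
    (0, 0, True): (30.0, 5.0),
}

# wing chord strata keyed by (adult, female); cm
_WINGCHORD_STRATA: Dict[Tuple[int, int], Tuple[float, float]] = {
    (1, 1): (11.0, 1.0),
    (1, 0): (11.0, 1.0),
    (0, 1): (11.0, 1.0),
    (0, 0): (8.0, 1.0),
}


@dataclass(frozen=True)
class BirdSimConfig:
    """Study conditions for the simulated banding survey."""

    n_birds: int = 50
    adult_fraction: float = 0.76  # 38 of 50 in the worked survey
    adult_female_prob: float = 0.50
    juvenile_female_prob: float = 0.75
    juvenile_partial_prob: float = 2.0 / 3.0  # 8 of 12 juveniles
    #: Beta concentration of the confidence distribution; its mean is the
    #: juvenile female probability, which makes the protocol calibrated.
    confidence_concentration: float = 5.0
    weight_strata: Dict[Tuple[int, int, bool], Tuple[float, float]] = field(
        default_factory=lambda: dict(_WEIGHT_STRATA)
    )
    wingchord_strata: Dict[Tuple[int, int], Tuple[float, float]] = field(
        default_factory=lambda: dict(_WINGCHORD_STRATA)
    )

    def __post_init__(self):
        for p in (
            self.adult_fraction,
            self.adult_female_prob,
            self.juvenile_female_prob,
            self.juvenile_partial_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p!r} outside [0, 1]")
        if self.n_birds < 0:
            raise ValueError("n_birds must be nonnegative")
        if self.confidence_concentration <= 0:
            raise ValueError("confidence concentration must be positive")
        for mean, sd in list(self.weight_strata.values()) + list(
            self.wingchord_strata.values()
        ):
            if sd <= 0:
                raise ValueError("stratum standard deviations must be positive")


@dataclass
class BirdDataset:
    """The banding table: one row per bird, three sex protocols side by side.

    ``sex_rho3`` equals ``sex_rho1`` on definitively sexed rows and carries a
    Bernoulli confidence literal elsewhere; ``sex_rho2`` is missing exactly
    where ``sex_rho3`` is nontrivial.
    """

    table: pd.DataFrame

    def protocol_sample(
        self,
        protocol: str = "rho3",
        covariates: Sequence[str] = (),
        with_truth: bool = True,
    ) -> ProtocolSample:
        """Records under one protocol; ``rho2`` drops unsexed birds."""
        col = f"sex_{protocol}"
        records = []
        for _, row in self.table.iterrows():
            cell = row[col]
            if pd.isna(cell):
                continue
            measure = parse_measure(str(cell))
            truth = float(row["sex_truth"]) if with_truth else None
            covs = {c: float(row[c]) for c in covariates}
            records.append(
                MeasurementRecord(
                    unit_id=int(row["index"]),
                    measure=measure,
                    covariates=covs,
                    truth=truth,
                )
            )
        return ProtocolSample(records, range_y=frozenset({0.0, 1.0}))

    def to_csv(self, path_or_buf=None):
        return self.table.to_csv(path_or_buf, index=False)


def generate_birds(config: BirdSimConfig = BirdSimConfig(), seed: int = 0) -> BirdDataset:
    """Simulate a banding survey; deterministic given the seed.

    The partial-status flag is drawn per juvenile *before* the confidence,
    truth, and weight so that the stratified weight distributions apply, and
    the calibrated mechanism draws confidence first and truth from it.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cc = config.confidence_concentration
    a = config.juvenile_female_prob * cc
    b = (1.0 - config.juvenile_female_prob) * cc
    for i in range(config.n_birds):
        adult = int(rng.random() < config.adult_fraction)
        if adult:
            partial = False
            female = int(rng.random() < config.adult_female_prob)
            confidence = None
        else:
            partial = bool(rng.random() < config.juvenile_partial_prob)
            if partial:
                confidence = float(rng.beta(a, b))
                female = int(rng.random() < confidence)
            else:
                confidence = None
                female = int(rng.random() < config.juvenile_female_prob)
        w_mean, w_sd = config.weight_strata[(adult, female, partial)]
        wc_mean, wc_sd = config.wingchord_strata[(adult, female)]
        weight = float(rng.normal(w_mean, w_sd))
        wingchord = float(rng.normal(wc_mean, wc_sd))
        rho1 = serialize_measure(make_point_mass(female))
        rho3 = (
            serialize_measure(make_bernoulli(confidence)) if partial else rho1
        )
        rows.append(
            {
                "index": i + 1,
                "age": adult,
                "weight": round(weight, 3),
                "wing_chord": round(wingchord, 3),
                "sex_rho3": rho3,
                "sex_rho2": None if partial else rho1,
                "sex_rho1": rho1,
                "sex_truth": female,
            }
        )
    return BirdDataset(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# the fixed 50-bird survey

# the 17 rows printed in the survey snapshot: index, age, weight, wing chord,
# rho3 literal, true sex
_PRINTED_ROWS = [
    (34, 1, 52.087, 11.239, "ber:0", 0),
    (35, 1, 56.623, 12.379, "ber:0", 0),
    (36, 1, 57.288, 10.048, "ber:0", 0),
    (37, 1, 68.327, 8.315, "ber:0", 0),
    (38, 1, 60.219, 10.613, "ber:0", 0),
    (39, 0, 38.566, 11.957, "ber:1", 1),
    (40, 0, 21.984, 9.999, "ber:1", 1),
    (41, 0, 32.770, 10.194, "ber:1", 1),
    (42, 0, 26.276, 11.780, "ber:1", 1),
    (43, 0, 14.701, 11.553, "ber:0.9", 1),
    (44, 0, 11.902, 11.812, "ber:0.9", 1),
    (45, 0, 25.015, 9.737, "ber:0.8", 1),
    (46, 0, 23.797, 12.210, "ber:0.8", 1),
    (47, 0, 12.305, 11.174, "ber:0.7", 1),
    (48, 0, 29.453, 8.261, "ber:0.4", 0),
    (49, 0, 33.304, 7.370, "ber:0.3", 0),
    (50, 0, 27.099, 7.424, "ber:0.2", 0),
]


def paper_bird_fixture(fill_seed: int = 20200917) -> BirdDataset:
    """The fixed 50-bird survey used throughout the worked example.

    Marginal counts are canonical: 38 adults of which 19 female, 4
    definitively sexed juveniles (all female), and 8 partially sexed
    juveniles with confidences 0.9, 0.9, 0.8, 0.8, 0.7, 0.4, 0.3, 0.2 and
    true sexes (1, 1, 1, 1, 1, 0, 0, 0).  Rows 34-50 (5 adult males, the 4
    definitive juvenile females, and the 8 partials) carry their published
    weights and wing chords; weights and wing chords of rows 1-33 (19 adult
    females, 14 adult males) are SYNTHETIC fills drawn from the stratum
    distributions with a fixed seed, as the originals were never published.
    """
    rng = np.random.default_rng(fill_seed)
    rows = []
    # rows 1-19: adult females; rows 20-33: adult males (fills)
    for i in range(1, 34):
        female = 1 if i <= 19 else 0
        w_mean, w_sd = _WEIGHT_STRATA[(1, female, False)]
        wc_mean, wc_sd = _WINGCHORD_STRATA[(1, female)]
        lit = serialize_measure(make_point_mass(female))
        rows.append(
            {
                "index": i,
                "age": 1,
                "weight": round(float(rng.normal(w_mean, w_sd)), 3),
                "wing_chord": round(float(rng.normal(wc_mean, wc_sd)), 3),
                "sex_rho3": lit,
                "sex_rho2": lit,
                "sex_rho1": lit,
                "sex_truth": female,
            }
        )
    for index, age, weight, wc, rho3_lit, truth in _PRINTED_ROWS:
        m = parse_measure(rho3_lit)
        partial = not m.is_point_mass
        truth_lit = serialize_measure(make_point_mass(truth))
        rows.append(
            {
                "index": index,
                "age": age,
                "weight": weight,
                "wing_chord": wc,
                "sex_rho3": rho3_lit if partial else truth_lit,
                "sex_rho2": None if partial else truth_lit,
                "sex_rho1": truth_lit,
                "sex_truth": truth,
            }
        )
    return BirdDataset(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# rating scale


def generate_ratings(
    n_patients: int,
    n_items: int = 17,
    category_scores: Sequence[int] = (0, 1, 2, 3, 4),
    concentration: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-item categorical confidence measures for a rating scale.

    Each patient carries a latent severity in (0, 1); per item a modal
    category is drawn Binomial(n_categories - 1, severity) and the assessor's
    confidence vector is Dirichlet-distributed around that mode with the
    given concentration.  Columns ``item<j>_rho2`` hold categorical measure
    literals; ``item<j>_rho1`` the companion point mass at the measure's
    modal category.  ``concentration=inf`` gives exact point masses, the
    classical single-score protocol.
    """
    if n_items < 1 or n_patients < 1:
        raise ValueError("need at least one patient and one item")
    scores = [int(s) for s in category_scores]
    if scores != sorted(set(scores)):
        raise ValueError("category scores must be strictly ascending integers")
    ncat = len(scores)
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_patients + 1):
        severity = float(rng.beta(2.0, 2.0))
        row: Dict[str, object] = {"patient": pid}
        for j in range(1, n_items + 1):
            modal = int(rng.binomial(ncat - 1, severity))
            if np.isinf(concentration):
                probs = np.zeros(ncat)
                probs[modal] = 1.0
            else:
                alpha = np.full(ncat, 0.3)
                alpha[modal] += concentration
                probs = rng.dirichlet(alpha)
            measure = make_categorical(scores, probs)
            row[f"item{j}_rho2"] = serialize_measure(measure)
            row[f"item{j}_rho1"] = str(scores[int(np.argmax(probs))])
        rows.append(row)
    return pd.DataFrame(rows)


def ratings_item_sample(
    ratings: pd.DataFrame, patient: int, protocol: str = "rho2"
) -> ProtocolSample:
    """One patient's items as a sample, for the generalized total score."""
    row = ratings.loc[ratings["patient"] == patient]
    if row.empty:
        raise ValueError(f"no patient {patient!r} in ratings table")
    row = row.iloc[0]
    cols = [c for c in ratings.columns if c.endswith(f"_{protocol}")]
    records = [
        MeasurementRecord(unit_id=c, measure=parse_measure(str(row[c])))
        for c in sorted(cols, key=lambda c: int(c.split("_")[0][4:]))
    ]
    return ProtocolSample(records)


_HAMD_ITEM1 = """patient,rho1,rho2
1,1,"cat:0:0,1:0.5,2:0.5,3:0,4:0"
2,1,"cat:0:0,1:1,2:0,3:0,4:0"
3,2,"cat:0:0,1:0.1,2:0.6,3:0.3,4:0"
4,2,"cat:0:0,1:0.1,2:0.8,3:0.1,4:0"
5,1,"cat:0:0,1:0.7,2:0.3,3:0,4:0"
6,3,"cat:0:0,1:0,2:0,3:0.8,4:0.2"
7,2,"cat:0:0,1:0.1,2:0.9,3:0,4:0"
8,1,"cat:0:0,1:0.6,2:0.4,3:0,4:0"
"""


def hamd_item1_fixture() -> pd.DataFrame:
    """The published item-1 confidences for 8 patients under both protocols."""
    return pd.read_csv(io.StringIO(_HAMD_ITEM1), dtype={"patient": int, "rho1": str, "rho2": str})
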