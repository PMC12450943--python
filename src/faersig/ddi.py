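"""Drug-drug interaction screening with the Omega shrinkage measure.

For a drug pair and an adverse event, let N11 be the number of reports
carrying both drugs and the event, N1. the number carrying both drugs,
N.1 the number carrying the event, and N the total report count. Under
independence of "takes the pair" and "has the event" the expected
co-report count is

    E11 = N1. * N.1 / N

and the shrinkage-stabilized disproportionality measure is

    Omega = log2((N11 + alpha) / (E11 + alpha)),  alpha = 0.5 by default.

The additive constant pulls sparse-count estimates toward zero, damping
the random fluctuation that makes raw ratios unreliable for rare
events. The 95% CI is Omega +/- 1.96 * SE with SE = 1/(ln 2 * sqrt(N11))
— the Poisson delta-method error of a base-2 log count. A pair-event
combination is a significant interaction signal when the CI lower bound
exceeds zero. No minimum N11 is imposed; counts are always reported so
sparse findings can be read as exploratory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import CaseData, normalize_drug_name, select_target_reports

DEFAULT_ALPHA = 0.5
Z95 = 1.96


@dataclass(frozen=True)
class PairEventCounts:
    drug_a: str
    drug_b: str
    event_pt: str
    n11: int
    n1dot: int
    ndot1: int
    n_total: int

    def __post_init__(self):
        if not (0 <= self.n11 <= min(self.n1dot, self.ndot1)):
            raise ValueError("n11 must satisfy 0 <= n11 <= min(n1dot, ndot1)")
        if self.n_total < max(self.n1dot, self.ndot1):
            raise ValueError("n_total must dominate both margins")


@dataclass
class DDIResult:
    counts: PairEventCounts
    e11: float
    alpha_shrink: float
    omega: float
    omega_lo: float
    omega_hi: float

    @property
    def significant(self) -> bool:
        return not math.isnan(self.omega_lo) and self.omega_lo > 0

    def to_dict(self) -> dict:
        return {
            "drug_a": self.counts.drug_a,
            "drug_b": self.counts.drug_b,
            "event_pt": self.counts.event_pt,
            "n11": self.counts.n11,
            "e11": self.e11,
            "omega": self.omega,
            "omega_lo": self.omega_lo,
            "omega_hi": self.omega_hi,
            "significant": self.significant,
        }


def omega_interval(omega: float, n11: int, z: float = Z95) -> tuple[float, float]:
    """95% CI around a given Omega with SE = 1/(ln 2 * sqrt(N11)).

    Exposed separately because the interval depends only on the point
    estimate and the co-report count. Undefined (NaN bounds) for N11 = 0.
    """
    if n11 <= 0:
        return float("nan"), float("nan")
    se = 1.0 / (math.log(2) * math.sqrt(n11))
    return omega - z * se, omega + z * se


def omega_statistic(counts: PairEventCounts, alpha_shrink: float = DEFAULT_ALPHA) -> DDIResult:
    """Omega, its CI and the significance flag for one pair-event combination."""
    if counts.n_total <= 0:
        raise ValueError("n_total must be positive")
    if alpha_shrink <= 0:
        raise ValueError("shrinkage constant must be positive")
    e11 = counts.n1dot * counts.ndot1 / counts.n_total
    omega = math.log2((counts.n11 + alpha_shrink) / (e11 + alpha_shrink))
    lo, hi = omega_interval(omega, counts.n11)
    return DDIResult(counts, e11, alpha_shrink, omega, lo, hi)


def pair_counts(
    data: CaseData,
    drug_a: str,
    drug_b: str,
    event_pt: str,
    role_filter_a: Iterable[str] = ("PS",),
) -> PairEventCounts:
    """Report-level counts for one (drug pair, event) combination.

    The target drug must appear in one of ``role_filter_a``'s roles; the
    co-drug is matched in any role (concomitant entries included), which
    maximizes co-report capture.
    """
    a_ids = set(select_target_reports(data, drug_a, role_filter_a))
    b_norm = normalize_drug_name(drug_b)
    b_ids = set(data.drugs.loc[data.drugs["drug_name_norm"].eq(b_norm), "caseid"])
    pair_ids = a_ids & b_ids
    event_ids = set(data.reac.loc[data.reac["pt"].eq(event_pt), "caseid"])
    return PairEventCounts(
        drug_a=normalize_drug_name(drug_a),
        drug_b=b_norm,
        event_pt=event_pt,
        n11=len(pair_ids & event_ids),
        n1dot=len(pair_ids),
        ndot1=len(event_ids),
        n_total=data.n_cases,
    )


def detect_ddi(
    data: CaseData,
    drug_a: str,
    co_drugs: Sequence[str],
    top_k_events: int = 10,
    alpha_shrink: float = DEFAULT_ALPHA,
    role_filter_a: Iterable[str] = ("PS",),
) -> pd.DataFrame:
    """Screen each co-drug's most frequent co-reported events for interaction.

    For every co-drug, the ``top_k_events`` most frequent PTs among the
    pair's co-reports (ties broken alphabetically) are evaluated with
    the Omega statistic. Pairs with zero co-reports yield no rows. All
    results carry N11 so small-count findings read as exploratory.
    """
    a_ids = set(select_target_reports(data, drug_a, role_filter_a))
    rows: list[dict] = []
    for co in co_drugs:
        b_norm = normalize_drug_name(co)
        b_ids = set(data.drugs.loc[data.drugs["drug_name_norm"].eq(b_norm), "caseid"])
        pair_ids = a_ids & b_ids
        if not pair_ids:
            continue
        co_reac = data.reac[data.reac["caseid"].isin(pair_ids)]
        freq = (
            co_reac[["caseid", "pt"]]
            .drop_duplicates()["pt"]
            .value_counts()
            .rename_axis("pt")
            .reset_index(name="n")
            .sort_values(["n", "pt"], ascending=[False, True], kind="mergesort")
        )
        for pt in freq["pt"].head(top_k_events):
            counts = pair_counts(data, drug_a, co, pt, role_filter_a)
            rows.append(omega_statistic(counts, alpha_shrink).to_dict())
    columns = ["drug_a", "drug_b", "event_pt", "n11", "e11", "omega", "omega_lo", "omega_hi", "significant"]
    return pd.DataFrame(rows, columns=columns)
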