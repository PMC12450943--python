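"""Disproportionality statistics on 2x2 drug-event contingency tables.

Spontaneous-report signal detection compares how often an event is
reported with the drug of interest against the database background:

    =============  ===========  ============
                   target event other events
    target drug         a            b
    other drugs         c            d
    =============  ===========  ============

Four statistics are computed per pair, with the conventional positivity
thresholds:

* ROR, reporting odds ratio ``ad/bc``; positive when the 95% CI lower
  bound exceeds 1 and at least 3 cases were reported.
* PRR, proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]``, flagged by
  the MHRA composite rule (PRR >= 2, chi-square >= 4, n >= 3).
* IC, the information component ``log2(a/E)`` with ``E=(a+b)(a+c)/N``
  (BCPNN tradition); positive when IC025 > 0.
* EBGM, the empirical-Bayes geometric mean in its observed/expected form
  ``aN/((a+b)(a+c))`` (MGPS tradition); positive when EBGM05 > 2 and
  n >= 3. By construction ``IC == log2(EBGM)``.

Interval bounds use delta-method standard errors on the log scale. A
pair is called a signal ("positive") when at least one algorithm flags
it; single-method detections are exploratory by convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import CaseData, select_target_reports

logger = logging.getLogger(__name__)

Z95 = 1.96
Z90_ONE_SIDED = 1.645
MIN_CASES = 3


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair in one stratum (report-level)."""

    a: int
    b: int
    c: int
    d: int
    level: str = "PT"
    stratum_label: str = "overall"

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n_total == 0:
            raise ValueError("empty stratum: all four cells are zero")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n_total


@dataclass
class SignalResult:
    """All four statistics plus per-algorithm positivity flags for one pair."""

    event: str
    level: str
    stratum_label: str
    n: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    chi2_uncorrected: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool
    flag_prr_mhra: bool
    flag_bcpnn: bool
    flag_mgps: bool
    zero_corrected: bool = False

    @property
    def positive(self) -> bool:
        return self.flag_ror or self.flag_prr_mhra or self.flag_bcpnn or self.flag_mgps

    def to_dict(self) -> dict:
        d = asdict(self)
        d["positive"] = self.positive
        return d


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Haldane-Anscombe: add 0.5 to every cell when any cell is zero.

    Applied to interval computation only; point estimates stay on raw
    counts whenever defined. Each application is logged.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        logger.info("zero cell in table %s; 0.5 continuity correction applied", t)
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True
    return float(t.a), float(t.b), float(t.c), float(t.d), False


def ror_stat(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with its delta-method 95% CI.

    ror = ad/bc; CI = exp(ln ror -/+ 1.96 * sqrt(1/a+1/b+1/c+1/d)).
    The point estimate uses raw counts when bc > 0, else the corrected
    cells; the interval always uses the corrected cells when any cell
    is zero.
    """
    a, b, c, d, corrected = _corrected_cells(t)
    ror = (t.a * t.d) / (t.b * t.c) if t.b * t.c > 0 else (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    centre = math.log((a * d) / (b * c))
    return ror, math.exp(centre - Z95 * se), math.exp(centre + Z95 * se)


def prr_chi2(t: ContingencyTable) -> tuple[float, float, float, float, float]:
    """PRR with 95% CI plus the Pearson chi-square (Yates and uncorrected).

    prr = [a/(a+b)] / [c/(c+d)];
    CI = exp(ln prr -/+ 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
    Returns (prr, lo, hi, chi2_yates, chi2_uncorrected). With c = 0 the
    PRR is infinite: flagged, no interval.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("PRR undefined: an entire drug row is empty")
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if min(obs.sum(axis=0)) == 0 or min(obs.sum(axis=1)) == 0:
        chi2_yates = chi2_uncorr = 0.0
    else:
        chi2_yates = float(chi2_contingency(obs, correction=True)[0])
        chi2_uncorr = float(chi2_contingency(obs, correction=False)[0])
    if t.c == 0:
        logger.warning("c = 0: PRR infinite, interval not computed")
        return float("inf"), float("nan"), float("nan"), chi2_yates, chi2_uncorr
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d)) if t.a + t.b > 0 else float("nan")
    a, b, c, d, corrected = _corrected_cells(t)
    se2 = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(se2, 0.0))
    centre = math.log((a / (a + b)) / (c / (c + d)))
    return prr, math.exp(centre - Z95 * se), math.exp(centre + Z95 * se), chi2_yates, chi2_uncorr


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """Information component log2(a/E) and its lower bound IC025.

    E = (a+b)(a+c)/N. The standard error of ln(a/E) is approximated by
    the PRR-style delta form and rescaled to the log2 scale.
    """
    if t.a == 0:
        raise ValueError("IC undefined for a = 0")
    e = t.expected_a
    if e == 0:
        raise ValueError("expected count is zero")
    ic = math.log2(t.a / e)
    a, b, c, d, _ = _corrected_cells(t)
    se2 = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(se2, 0.0)) / math.log(2)
    return ic, ic - Z95 * se


def mgps_ebgm(t: ContingencyTable) -> tuple[float, float]:
    """Observed/expected relative reporting ratio with its one-sided 5% bound.

    ebgm = aN/((a+b)(a+c)); ebgm05 = exp(ln ebgm - 1.645*sqrt(1/a+1/b+1/c+1/d)).
    log2(ebgm) equals the information component exactly (shared E).
    """
    if t.a == 0:
        raise ValueError("EBGM undefined for a = 0")
    e = t.expected_a
    if e == 0:
        raise ValueError("expected count is zero")
    ebgm = t.a / e
    a, b, c, d, _ = _corrected_cells(t)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, math.exp(math.log(ebgm) - Z90_ONE_SIDED * se)


def evaluate_signal(t: ContingencyTable, event: str = "") -> SignalResult:
    """Compute all four statistics and the per-algorithm positivity flags.

    Flags: ROR (n>=3 and CI low >1); PRR/MHRA (n>=3, PRR>=2, chi2>=4,
    Yates-corrected); BCPNN (IC025>0); MGPS (n>=3 and EBGM05>2). A pair
    is positive when any flag is set.
    """
    n = t.a
    ror, ror_lo, ror_hi = ror_stat(t)
    prr, prr_lo, prr_hi, chi2_yates, chi2_uncorr = prr_chi2(t)
    if n > 0:
        ic, ic025 = bcpnn_ic(t)
        ebgm, ebgm05 = mgps_ebgm(t)
    else:
        ic = ic025 = ebgm = ebgm05 = float("nan")
    zero_corrected = t.a == 0 or t.b == 0 or t.c == 0 or t.d == 0
    return SignalResult(
        event=event,
        level=t.level,
        stratum_label=t.stratum_label,
        n=n,
        ror=ror,
        ror_lo=ror_lo,
        ror_hi=ror_hi,
        prr=prr,
        prr_lo=prr_lo,
        prr_hi=prr_hi,
        chi2=chi2_yates,
        chi2_uncorrected=chi2_uncorr,
        ic=ic,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
        flag_ror=bool(n >= MIN_CASES and not math.isnan(ror_lo) and ror_lo > 1),
        flag_prr_mhra=bool(n >= MIN_CASES and prr >= 2 and chi2_yates >= 4),
        flag_bcpnn=bool(n > 0 and ic025 > 0),
        flag_mgps=bool(n >= MIN_CASES and ebgm05 > 2),
        zero_corrected=zero_corrected,
    )


# ---------------------------------------------------------------------------
# case-level table construction


def build_contingency(
    data: CaseData,
    drug: str,
    event: str,
    level: str = "PT",
    role_filter: Iterable[str] = ("PS",),
    stratum_caseids: Iterable[str] | None = None,
    stratum_label: str = "overall",
    annotated_reac: pd.DataFrame | None = None,
) -> ContingencyTable:
    """Build the 2x2 table for one drug-event pair.

    Counting is report-level: a report lands in cell ``a`` (or ``c``)
    when at least one of its reactions matches the event, however many
    times the event is listed. With ``level='SOC'`` the event is a
    system organ class name and ``annotated_reac`` (from
    :func:`faersig.io.map_pt_to_soc`) must be supplied. When a stratum
    is given, all four cells are computed from that stratum's reports
    only.
    """
    all_ids = set(data.caseids)
    if stratum_caseids is not None:
        all_ids &= set(stratum_caseids)
    if not all_ids:
        raise ValueError(f"empty stratum {stratum_label!r}")
    target_ids = set(select_target_reports(data, drug, role_filter)) & all_ids
    if level == "SOC":
        reac = annotated_reac if annotated_reac is not None else data.reac
        if "soc_name" not in reac.columns:
            raise ValueError("SOC-level tables need SOC-annotated reactions")
        event_ids = set(reac.loc[reac["soc_name"].eq(event), "caseid"]) & all_ids
    else:
        event_ids = set(data.reac.loc[data.reac["pt"].eq(event), "caseid"]) & all_ids
    a = len(target_ids & event_ids)
    b = len(target_ids - event_ids)
    c = len(event_ids - target_ids)
    d = len(all_ids) - a - b - c
    return ContingencyTable(a, b, c, d, level=level, stratum_label=stratum_label)


def signal_table(
    data: CaseData,
    drug: str,
    level: str = "PT",
    role_filter: Iterable[str] = ("PS",),
    stratum_caseids: Iterable[str] | None = None,
    stratum_label: str = "overall",
    annotated_reac: pd.DataFrame | None = None,
    min_events: int = 1,
) -> pd.DataFrame:
    """Evaluate every event observed among target-drug reports.

    Vectorized across events (one pass over the reaction frame); returns
    one row per event with all statistics and flags, or an empty frame
    with full headers when the stratum holds no target reports.
    """
    all_ids = set(data.caseids)
    if stratum_caseids is not None:
        all_ids &= set(stratum_caseids)
    columns = list(SignalResult.__dataclass_fields__) + ["positive"]
    if not all_ids:
        logger.warning("stratum %r contains no reports", stratum_label)
        return pd.DataFrame(columns=columns)
    target_ids = set(select_target_reports(data, drug, role_filter)) & all_ids
    if not target_ids:
        logger.warning("stratum %r contains no target-drug reports", stratum_label)
        return pd.DataFrame(columns=columns)

    if level == "SOC":
        reac = annotated_reac if annotated_reac is not None else data.reac
        if "soc_name" not in reac.columns:
            raise ValueError("SOC-level tables need SOC-annotated reactions")
        reac = reac[reac["soc_name"].ne("")]
        key = "soc_name"
    else:
        reac, key = data.reac, "pt"
    reac = reac[reac["caseid"].isin(all_ids)]
    # report-level: one (caseid, event) contribution regardless of repeats
    pairs = reac[["caseid", key]].drop_duplicates()
    in_target = pairs["caseid"].isin(target_ids)
    a_counts = pairs.loc[in_target, key].value_counts()
    c_counts = pairs.loc[~in_target, key].value_counts()
    n_target, n_all = len(target_ids), len(all_ids)

    rows = []
    for event in sorted(a_counts.index[a_counts >= min_events]):
        a = int(a_counts[event])
        c = int(c_counts.get(event, 0))
        t = ContingencyTable(
            a, n_target - a, c, n_all - n_target - c, level=level, stratum_label=stratum_label
        )
        rows.append(evaluate_signal(t, event=event).to_dict())
    return pd.DataFrame(rows, columns=columns)


def rank_signals(
    results: Sequence[SignalResult] | pd.DataFrame,
    by: str = "frequency",
    k: int | None = None,
) -> pd.DataFrame:
    """Order signal results descending by frequency (n) or ROR.

    The sort is stable with ties broken by event name (ascending), so
    repeated runs produce identical tables. ``k`` truncates to the top k.
    """
    if by not in ("frequency", "ror"):
        raise ValueError("rank key must be 'frequency' or 'ror'")
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame([r.to_dict() for r in results])
    if df.empty:
        return df
    key = "n" if by == "frequency" else "ror"
    df = df.sort_values(["event"], kind="mergesort")
    df = df.sort_values([key], ascending=False, kind="mergesort").reset_index(drop=True)
    return df.head(k) if k is not None else df
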