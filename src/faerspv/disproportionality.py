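"""Drug–event disproportionality statistics on 2×2 contingency tables.

For a (drug, event) pair screened against the whole-database background the
four-grid table is

    a = reports of the drug containing the event PT
    b = reports of the drug without it
    c = other reports containing it
    d = other reports without it,        n = a + b + c + d

with the report as the counting unit (a PT counts once per report). Four
estimators are computed:

* ROR  = (a·d)/(b·c), 95% CI exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))
* PRR  = [a/(a+b)] / [c/(c+d)],
  95% CI exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))
* MHRA χ² with Yates continuity correction,
  χ² = n·(|ad − bc| − n/2)² / [(a+b)(c+d)(a+c)(b+d)], clamped to 0 when
  |ad − bc| ≤ n/2 (the correction can only shrink the statistic)
* BCPNN information component (Bate's closed-form Bayesian estimate), which
  stays defined for zero cells and is therefore used alone for pairs with
  fewer than three reports.

A pair is declared a signal only when all frequentist criteria hold at
once: a ≥ 3, ROR and PRR 95% lower bounds > 1, PRR ≥ 2 and χ² ≥ 4. Signal
intensity is graded from the IC 2.5% credibility bound (weak ≤ 1.5 <
moderate ≤ 3 < strong) — a package convention, documented in the methods
note. No multiple-testing adjustment is applied; disproportionality screens
conventionally report unadjusted signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

Z95 = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = math.log(2.0)


class EmptyMarginError(ValueError):
    """The requested product has no reports in the dataset."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class BcpnnParams:
    """Hyperparameters of the closed-form BCPNN information component."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


@dataclass
class SignalMetrics:
    table: ContingencyTable
    ror: float = math.nan
    ror_lo95: float = math.nan
    ror_hi95: float = math.nan
    prr: float = math.nan
    prr_lo95: float = math.nan
    prr_hi95: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic_var: float = math.nan
    ic025: float = math.nan
    flags: Dict[str, bool] = field(default_factory=dict)
    combined_signal: bool = False
    intensity: str = "none"  # none / weak / moderate / strong
    reason: str = ""


def ror_with_ci(t: ContingencyTable, z: float = Z95) -> Tuple[float, float, float]:
    """Reporting odds ratio with log-normal CI; NaNs for any zero cell.

    No continuity correction is added: pairs this rare are screened by the
    a-count threshold (and by BCPNN), not by a patched odds ratio.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def prr_with_ci(t: ContingencyTable, z: float = Z95) -> Tuple[float, float, float]:
    """Proportional reporting ratio with log-normal CI; NaNs if a or c is 0."""
    if t.a == 0 or t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return (math.nan, math.nan, math.nan)
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se_sq = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    se = math.sqrt(max(se_sq, 0.0))
    return (prr, prr * math.exp(-z * se), prr * math.exp(z * se))


def chi2_yates(t: ContingencyTable, yates: bool = True) -> float:
    """2×2 chi-square; Yates-corrected by default, NaN on a zero margin."""
    r1, r0 = t.a + t.b, t.c + t.d
    c1, c0 = t.a + t.c, t.b + t.d
    if min(r1, r0, c1, c0) == 0:
        return math.nan
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - t.n / 2.0, 0.0)
    return t.n * diff * diff / (r1 * r0 * c1 * c0)


def bcpnn_ic(
    t: ContingencyTable, params: Optional[BcpnnParams] = None
) -> Tuple[float, float, float]:
    """Closed-form BCPNN information component (ic, ic_var, ic025).

    Defined for zero cells by construction, which is exactly why it serves
    as the sole detector for pairs with a < 3.
    """
    p = params or BcpnnParams()
    a, n = float(t.a), float(t.n)
    row = t.a + t.b  # drug margin
    col = t.a + t.c  # event margin
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((row + p.alpha1) * (col + p.beta1))
    ic = math.log2(
        (a + p.gamma11)
        * (n + p.alpha)
        * (n + p.beta)
        / ((n + gamma) * (row + p.alpha1) * (col + p.beta1))
    )
    var = (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - row + p.alpha - p.alpha1) / ((row + p.alpha1) * (1 + n + p.alpha))
        + (n - col + p.beta - p.beta1) / ((col + p.beta1) * (1 + n + p.beta))
    ) / (_LN2 * _LN2)
    return (ic, var, ic - 2.0 * math.sqrt(var))


def grade_intensity(ic025: float) -> str:
    """Signal-intensity grade from the IC 2.5% bound (package convention)."""
    if math.isnan(ic025):
        return "none"
    if ic025 > 3.0:
        return "strong"
    if ic025 > 1.5:
        return "moderate"
    return "weak"


def combined_signal(m: SignalMetrics, min_a: int = 3) -> Tuple[bool, str, str]:
    """Evaluate the combined threshold; returns (signal, intensity, reason).

    signal ⇔ a ≥ min_a AND ROR lo95 > 1 AND PRR lo95 > 1 AND PRR ≥ 2
    AND χ² ≥ 4. Undefined metrics (zero cells) fail closed with an
    'insufficient data' reason.
    """
    t = m.table
    if t.a < min_a:
        return (False, "none", f"a < {min_a}")
    vals = (m.ror_lo95, m.prr, m.prr_lo95, m.chi2)
    if any(math.isnan(v) for v in vals):
        return (False, "none", "insufficient data")
    ok = m.ror_lo95 > 1.0 and m.prr_lo95 > 1.0 and m.prr >= 2.0 and m.chi2 >= 4.0
    if not ok:
        return (False, "none", "below threshold")
    return (True, grade_intensity(m.ic025), "")


def compute_metrics(
    t: ContingencyTable,
    min_a: int = 3,
    yates: bool = True,
    bcpnn_params: Optional[BcpnnParams] = None,
) -> SignalMetrics:
    """All four estimators plus per-algorithm and combined flags."""
    m = SignalMetrics(table=t)
    m.ror, m.ror_lo95, m.ror_hi95 = ror_with_ci(t)
    m.prr, m.prr_lo95, m.prr_hi95 = prr_with_ci(t)
    m.chi2 = chi2_yates(t, yates=yates)
    m.ic, m.ic_var, m.ic025 = bcpnn_ic(t, bcpnn_params)
    m.flags = {
        "ror": t.a >= min_a and not math.isnan(m.ror_lo95) and m.ror_lo95 > 1.0,
        "prr": t.a >= min_a and not math.isnan(m.prr_lo95) and m.prr_lo95 > 1.0,
        "mhra": t.a >= min_a
        and not math.isnan(m.prr)
        and not math.isnan(m.chi2)
        and m.prr >= 2.0
        and m.chi2 >= 4.0,
        "bcpnn": m.ic025 > 0.0,
    }
    m.combined_signal, m.intensity, m.reason = combined_signal(m, min_a=min_a)
    return m


class ReportSet:
    """Report-level view of a dataset for contingency-table construction.

    Built from (report_id, product_id-or-None, PT collection) triples; PTs
    are de-duplicated within a report so the report is the counting unit.
    """

    def __init__(self, reports: Iterable[Tuple[Hashable, Optional[str], Iterable[str]]]):
        self.n_reports = 0
        self._product_totals: Dict[str, int] = {}
        self._pt_totals: Dict[str, int] = {}
        self._pair_counts: Dict[Tuple[str, str], int] = {}
        for _rid, product, pts in reports:
            self.n_reports += 1
            unique: Set[str] = set(pts)
            if product is not None:
                self._product_totals[product] = self._product_totals.get(product, 0) + 1
            for pt in unique:
                self._pt_totals[pt] = self._pt_totals.get(pt, 0) + 1
                if product is not None:
                    key = (product, pt)
                    self._pair_counts[key] = self._pair_counts.get(key, 0) + 1

    @classmethod
    def from_bundles(cls, matched_bundles) -> "ReportSet":
        """From (CaseBundle, product_id-or-None) pairs."""
        return cls(
            (b.primaryid, pid, b.unique_pts()) for b, pid in matched_bundles
        )

    def products(self) -> List[str]:
        return sorted(self._product_totals)

    def pts(self) -> List[str]:
        return sorted(self._pt_totals)

    def product_total(self, product: str) -> int:
        return self._product_totals.get(product, 0)

    def pt_total(self, pt: str) -> int:
        return self._pt_totals.get(pt, 0)

    def pair_count(self, product: str, pt: str) -> int:
        return self._pair_counts.get((product, pt), 0)


def build_table(product_id: str, pt: str, reports: ReportSet) -> ContingencyTable:
    """Four-grid table for one (product, PT) pair against everything else."""
    n_prod = reports.product_total(product_id)
    if n_prod == 0:
        raise EmptyMarginError(f"product {product_id!r} has no reports")
    a = reports.pair_count(product_id, pt)
    b = n_prod - a
    c = reports.pt_total(pt) - a
    d = reports.n_reports - n_prod - c
    return ContingencyTable(a, b, c, d)


_SCREEN_COLUMNS = [
    "product_id", "pt", "a", "b", "c", "d",
    "ror", "ror_lo95", "ror_hi95", "prr", "prr_lo95", "prr_hi95",
    "chi2", "ic", "ic_var", "ic025",
    "flag_ror", "flag_prr", "flag_mhra", "flag_bcpnn",
    "combined_signal", "intensity", "reason",
]


def _metrics_row(product: str, pt: str, m: SignalMetrics) -> Dict[str, object]:
    t = m.table
    return {
        "product_id": product, "pt": pt,
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
        "ror": m.ror, "ror_lo95": m.ror_lo95, "ror_hi95": m.ror_hi95,
        "prr": m.prr, "prr_lo95": m.prr_lo95, "prr_hi95": m.prr_hi95,
        "chi2": m.chi2, "ic": m.ic, "ic_var": m.ic_var, "ic025": m.ic025,
        "flag_ror": m.flags["ror"], "flag_prr": m.flags["prr"],
        "flag_mhra": m.flags["mhra"], "flag_bcpnn": m.flags["bcpnn"],
        "combined_signal": m.combined_signal, "intensity": m.intensity,
        "reason": m.reason,
    }


def screen(
    reports: ReportSet,
    products: Sequence[str],
    pts: Sequence[str],
    min_a: int = 3,
    yates: bool = True,
    bcpnn_params: Optional[BcpnnParams] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every (product, PT) pair; returns (main, low-count) tables.

    The main table holds pairs with a ≥ min_a, fully evaluated with all
    four algorithms and the combined threshold. Pairs observed at least
    once but below min_a go to the low-count companion table, evaluated
    with BCPNN only (its flag is ic025 > 0).
    """
    main_rows, low_rows = [], []
    for product in products:
        if reports.product_total(product) == 0:
            continue
        for pt in pts:
            t = build_table(product, pt, reports)
            if t.a >= min_a:
                m = compute_metrics(t, min_a=min_a, yates=yates, bcpnn_params=bcpnn_params)
                main_rows.append(_metrics_row(product, pt, m))
            elif t.a >= 1:
                ic, ic_var, ic025 = bcpnn_ic(t, bcpnn_params)
                low_rows.append(
                    {
                        "product_id": product, "pt": pt,
                        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                        "ic": ic, "ic_var": ic_var, "ic025": ic025,
                        "flag_bcpnn": ic025 > 0.0,
                    }
                )
    main = pd.DataFrame(main_rows, columns=_SCREEN_COLUMNS)
    low = pd.DataFrame(
        low_rows,
        columns=["product_id", "pt", "a", "b", "c", "d", "ic", "ic_var", "ic025", "flag_bcpnn"],
    )
    return main, low


def heatmap_matrix(screen_df: pd.DataFrame, value: str = "prr") -> Dict[str, Dict[str, float]]:
    """Products × PTs matrix of one metric (JSON-serialisable nested dict)."""
    out: Dict[str, Dict[str, float]] = {}
    for rec in screen_df.to_dict("records"):
        v = rec[value]
        if isinstance(v, float) and math.isnan(v):
            continue
        out.setdefault(rec["product_id"], {})[rec["pt"]] = float(v)
    return out


def intensity_matrix(screen_df: pd.DataFrame) -> Dict[str, Dict[str, Dict[str, object]]]:
    """Per-(product, PT) four-algorithm flags and combined intensity grade."""
    out: Dict[str, Dict[str, Dict[str, object]]] = {}
    for rec in screen_df.to_dict("records"):
        out.setdefault(rec["product_id"], {})[rec["pt"]] = {
            "ror": bool(rec["flag_ror"]),
            "prr": bool(rec["flag_prr"]),
            "mhra": bool(rec["flag_mhra"]),
            "bcpnn": bool(rec["flag_bcpnn"]),
            "combined": bool(rec["combined_signal"]),
            "intensity": rec["intensity"],
        }
    return out
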