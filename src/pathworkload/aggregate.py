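"""Result surfaces: yearly totals, stratum medians, normalized trends and
the pure-practice fee/workload comparison.

The yearly table mirrors the study-style summary (total L4E, W2Q, fees,
blocks, report lines, IHCs, special stains, FTEs, cases per year); trend
series are normalised to a reference year; stratified medians feed the
hypothetical "pure practice" comparison, which converts a yearly workload
target into fees (or L4E units) for a practice consisting of a single case
type, using only that stratum's median fee/L4E/W2Q per case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import NormalizationError
from .workforce import PathologistYearActivity, total_fte

logger = logging.getLogger(__name__)

#: Default yearly workload target per pathologist, in L4E units.
DEFAULT_L4E_TARGET = 7560.0
#: Default yearly workload target per pathologist, in W2Q units.
DEFAULT_W2Q_TARGET = 7500.0

YEARLY_COLUMNS = [
    "year", "l4e_total", "w2q_total", "sob_fees_total", "blocks_total",
    "dx_lines_total", "micro_lines_total", "ccs_lines_total",
    "report_lines_total", "ihc_total", "special_stain_total",
    "fte_total", "case_total",
]


@dataclass(frozen=True)
class StratumSummary:
    """Per-stratum medians (L4E units, W2Q units, fee in CAD)."""

    stratum: str
    median_l4e: float
    median_w2q: float
    median_fee: float


@dataclass(frozen=True)
class StratumPractice:
    """Derived yearly values for a hypothetical single-stratum practice."""

    stratum: str
    #: Fee total (cents) when working to the L4E target.
    fees_at_l4e_target_cents: int
    #: Fee total (cents) when working to the W2Q target.
    fees_at_w2q_target_cents: int
    #: L4E units delivered when working to the W2Q target.
    l4e_equiv_of_w2q_target: float

    @property
    def fees_at_l4e_target(self) -> float:
        return self.fees_at_l4e_target_cents / 100.0

    @property
    def fees_at_w2q_target(self) -> float:
        return self.fees_at_w2q_target_cents / 100.0


@dataclass(frozen=True)
class PracticeComparison:
    l4e_target: float
    w2q_target: float
    per_stratum: dict[str, StratumPractice]

    def pairwise(self, a: str, b: str) -> dict[str, float]:
        """Differences and ratios between two pure practices (a minus b,
        a over b)."""
        pa, pb = self.per_stratum[a], self.per_stratum[b]
        return {
            "fee_diff_at_l4e_target": (
                pa.fees_at_l4e_target_cents - pb.fees_at_l4e_target_cents
            ) / 100.0,
            "fee_diff_at_w2q_target": (
                pa.fees_at_w2q_target_cents - pb.fees_at_w2q_target_cents
            ) / 100.0,
            "fee_ratio_at_w2q_target": (
                pa.fees_at_w2q_target_cents / pb.fees_at_w2q_target_cents
            ),
            "l4e_equiv_ratio": (
                pa.l4e_equiv_of_w2q_target / pb.l4e_equiv_of_w2q_target
            ),
        }


def aggregate_yearly(
    records: pd.DataFrame,
    activities: list[PathologistYearActivity] | None = None,
) -> pd.DataFrame:
    """One row of totals per calendar year from the scored-record table.

    Totals are plain sums over cases (permutation invariant); the FTE
    column sums the per-pathologist activities for each year (0 when no
    activities are supplied).
    """
    rows = []
    for year, grp in records.groupby("year", sort=True):
        fte = total_fte(activities, int(year)) if activities else 0.0
        dx = int(grp["dx_lines"].sum())
        micro = int(grp["micro_lines"].sum())
        ccs = int(grp["ccs_lines"].sum())
        rows.append({
            "year": int(year),
            "l4e_total": float(grp["l4e"].sum()),
            "w2q_total": float(grp["w2q"].sum()),
            "sob_fees_total": int(grp["fee_cents"].sum()) / 100.0,
            "blocks_total": int(grp["blocks"].sum()),
            "dx_lines_total": dx,
            "micro_lines_total": micro,
            "ccs_lines_total": ccs,
            "report_lines_total": dx + micro + ccs,
            "ihc_total": int(grp["ihc"].sum()),
            "special_stain_total": int(grp["special_stains"].sum()),
            "fte_total": fte,
            "case_total": int(len(grp)),
        })
    return pd.DataFrame(rows, columns=YEARLY_COLUMNS)


def normalize_series(table: pd.DataFrame, ref_year: int) -> pd.DataFrame:
    """Divide every metric column by its value in ``ref_year`` (the
    reference row becomes all 1.0).

    Raises :class:`NormalizationError` when a metric is zero in the
    reference year, and ``ValueError`` when the reference year is absent.
    """
    if ref_year not in set(table["year"]):
        raise ValueError(f"reference year {ref_year} not present in table")
    ref = table.loc[table["year"] == ref_year].iloc[0]
    out = table.copy()
    for col in table.columns:
        if col == "year":
            continue
        denom = ref[col]
        if denom == 0:
            raise NormalizationError(
                f"metric {col!r} is zero in reference year {ref_year}"
            )
        out[col] = table[col] / denom
    return out


def percent_change(v_start: float, v_end: float) -> int:
    """Signed integer percent change, rounded half away from zero."""
    if v_start <= 0:
        raise ValueError(f"start value must be positive, got {v_start}")
    pct = 100.0 * (v_end - v_start) / v_start
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def stratum_medians(records: pd.DataFrame) -> list[StratumSummary]:
    """Per-stratum medians of final L4E, final W2Q and fee (CAD).

    Empty strata are omitted with a logged warning.
    """
    out: list[StratumSummary] = []
    for stratum, grp in records.groupby("stratum", sort=True):
        if grp.empty:  # pragma: no cover - groupby never yields empty groups
            logger.warning("stratum %s has no cases; omitted", stratum)
            continue
        out.append(StratumSummary(
            stratum=str(stratum),
            median_l4e=float(grp["l4e"].median()),
            median_w2q=float(grp["w2q"].median()),
            median_fee=float(grp["fee"].median()),
        ))
    return out


def pure_practice_comparison(
    summaries: list[StratumSummary],
    l4e_target: float = DEFAULT_L4E_TARGET,
    w2q_target: float = DEFAULT_W2Q_TARGET,
) -> PracticeComparison:
    """Convert workload targets into yearly fee totals per pure practice.

    For each stratum with medians (fee f, l4e u, w2q w) per case:

    * fees at the L4E target = ``l4e_target × f / u``
    * fees at the W2Q target = ``w2q_target × f / w``
    * L4E delivered at the W2Q target = ``w2q_target × u / w``

    Fee results are rounded to cents.  Raises ``ValueError`` on a zero
    median divisor.
    """
    per: dict[str, StratumPractice] = {}
    for s in summaries:
        if s.median_l4e <= 0 or s.median_w2q <= 0:
            raise ValueError(
                f"stratum {s.stratum}: zero median workload divisor"
            )
        fee_cents = round(s.median_fee * 100)
        per[s.stratum] = StratumPractice(
            stratum=s.stratum,
            fees_at_l4e_target_cents=round(l4e_target * fee_cents / s.median_l4e),
            fees_at_w2q_target_cents=round(w2q_target * fee_cents / s.median_w2q),
            l4e_equiv_of_w2q_target=w2q_target * s.median_l4e / s.median_w2q,
        )
    return PracticeComparison(
        l4e_target=l4e_target, w2q_target=w2q_target, per_stratum=per
    )


def fee_per_unit_trend(table: pd.DataFrame) -> pd.Series:
    """CAD per L4E unit per year (total fees / total L4E).

    Raises ``ValueError`` when a year has zero L4E total.
    """
    if (table["l4e_total"] <= 0).any():
        bad = table.loc[table["l4e_total"] <= 0, "year"].tolist()
        raise ValueError(f"zero L4E total in year(s) {bad}")
    s = table["sob_fees_total"] / table["l4e_total"]
    s.index = table["year"]
    return s.rename("fee_per_l4e")


def fee_per_l4e_by_stratum(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year, per-stratum CAD per L4E unit from the scored records."""
    g = records.groupby(["year", "stratum"])
    out = (g["fee"].sum() / g["l4e"].sum()).rename("fee_per_l4e")
    return out.reset_index()
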