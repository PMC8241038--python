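"""Work2Quality (W2Q) scoring and Ontario Schedule-of-Benefits fees.

Both computations read the coded procedure events of the parsed report and
count **all** billable code occurrences (every container's tier code, plus
the cytology code on cell-block cases) — unlike stratification, which keeps
only the highest code.

W2Q adds adjustments for internal (informal) and external (formal)
consults, special stains, IHC, molecular testing, synoptic reports and
frozen sections; it has no teaching adjustment.  The fee total prices the
same code occurrences under the March-2020 Ontario Schedule of Benefits;
consults contribute nothing to fees.  Per-case caps: 50 W2Q units and
$1,500.  Currency arithmetic is exact, in integer cents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import BILLABLE_CODES, ScoringConfig
from .errors import ScoringError
from .report_parser import PathologyReport, count_ihc


@dataclass(frozen=True)
class W2QScore:
    """Per-case W2Q decomposition."""

    base: float
    adjustments: float
    final: float
    capped: bool = False


@dataclass(frozen=True)
class FeeTotal:
    """Per-case Schedule-of-Benefits fee decomposition (integer cents)."""

    per_code_fees: list[tuple[str, int, int]] = field(default_factory=list)
    total_cents: int = 0
    capped: bool = False

    @property
    def total(self) -> float:
        """Total in dollars."""
        return self.total_cents / 100.0


def score_w2q(report: PathologyReport, config: ScoringConfig) -> W2QScore:
    """Score one parsed report under W2Q.

    ``final = min(cap, base + adjustments)``; the teaching flag never
    enters.  Raises :class:`ScoringError` for an unweighted tier code.
    """
    w = config.w2q
    base = 0.0
    for code, count in report.procedure_events:
        if code in BILLABLE_CODES:
            if code not in w.base:
                raise ScoringError(f"no W2Q weight configured for code {code}")
            base += w.base[code] * count

    informal_docs = _informal_doctor_count(report)
    adjustments = (
        w.ihc * count_ihc(report, config.caps.ihc_max)
        + w.special_stain * report.event_count("SS")
        + w.molecular * report.event_count("MOL")
        + w.frozen_section * report.event_count("FS")
        + (w.synoptic if report.has_section("CANCER CARE SUMMARY") else 0.0)
        + (w.internal_consult if informal_docs > 0 else 0.0)
        + (w.external_consult if report.has_section("CONSULTATION") else 0.0)
    )
    value = base + adjustments
    capped = value > config.caps.w2q_max
    return W2QScore(
        base=base,
        adjustments=adjustments,
        final=min(value, config.caps.w2q_max),
        capped=capped,
    )


def _informal_doctor_count(report: PathologyReport) -> int:
    from .l4e_scoring import count_unique_doctors

    return count_unique_doctors(
        report.section_text("DIAGNOSIS"), report.section_text("MICROSCOPIC")
    )


def compute_sobf(report: PathologyReport, config: ScoringConfig) -> FeeTotal:
    """Schedule-of-Benefits fee total for one case.

    Every billable code occurrence is priced (all tier codes, not just the
    highest; cytology codes too).  Consult sections contribute nothing.
    The total is capped at the configured per-case maximum ($1,500).
    Raises :class:`ScoringError` when a billable code is missing from the
    fee schedule.
    """
    fees = config.sob_fees_cents
    per_code: list[tuple[str, int, int]] = []
    total = 0
    for code, count in report.procedure_events:
        if code not in BILLABLE_CODES:
            continue
        if code not in fees:
            raise ScoringError(f"code {code} missing from the fee schedule")
        fee = fees[code]
        per_code.append((code, count, fee))
        total += count * fee
    capped = total > config.caps.fee_max_cents
    return FeeTotal(
        per_code_fees=per_code,
        total_cents=min(total, config.caps.fee_max_cents),
        capped=capped,
    )


def format_cents(cents: int) -> str:
    """Render integer cents as a two-decimal dollar string."""
    sign = "-" if cents < 0 else ""
    cents = abs(cents)
    return f"{sign}{cents // 100}.{cents % 100:02d}"
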