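"""CAP-ACP Level-4-Equivalent (2018 update) per-case workload scoring.

The scoring chain, in order:

1. **Base L4E** from the specimen parts: per-code base points, plus
   per-extra-fragment/per-extra-core increments for biopsy codes and a
   per-block increment for cases carrying an excision code (L865/L866).
   Cytology code events contribute their base points directly.
2. **Micro-only discount** on the base (grossing is performed by pathology
   assistants/residents): 10% off when base exceeds 10 units, else 5%.
3. **Additions**: ancillary testing (IHC via HR codes, special stains,
   molecular tests), frozen sections, synoptic report (3 L4E), and
   informal-consultation points from 'Dr.' mentions (0.5 for one unique
   doctor, 1.0 for two or more).
4. **Multipliers**: x1.5 when the report carries a formal consultation
   section; x1.3 teaching adjustment (resident sign-out) when enabled.
5. **Cap**: the final value is limited to 50 L4E per case (a data-cleaning
   guard against coding errors).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .config import BIOPSY_CODES, CYTOLOGY_CODE, EXCISION_CODES, L86X_CODES, ScoringConfig
from .errors import ScoringError
from .report_parser import PathologyReport, SpecimenPart, count_ihc

#: 'Dr.'/'DR.' followed by a capitalised surname token; unique individuals
#: are identified by lower-cased surname.
_DOCTOR_RE = re.compile(r"\b[Dd][Rr]\.\s+([A-Z][A-Za-z\-']+)")


@dataclass(frozen=True)
class L4EBreakdown:
    """Per-case L4E decomposition with every adjustment step recorded."""

    base: float
    discounted_base: float
    ancillary: float
    informal_consult_points: float
    formal_consult_applied: bool
    teaching_applied: bool
    final: float
    capped: bool = False


def base_l4e(
    parts: list[SpecimenPart],
    report: PathologyReport,
    config: ScoringConfig,
) -> float:
    """Base L4E before any adjustment.

    Sums per-part base points with fragment/core increments (biopsy codes)
    and the per-block increment (excision cases), plus base points for
    cytology code events.  Raises :class:`ScoringError` for a tier code
    absent from the config tables.
    """
    pts = config.l4e
    total = 0.0
    has_excision = False
    for part in parts:
        code = part.l86x_code
        if code is None:
            continue
        if code not in pts.base:
            raise ScoringError(f"no L4E base points configured for code {code}")
        total += pts.base[code]
        if code in BIOPSY_CODES:
            total += pts.per_extra_fragment * max(0, part.fragment_count - 1)
            total += pts.per_extra_core * max(0, part.core_count - 1)
        if code in EXCISION_CODES:
            has_excision = True
    if has_excision:
        total += pts.per_block * report.block_count
    for code, count in report.procedure_events:
        if code == CYTOLOGY_CODE:
            if code not in pts.base:
                raise ScoringError(f"no L4E base points configured for code {code}")
            total += pts.base[code] * count
        elif code in L86X_CODES and not any(p.l86x_code for p in report.parts):
            # Tier codes with no part association (degenerate reports) are
            # still work: score them at base value.
            total += pts.base.get(code, 0.0) * count
    return total


def micro_only_discount(base: float, config: ScoringConfig) -> float:
    """Discount the base L4E for not grossing: ``base * 0.90`` above the
    threshold (10 units), ``base * 0.95`` at or below it."""
    d = config.discount
    rate = d.high_rate if base > d.threshold else d.low_rate
    return base * (1.0 - rate)


def informal_consult_points(
    dx_text: str, micro_text: str, config: ScoringConfig
) -> float:
    """L4E added for informal (intradepartmental) consultations, detected
    as unique 'Dr. <Surname>' mentions in the diagnosis and microscopic
    sections."""
    doctors = {
        m.group(1).lower()
        for m in _DOCTOR_RE.finditer(dx_text)
    } | {
        m.group(1).lower()
        for m in _DOCTOR_RE.finditer(micro_text)
    }
    if not doctors:
        return 0.0
    if len(doctors) == 1:
        return config.informal_consult.one_doctor
    return config.informal_consult.two_or_more


def count_unique_doctors(dx_text: str, micro_text: str) -> int:
    """Number of unique doctors mentioned as 'Dr. X' in dx/micro text."""
    return len({
        m.group(1).lower()
        for m in _DOCTOR_RE.finditer(dx_text + "\n" + micro_text)
    })


def score_l4e(report: PathologyReport, config: ScoringConfig) -> L4EBreakdown:
    """Score one parsed report through the full L4E chain."""
    base = base_l4e(report.parts, report, config)
    discounted = micro_only_discount(base, config)

    pts = config.l4e
    ancillary = (
        pts.ihc * count_ihc(report, config.caps.ihc_max)
        + pts.special_stain * report.event_count("SS")
        + pts.molecular * report.event_count("MOL")
        + pts.frozen_section * report.event_count("FS")
        + (pts.synoptic if report.has_section("CANCER CARE SUMMARY") else 0.0)
    )
    informal = informal_consult_points(
        report.section_text("DIAGNOSIS"),
        report.section_text("MICROSCOPIC"),
        config,
    )

    value = discounted + ancillary + informal
    formal = report.has_section("CONSULTATION")
    if formal:
        value *= config.multipliers.formal_consult
    teaching = config.multipliers.teaching_enabled
    if teaching:
        value *= config.multipliers.teaching

    capped = value > config.caps.l4e_max
    final = min(value, config.caps.l4e_max)
    return L4EBreakdown(
        base=base,
        discounted_base=discounted,
        ancillary=ancillary,
        informal_consult_points=informal,
        formal_consult_applied=formal,
        teaching_applied=teaching,
        final=final,
        capped=capped,
    )
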