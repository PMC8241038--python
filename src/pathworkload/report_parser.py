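"""Parse final-report text into structured records.

The laboratory "final" dialect handled here is line oriented, one UTF-8 file
per case::

    CASE: <id>
    SIGNED: <YYYY-MM-DD> BY <pathologist-id>
    SOURCE OF SPECIMEN:
    A. stomach biopsies x3
    ...
    DIAGNOSIS:
    ...
    PATHOLOGY PROCEDURES:
    L864 x1
    HR x4
    BLK x3

Sections are introduced by fixed uppercase headers.  The ``PATHOLOGY
PROCEDURES`` section holds one line per coded procedure occurrence,
``<CODE> x<count>``; ``BLK`` lines record the paraffin block count.  L86x
tier codes are applied per specimen container (one line per part, in
container order), which lets the parser re-associate codes with the parts
listed under ``SOURCE OF SPECIMEN``.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field

from .config import L86X_CODES
from .errors import ParseError

logger = logging.getLogger(__name__)

#: Dialect section headers, in canonical report order.
SECTION_HEADERS = (
    "SOURCE OF SPECIMEN",
    "GROSS PATHOLOGY",
    "DIAGNOSIS",
    "MICROSCOPIC",
    "CANCER CARE SUMMARY",
    "CONSULTATION",
    "PATHOLOGY PROCEDURES",
)

_CASE_RE = re.compile(r"^CASE:\s*(\S+)\s*$")
_SIGNED_RE = re.compile(r"^SIGNED:\s*(\d{4}-\d{2}-\d{2})\s+BY\s+(\S+)\s*$")
_PROC_RE = re.compile(r"^([A-Z0-9]+)\s+x(\d+)\s*$")

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
}
_COUNT_WORD = r"(\d+|" + "|".join(_NUMBER_WORDS) + r")"
_X_COUNT_RE = re.compile(r"x\s*(\d+)\b", re.IGNORECASE)
_CORE_RE = re.compile(_COUNT_WORD + r"\s+cores?\b", re.IGNORECASE)
_FRAG_RE = re.compile(_COUNT_WORD + r"\s+fragments?\b", re.IGNORECASE)


@dataclass
class SpecimenPart:
    """One specimen container as labelled by the submitting physician."""

    label: str
    l86x_code: str | None = None
    fragment_count: int = 1
    core_count: int = 0


@dataclass
class PathologyReport:
    """A parsed final report."""

    case_id: str
    signout_date: _dt.date
    pathologist_id: str
    sections: dict[str, list[str]] = field(default_factory=dict)
    procedure_events: list[tuple[str, int]] = field(default_factory=list)
    parts: list[SpecimenPart] = field(default_factory=list)
    block_count: int = 0

    def section_lines(self, name: str) -> list[str]:
        return self.sections.get(name, [])

    def section_text(self, name: str) -> str:
        return "\n".join(self.section_lines(name))

    def has_section(self, name: str) -> bool:
        """True when the section is present with at least one non-empty line."""
        return any(ln.strip() for ln in self.sections.get(name, []))

    def event_count(self, code: str) -> int:
        return sum(n for c, n in self.procedure_events if c == code)


@dataclass(frozen=True)
class SectionMetrics:
    """Non-empty line and non-space character counts for the three sections
    the pathologist writes: diagnosis, microscopic and the synoptic Cancer
    Care Summary."""

    dx_lines: int = 0
    micro_lines: int = 0
    ccs_lines: int = 0
    dx_chars: int = 0
    micro_chars: int = 0
    ccs_chars: int = 0


def _parse_count(token: str) -> int:
    token = token.lower()
    return int(token) if token.isdigit() else _NUMBER_WORDS[token]


def extract_parts(source_lines: list[str]) -> list[SpecimenPart]:
    """One :class:`SpecimenPart` per non-empty container line.

    Fragment/core counts are read from ``x<n>``, ``<n> cores`` and
    ``<n> fragments`` patterns (digits, or the written-out words one–ten).
    Lines without a recognisable count default to a single fragment; the
    parse is lenient and never raises.
    """
    parts: list[SpecimenPart] = []
    for line in source_lines:
        label = line.strip()
        if not label:
            continue
        part = SpecimenPart(label=label)
        m = _CORE_RE.search(label)
        if m:
            part.core_count = _parse_count(m.group(1))
            part.fragment_count = 0
        else:
            m = _FRAG_RE.search(label) or _X_COUNT_RE.search(label)
            if m:
                part.fragment_count = _parse_count(m.group(1))
        parts.append(part)
    return parts


def parse_report(text: str) -> PathologyReport:
    """Parse one final-report text into a :class:`PathologyReport`.

    Raises :class:`~pathworkload.errors.ParseError` when the CASE/SIGNED
    header is missing or the sign-out date is malformed.  Unknown lines
    before the first section header are ignored with a logged warning;
    unknown procedure codes are preserved verbatim (scorers ignore them).
    """
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty report: missing CASE header (line 1)")
    m = _CASE_RE.match(lines[0])
    if not m:
        raise ParseError(f"line 1 is not a CASE header: {lines[0]!r}")
    case_id = m.group(1)
    if len(lines) < 2:
        raise ParseError(f"case {case_id}: missing SIGNED header (line 2)")
    m = _SIGNED_RE.match(lines[1])
    if not m:
        raise ParseError(f"case {case_id}: line 2 is not a SIGNED header: {lines[1]!r}")
    try:
        signout = _dt.date.fromisoformat(m.group(1))
    except ValueError as exc:
        raise ParseError(f"case {case_id}: malformed sign-out date {m.group(1)!r}") from exc

    report = PathologyReport(
        case_id=case_id, signout_date=signout, pathologist_id=m.group(2)
    )

    header_set = {h + ":" for h in SECTION_HEADERS}
    current: str | None = None
    for lineno, raw in enumerate(lines[2:], start=3):
        stripped = raw.strip()
        if stripped in header_set:
            current = stripped[:-1]
            report.sections.setdefault(current, [])
            continue
        if current is None:
            if stripped:
                logger.warning(
                    "case %s: ignoring line %d before first section header: %r",
                    case_id, lineno, stripped,
                )
            continue
        report.sections[current].append(raw.rstrip())

    for raw in report.section_lines("PATHOLOGY PROCEDURES"):
        stripped = raw.strip()
        if not stripped:
            continue
        m = _PROC_RE.match(stripped)
        if not m:
            logger.warning("case %s: unparseable procedure line %r", case_id, stripped)
            continue
        report.procedure_events.append((m.group(1), int(m.group(2))))

    report.block_count = report.event_count("BLK")

    report.parts = extract_parts(report.section_lines("SOURCE OF SPECIMEN"))
    # Re-associate tier codes with parts: one procedure line per coded
    # container, emitted in container order.
    tier_occurrences: list[str] = []
    for code, count in report.procedure_events:
        if code in L86X_CODES:
            tier_occurrences.extend([code] * count)
    for part, code in zip(report.parts, tier_occurrences):
        part.l86x_code = code
    if len(tier_occurrences) > len(report.parts):
        logger.warning(
            "case %s: %d tier code occurrences exceed %d parts",
            case_id, len(tier_occurrences), len(report.parts),
        )
    return report


def _count_lines_chars(lines: list[str]) -> tuple[int, int]:
    nonempty = [ln for ln in lines if ln.strip()]
    return len(nonempty), sum(len(ln) - ln.count(" ") - ln.count("\t") for ln in nonempty)


def count_section_metrics(report: PathologyReport) -> SectionMetrics:
    """Line/character metrics for the diagnosis, microscopic and CCS
    sections.  Missing sections count as zero; blank lines are excluded and
    characters are counted excluding whitespace."""
    dx_l, dx_c = _count_lines_chars(report.section_lines("DIAGNOSIS"))
    mi_l, mi_c = _count_lines_chars(report.section_lines("MICROSCOPIC"))
    cc_l, cc_c = _count_lines_chars(report.section_lines("CANCER CARE SUMMARY"))
    return SectionMetrics(dx_l, mi_l, cc_l, dx_c, mi_c, cc_c)


def count_ihc(report: PathologyReport, max_count: int = 99) -> int:
    """Number of immunohistochemical stains, proxied by HR (heat-retrieval)
    procedure codes, clamped at ``max_count`` (coding errors have produced
    three-digit HR counts on single cases)."""
    n = report.event_count("HR")
    if n > max_count:
        logger.warning(
            "case %s: HR count %d exceeds cap %d; clamped",
            report.case_id, n, max_count,
        )
        return max_count
    return n
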