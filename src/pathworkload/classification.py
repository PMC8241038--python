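"""Case stratification by L86x billing tier.

A case may carry several tier codes (one per container); for reporting it
is classified by the *highest* tier code present.  Cases carrying no L86x
code at all — cytology without a cell block — form their own stratum,
``L86x0``.  For summary statistics the three lowest tiers (L861–L863, small
resections) are lumped into a single stratum; scoring and billing always
use the individual codes.
"""

from __future__ import annotations

from enum import Enum

from .config import L86X_CODES
from .report_parser import PathologyReport


class L86xStratum(str, Enum):
    """Reporting strata (L861–L863 lumped)."""

    L861_3 = "L861_3"
    L864 = "L864"
    L865 = "L865"
    L866 = "L866"
    L86X0 = "L86x0"


_CODE_TO_STRATUM = {
    "L861": L86xStratum.L861_3,
    "L862": L86xStratum.L861_3,
    "L863": L86xStratum.L861_3,
    "L864": L86xStratum.L864,
    "L865": L86xStratum.L865,
    "L866": L86xStratum.L866,
}

#: Ascending tier order used to pick the highest code.
_TIER_RANK = {code: i for i, code in enumerate(L86X_CODES)}


def highest_l86x_code(codes) -> str | None:
    """The highest-ranked L86x code in ``codes``; None if none present."""
    tier_codes = [c for c in codes if c in _TIER_RANK]
    if not tier_codes:
        return None
    return max(tier_codes, key=_TIER_RANK.__getitem__)


def classify_l86x(report: PathologyReport) -> L86xStratum:
    """Assign the reporting stratum from the case's tier-code multiset.

    Pure function of the codes present (order/multiplicity irrelevant):
    highest code wins; no code at all maps to the cytology stratum.
    """
    codes = [c for c, n in report.procedure_events if n > 0]
    codes.extend(p.l86x_code for p in report.parts if p.l86x_code)
    top = highest_l86x_code(codes)
    if top is None:
        return L86xStratum.L86X0
    return _CODE_TO_STRATUM[top]
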