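"""End-to-end scoring: report texts -> one scored record per case.

This is the glue the CLI, the tests and the aggregation layer share: parse
each report, classify it, compute section metrics and run all three
scoring systems, emitting a flat table (one row per case).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .classification import classify_l86x
from .config import ScoringConfig, default_config
from .l4e_scoring import score_l4e
from .report_parser import PathologyReport, count_ihc, count_section_metrics, parse_report
from .w2q_fees import compute_sobf, score_w2q

#: Columns of the scored-record table.
RECORD_COLUMNS = [
    "case_id", "year", "signout_date", "pathologist_id", "stratum",
    "l4e_base", "l4e", "w2q", "fee_cents", "fee",
    "blocks", "ihc", "special_stains",
    "dx_lines", "micro_lines", "ccs_lines",
    "dx_chars", "micro_chars", "ccs_chars",
]


def score_report(report: PathologyReport, config: ScoringConfig) -> dict:
    """One scored record (dict) for a parsed report."""
    stratum = classify_l86x(report)
    metrics = count_section_metrics(report)
    l4e = score_l4e(report, config)
    w2q = score_w2q(report, config)
    fee = compute_sobf(report, config)
    return {
        "case_id": report.case_id,
        "year": report.signout_date.year,
        "signout_date": report.signout_date,
        "pathologist_id": report.pathologist_id,
        "stratum": stratum.value,
        "l4e_base": l4e.base,
        "l4e": l4e.final,
        "w2q": w2q.final,
        "fee_cents": fee.total_cents,
        "fee": fee.total,
        "blocks": report.block_count,
        "ihc": count_ihc(report, config.caps.ihc_max),
        "special_stains": report.event_count("SS"),
        "dx_lines": metrics.dx_lines,
        "micro_lines": metrics.micro_lines,
        "ccs_lines": metrics.ccs_lines,
        "dx_chars": metrics.dx_chars,
        "micro_chars": metrics.micro_chars,
        "ccs_chars": metrics.ccs_chars,
    }


def score_corpus(
    texts: Iterable[str], config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Parse and score a corpus of report texts into the scored-record
    table (one row per case)."""
    cfg = config or default_config()
    rows = [score_report(parse_report(t), cfg) for t in texts]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
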