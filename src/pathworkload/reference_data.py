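"""Published reference tables from the 2011–2019 regional-laboratory
workload study that this package's analysis reproduces.

Three small tables are shipped as CSV:

* ``yearly_totals.csv`` — per-year totals of L4E units, W2Q units,
  Schedule-of-Benefits fees (CAD), blocks, report lines, IHCs, special
  stains, pathologist FTEs and cases;
* ``report_lines.csv`` — per-year line counts of the diagnosis,
  microscopic and Cancer Care Summary sections;
* ``stratum_medians.csv`` — per-L86x-stratum median L4E, W2Q and fee.

They are inputs (printed summary values transcribed from the published
study), not outputs of this package; desk-scale arithmetic — trend
percentages, fee-per-unit quotients and the pure-practice comparison — is
recomputed from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .aggregate import StratumSummary


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("pathworkload.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_published_yearly_totals() -> pd.DataFrame:
    """Per-year workload/workforce totals (fees in CAD dollars)."""
    return _read("yearly_totals.csv")


def load_published_report_lines() -> pd.DataFrame:
    """Per-year diagnosis/microscopic/CCS line counts."""
    return _read("report_lines.csv")


def load_published_stratum_medians() -> list[StratumSummary]:
    """Per-stratum median L4E/W2Q/fee as :class:`StratumSummary` records."""
    df = _read("stratum_medians.csv")
    return [
        StratumSummary(
            stratum=row.stratum,
            median_l4e=float(row.l4e),
            median_w2q=float(row.w2q),
            median_fee=float(row.fee),
        )
        for row in df.itertuples()
    ]
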