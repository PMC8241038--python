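"""Manual-audit workflow: seeded case sampling and coding accuracy.

A random, anonymized subset of scored cases is exported for human
re-scoring of the L4E value; re-imported manual scores are compared with
the machine scores and summarised as an agreement proportion.  Agreement
means the absolute difference is within the configured tolerance (default
0.05 L4E units, one quantisation step of the point tables).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AuditError

#: Columns of the exported audit sample (pathologist identifiers are
#: stripped; the manual column ships blank).
AUDIT_COLUMNS = ["case_id", "machine_l4e", "manual_l4e"]


def sample_for_audit(records: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of ``n`` cases without replacement, shuffled,
    deterministic for a fixed seed.

    The output carries only the case id, the machine L4E score and a blank
    ``manual_l4e`` column — pathologist identifiers are stripped so the
    audit is blinded.  Raises :class:`AuditError` when ``n`` exceeds the
    population.
    """
    if n > len(records):
        raise AuditError(
            f"audit sample size {n} exceeds population {len(records)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))[:n]
    out = records.iloc[idx][["case_id", "l4e"]].rename(
        columns={"l4e": "machine_l4e"}
    )
    out["manual_l4e"] = np.nan
    return out.reset_index(drop=True)


def audit_accuracy(records: pd.DataFrame, tolerance: float = 0.05) -> float:
    """Proportion of audited cases whose manual L4E agrees with the machine
    score within ``tolerance``.

    Rows without a manual value are ignored; raises :class:`AuditError`
    when none carry one.  Order invariant, result in [0, 1].
    """
    scored = records.dropna(subset=["manual_l4e"])
    if scored.empty:
        raise AuditError("no audit records carry a manual L4E value")
    # small epsilon so a difference of exactly one quantisation step is
    # not rejected by float representation error
    agree = (scored["machine_l4e"] - scored["manual_l4e"]).abs() <= tolerance + 1e-9
    return float(agree.mean())
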