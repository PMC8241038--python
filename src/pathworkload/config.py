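"""Scoring configuration: the editable tables every scorer reads.

All point values, fee codes, caps, discount rules and multipliers live in a
single :class:`ScoringConfig` so that a site can re-score a corpus under its
own tariffs by editing one YAML file.  The shipped defaults model a Canadian
academic regional laboratory billing under the Ontario Schedule of Benefits
(March 2020) and scoring under the CAP-ACP Level-4-Equivalent 2018 update
(L4E) and the Ontario Work2Quality (W2Q) system.

Billing codes
-------------
``L861``–``L866``
    The six-tier Ontario surgical-pathology codes, roughly ordered by
    specimen complexity (L864 ~ most biopsies, L866 ~ large cancer
    resections).  A case may carry several; one code per specimen container.
``L805``
    Stand-in cytology professional code (e.g. Pap test, urine cytology).
    The schedule has a family of cytology codes; a single representative
    code is used here, and its fee is a placeholder calibrated to the
    published median fee of cytology-without-cell-block cases.

Ancillary procedure codes: ``HR`` (heat retrieval, the proxy for one
immunohistochemical stain), ``SS`` (special stain), ``MOL`` (molecular
test), ``FS`` (frozen section / intraoperative consult), ``BLK`` (paraffin
block count).
"""

from __future__ import annotations

import io
import json
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

CONFIG_SCHEMA_VERSION = "1"

#: Ontario surgical-pathology tier codes, ascending complexity.
L86X_CODES = ("L861", "L862", "L863", "L864", "L865", "L866")
#: Representative cytology professional code.
CYTOLOGY_CODE = "L805"
#: Billable codes = tier codes + cytology.
BILLABLE_CODES = L86X_CODES + (CYTOLOGY_CODE,)
#: Ancillary (non-billable here) procedure codes.
ANCILLARY_CODES = ("HR", "SS", "MOL", "FS", "BLK")

#: Tier codes whose work is captured by fragment/core counting (biopsies).
BIOPSY_CODES = ("L861", "L862", "L863", "L864")
#: Tier codes whose work is captured by block counting (large excisions).
EXCISION_CODES = ("L865", "L866")


class DiscountRule(BaseModel):
    """'Micro-only' discount applied to the base L4E when the pathologist
    does not gross the specimen (grossing done by assistants/residents).

    Base values strictly above ``threshold`` are discounted at
    ``high_rate``; values at or below it at ``low_rate``.  A base of exactly
    ``threshold`` receives the milder discount (the rule is stated as an
    open interval on both sides; the milder reading is used).
    """

    model_config = ConfigDict(extra="forbid")

    threshold: float = 10.0
    high_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    low_rate: float = Field(default=0.05, ge=0.0, le=1.0)


class Caps(BaseModel):
    """Per-case maxima introduced as a data-cleaning guard against coding
    errors producing extreme values (e.g. a case recorded with 442 HR
    codes)."""

    model_config = ConfigDict(extra="forbid")

    l4e_max: float = Field(default=50.0, gt=0)
    w2q_max: float = Field(default=50.0, gt=0)
    fee_max_cents: int = Field(default=150_000, gt=0)  # $1,500.00
    ihc_max: int = Field(default=99, gt=0)  # HR count truncated to two digits


class Multipliers(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: Case value multiplier when the report carries a formal consultation
    #: section.
    formal_consult: float = Field(default=1.5, ge=0)
    #: Teaching-hospital adjustment (residents participate in sign-out).
    teaching: float = Field(default=1.3, ge=0)
    #: Teaching adjustment can be switched off to model non-teaching sites.
    teaching_enabled: bool = True


class InformalConsultPoints(BaseModel):
    """L4E added for intradepartmental slide reviews detected as 'Dr.'
    mentions in the diagnosis/microscopic text."""

    model_config = ConfigDict(extra="forbid")

    one_doctor: float = Field(default=0.5, ge=0)
    two_or_more: float = Field(default=1.0, ge=0)


class L4EPoints(BaseModel):
    """Per-code base L4E values plus count-driven increments.

    ``base`` values are calibrated constants (the L4E manual's full point
    catalogue is an external document): they are chosen so that scoring the
    default synthetic corpus end-to-end reproduces the published per-tier
    median L4E values.  Fragment/core increments apply per part beyond the
    first fragment/core for biopsy codes; the block increment applies per
    recorded block on cases carrying an excision code (L865/L866).
    """

    model_config = ConfigDict(extra="forbid")

    base: dict[str, float] = Field(
        default_factory=lambda: {
            "L861": 0.4,
            "L862": 0.4,
            "L863": 0.4,
            "L864": 0.8,
            "L865": 0.7789473684210525,
            "L866": 4.65,
            "L805": 1.0,
        }
    )
    per_extra_fragment: float = Field(default=0.1, ge=0)
    per_extra_core: float = Field(default=0.1, ge=0)
    per_block: float = Field(default=0.2, ge=0)
    ihc: float = Field(default=0.5, ge=0)
    special_stain: float = Field(default=0.25, ge=0)
    molecular: float = Field(default=1.0, ge=0)
    frozen_section: float = Field(default=2.0, ge=0)
    synoptic: float = Field(default=3.0, ge=0)

    @field_validator("base")
    @classmethod
    def _nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        for code, pts in v.items():
            if pts < 0:
                raise ValueError(f"l4e base points for {code} must be >= 0")
        return v


class W2QWeights(BaseModel):
    """Work2Quality per-code weights and ancillary adjustments.

    The W2Q definition is an external regional document; per-code weights
    are calibrated so default-corpus stratum medians reproduce the published
    medians.  Ancillary testing is weighted more heavily than in L4E, and
    no teaching adjustment exists in W2Q.
    """

    model_config = ConfigDict(extra="forbid")

    base: dict[str, float] = Field(
        default_factory=lambda: {
            "L861": 0.29,
            "L862": 0.29,
            "L863": 0.29,
            "L864": 1.7,
            "L865": 2.54,
            "L866": 5.49,
            "L805": 0.56,
        }
    )
    ihc: float = Field(default=0.5, ge=0)
    special_stain: float = Field(default=0.3, ge=0)
    molecular: float = Field(default=1.0, ge=0)
    frozen_section: float = Field(default=1.0, ge=0)
    synoptic: float = Field(default=1.0, ge=0)
    internal_consult: float = Field(default=0.5, ge=0)
    external_consult: float = Field(default=1.0, ge=0)

    @field_validator("base")
    @classmethod
    def _nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        for code, pts in v.items():
            if pts < 0:
                raise ValueError(f"w2q weight for {code} must be >= 0")
        return v


class AuditSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: |machine - manual| tolerance (L4E units) for counting agreement;
    #: point values are quantised in 0.05 steps, so 0.05 is one step.
    agreement_tolerance: float = Field(default=0.05, ge=0)


class ScoringConfig(BaseModel):
    """All tunable scoring tables, round-trippable through YAML/JSON."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = CONFIG_SCHEMA_VERSION
    l4e: L4EPoints = Field(default_factory=L4EPoints)
    w2q: W2QWeights = Field(default_factory=W2QWeights)
    #: Ontario Schedule of Benefits fee per billable code, in integer cents
    #: (currency arithmetic is exact).  Tier fees equal the published
    #: per-tier median fees; the cytology fee is a placeholder (see module
    #: docstring).
    sob_fees_cents: dict[str, int] = Field(
        default_factory=lambda: {
            "L861": 1430,
            "L862": 1430,
            "L863": 1430,
            "L864": 9730,
            "L865": 16560,
            "L866": 34725,
            "L805": 460,
        }
    )
    caps: Caps = Field(default_factory=Caps)
    discount: DiscountRule = Field(default_factory=DiscountRule)
    multipliers: Multipliers = Field(default_factory=Multipliers)
    informal_consult: InformalConsultPoints = Field(
        default_factory=InformalConsultPoints
    )
    audit: AuditSettings = Field(default_factory=AuditSettings)

    @field_validator("sob_fees_cents")
    @classmethod
    def _nonnegative_fees(cls, v: dict[str, int]) -> dict[str, int]:
        for code, fee in v.items():
            if fee < 0:
                raise ValueError(f"fee for {code} must be >= 0")
        return v

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ScoringConfig":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
        data = yaml.safe_load(io.StringIO(text))
        return cls.model_validate(data)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, indent=2)


def default_config(**overrides: object) -> ScoringConfig:
    """The shipped default :class:`ScoringConfig` (teaching site, March-2020
    Ontario fees, calibrated L4E/W2Q tables)."""
    cfg = ScoringConfig()
    if overrides:
        cfg = cfg.model_copy(update=dict(overrides))
    return cfg


def zero_config() -> ScoringConfig:
    """A config with every point value and fee set to zero (caps retained).

    Useful as a degenerate baseline: any report scores 0 under it.
    """
    cfg = ScoringConfig()
    cfg.l4e.base = {c: 0.0 for c in cfg.l4e.base}
    for f in ("per_extra_fragment", "per_extra_core", "per_block", "ihc",
              "special_stain", "molecular", "frozen_section", "synoptic"):
        setattr(cfg.l4e, f, 0.0)
    cfg.w2q.base = {c: 0.0 for c in cfg.w2q.base}
    for f in ("ihc", "special_stain", "molecular", "frozen_section",
              "synoptic", "internal_consult", "external_consult"):
        setattr(cfg.w2q, f, 0.0)
    cfg.sob_fees_cents = {c: 0 for c in cfg.sob_fees_cents}
    cfg.informal_consult.one_doctor = 0.0
    cfg.informal_consult.two_or_more = 0.0
    return cfg
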