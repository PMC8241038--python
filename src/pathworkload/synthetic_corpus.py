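"""Seeded synthetic final-report corpora with ground-truth annotations.

Real accessioned pathology reports are confidential, so every downstream
stage (parsing, classification, scoring, workforce estimation,
aggregation) is exercised on generated corpora whose statistical structure
emulates a nine-year regional academic laboratory:

* a six-tier L86x case mix that drifts away from cytology and toward
  larger resections over the years;
* per-tier block/fragment/core count distributions;
* HR-code (IHC) intensity that rises then falls over the period;
* synoptic-report (Cancer Care Summary) adoption rising over the years on
  malignant-resection cases;
* informal consultations injected as literal ``Dr. <Surname>`` mentions in
  the diagnosis/microscopic text, and formal consultation sections;
* a pathologist roster with per-year allowed signing weeks, so FTE
  estimation is recoverable from the emitted sign-out dates.

Every case draws from its own pseudo-random stream keyed by
``(seed, case index)``, so generation is insertion-order independent and a
spec+seed pair yields a byte-identical corpus.

The emitted report dialect is the line-oriented format described in
:mod:`pathworkload.report_parser`; note it is a stand-in for the
(proprietary, undocumented) LIS export syntax — the analysis depends only
on named sections and coded procedure lines.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .report_parser import _count_lines_chars  # same convention as the parser

#: Code-level tier labels used by the mix vector (L86x0 = no tier code).
MIX_LABELS = ("L861", "L862", "L863", "L864", "L865", "L866", "L86x0")

#: Reporting strata (lumped) used for tier targets.
STRATA = ("L861_3", "L864", "L865", "L866", "L86x0")

_CODE_TO_STRATUM = {
    "L861": "L861_3", "L862": "L861_3", "L863": "L861_3",
    "L864": "L864", "L865": "L865", "L866": "L866", "L86x0": "L86x0",
}

#: Published per-stratum median targets (L4E units, W2Q units, fee CAD)
#: that the default generator + default scoring config are calibrated to
#: recover.
DEFAULT_TIER_TARGETS: dict[str, dict[str, float]] = {
    "L861_3": {"l4e": 0.6175, "w2q": 0.29, "fee": 14.30},
    "L864": {"l4e": 1.8525, "w2q": 2.00, "fee": 97.30},
    "L865": {"l4e": 5.135, "w2q": 4.04, "fee": 165.60},
    "L866": {"l4e": 15.32375, "w2q": 8.29, "fee": 347.25},
    "L86x0": {"l4e": 1.235, "w2q": 0.56, "fee": 4.60},
}


class RosterEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pathologist_id: str
    #: Number of ISO weeks per calendar year in which this pathologist is
    #: available to sign (>=42 behaves as full time).
    weeks_per_year: int = Field(ge=1, le=53)


class ConsultRates(BaseModel):
    model_config = ConfigDict(extra="forbid")

    informal_one: float = Field(default=0.04, ge=0, le=1)
    informal_two: float = Field(default=0.02, ge=0, le=1)
    formal: float = Field(default=0.02, ge=0, le=1)


class CorpusSpec(BaseModel):
    """Full description of a synthetic corpus; seed-deterministic."""

    model_config = ConfigDict(extra="forbid")

    years: tuple[int, int] = (2011, 2019)
    cases_per_year: int = Field(default=2000, ge=0)
    #: Per-year probability vector over MIX_LABELS.
    tier_mix: dict[int, dict[str, float]]
    tier_targets: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TIER_TARGETS.items()}
    )
    #: Per-code (base_blocks, poisson_lambda) block-count parameters.
    blocks_model: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "L861": (1, 0.8), "L862": (1, 0.8), "L863": (1, 0.8),
            "L864": (1, 0.5), "L865": (5, 3.0), "L866": (14, 6.0),
            "L86x0": (0, 0.0),
        }
    )
    #: Per-year mean HR (IHC proxy) codes per case.
    ihc_model: dict[int, float]
    #: Per-year probability that a malignant-resection (L865/L866) case
    #: carries a Cancer Care Summary section.
    synoptic_rate: dict[int, float]
    consult_rates: ConsultRates = Field(default_factory=ConsultRates)
    roster: list[RosterEntry]
    seed: int = 1

    @field_validator("years")
    @classmethod
    def _ordered_years(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[0] > v[1]:
            raise ValueError("years: start year must not exceed end year")
        return v

    @field_validator("roster")
    @classmethod
    def _nonempty_roster(cls, v: list[RosterEntry]) -> list[RosterEntry]:
        if not v:
            raise ValueError("roster: must contain at least one pathologist")
        return v

    @model_validator(mode="after")
    def _check_rates_and_mix(self) -> "CorpusSpec":
        y0, y1 = self.years
        for year in range(y0, y1 + 1):
            if year not in self.tier_mix:
                raise ValueError(f"tier_mix: missing year {year}")
            mix = self.tier_mix[year]
            if set(mix) != set(MIX_LABELS):
                raise ValueError(f"tier_mix[{year}]: labels must be {MIX_LABELS}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"tier_mix[{year}]: probabilities sum to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"tier_mix[{year}]: negative probability")
            if year not in self.ihc_model:
                raise ValueError(f"ihc_model: missing year {year}")
            if self.ihc_model[year] < 0:
                raise ValueError(f"ihc_model[{year}]: must be >= 0")
            if year not in self.synoptic_rate:
                raise ValueError(f"synoptic_rate: missing year {year}")
            if not 0 <= self.synoptic_rate[year] <= 1:
                raise ValueError(f"synoptic_rate[{year}]: must be in [0, 1]")
        c = self.consult_rates
        if c.informal_one + c.informal_two > 1:
            raise ValueError("consult_rates: informal_one + informal_two must be <= 1")
        return self


@dataclass
class GroundTruth:
    """Oracle record for one generated case (keyed by case_id)."""

    case_id: str
    year: int
    stratum: str
    part_codes: list[str]
    fragment_counts: list[int]
    core_counts: list[int]
    block_count: int
    hr_count: int
    ss_count: int
    mol_count: int
    fs_count: int
    cellblock: bool
    synoptic: bool
    informal_doctors: int
    formal_consult: bool
    signout_date: _dt.date
    pathologist_id: str
    dx_lines: int = 0
    micro_lines: int = 0
    ccs_lines: int = 0
    dx_chars: int = 0
    micro_chars: int = 0
    ccs_chars: int = 0


GROUND_TRUTH_COLUMNS = [f.name for f in _dc_fields(GroundTruth)]


# --- default spec ---------------------------------------------------------

_MIX_2011 = {"L861": 0.020, "L862": 0.020, "L863": 0.040,
             "L864": 0.450, "L865": 0.080, "L866": 0.035, "L86x0": 0.355}
_MIX_2019 = {"L861": 0.025, "L862": 0.025, "L863": 0.045,
             "L864": 0.460, "L865": 0.120, "L866": 0.065, "L86x0": 0.260}
#: Rise-then-fall IHC intensity (mean HR/case), shaped like the published
#: yearly IHC-per-case ratios.
_IHC_BY_YEAR = {2011: 0.61, 2012: 0.72, 2013: 0.98, 2014: 1.26, 2015: 1.29,
                2016: 1.15, 2017: 1.15, 2018: 1.08, 2019: 0.98}


def _interp_mix(year: int, y0: int, y1: int) -> dict[str, float]:
    t = 0.0 if y1 == y0 else (year - y0) / (y1 - y0)
    mix = {k: (1 - t) * _MIX_2011[k] + t * _MIX_2019[k] for k in MIX_LABELS}
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


def default_roster() -> list[RosterEntry]:
    entries = [RosterEntry(pathologist_id=f"P{i:02d}", weeks_per_year=52)
               for i in range(1, 12)]
    for i, w in zip((12, 13, 14, 15), (20, 24, 30, 36)):
        entries.append(RosterEntry(pathologist_id=f"P{i:02d}", weeks_per_year=w))
    return entries


def default_corpus_spec(
    years: tuple[int, int] = (2011, 2019),
    cases_per_year: int = 2000,
    seed: int = 1,
) -> CorpusSpec:
    """The study-conditions spec: nine years of drifting case mix, IHC
    rise-then-fall, synoptic adoption and a 15-pathologist roster."""
    y0, y1 = years
    span = range(y0, y1 + 1)
    return CorpusSpec(
        years=years,
        cases_per_year=cases_per_year,
        tier_mix={y: _interp_mix(y, y0, y1) for y in span},
        ihc_model={
            y: _IHC_BY_YEAR.get(y, 1.0) for y in span
        },
        synoptic_rate={
            y: 0.25 + (0.0 if y1 == y0 else 0.30 * (y - y0) / (y1 - y0))
            for y in span
        },
        roster=default_roster(),
        seed=seed,
    )


# --- generation internals -------------------------------------------------

_N_PARTS_P = {
    "L861_3": ([1, 2, 3], [0.80, 0.15, 0.05]),
    "L864": ([1, 2, 3], [0.72, 0.23, 0.05]),
    "L865": ([1, 2], [0.85, 0.15]),
    "L866": ([1, 2], [0.90, 0.10]),
    "L86x0": ([1], [1.0]),
}
_FRAG_P = ([1, 2, 3, 4], [0.65, 0.20, 0.10, 0.05])
#: Relative IHC propensity by stratum (cancer resections stain most).
_IHC_TIER_WEIGHT = {"L861_3": 0.3, "L864": 1.0, "L865": 1.5, "L866": 2.5,
                    "L86x0": 0.05}
#: IHC arrives in panels: a minority of cases receive several stains.
#: Panel size is 2 + Poisson(2.5) HR codes (mean _IHC_PANEL_MEAN).
_IHC_PANEL_MEAN = 4.5
#: Special-stain intensity (Poisson mean) by stratum.
_SS_LAMBDA = {"L861_3": 0.08, "L864": 0.12, "L865": 0.20, "L866": 0.35,
              "L86x0": 0.01}
#: Fraction of intermediate resections (L865) that are malignant and hence
#: synoptic-eligible; large resections (L866) are all cancer resections.
_L865_MALIGNANT_FRACTION = 0.25

_BIOPSY_LABELS = ("stomach biopsies", "colon polyp", "skin lesion",
                  "endometrial curettings", "breast core biopsy",
                  "duodenal biopsies")
_SMALL_RESECTION_LABELS = ("appendix", "gallbladder", "ganglion cyst",
                           "tonsils", "hemorrhoids")
_MID_RESECTION_LABELS = ("uterus and cervix", "salivary gland resection",
                         "thyroid lobe", "colon segment")
_LARGE_RESECTION_LABELS = ("radical prostatectomy", "laryngectomy",
                           "mastectomy with axillary contents",
                           "total colectomy for carcinoma")
_CYTO_LABELS = ("urine cytology", "pap test", "pleural fluid",
                "bronchial washings")

_DX_PHRASES = (
    "Fragments of benign mucosa with mild chronic inflammation.",
    "No evidence of dysplasia or malignancy identified.",
    "Invasive carcinoma, see synoptic summary.",
    "Benign tissue consistent with the clinical impression.",
    "Focal active inflammation without granulomas.",
    "Margins are free of tumour.",
    "Tubular adenoma with low-grade dysplasia.",
    "Reactive changes only.",
)
_MICRO_PHRASES = (
    "Sections show preserved architecture.",
    "There is a mild lymphocytic infiltrate.",
    "Special studies were reviewed and are noncontributory.",
    "The lesion is well circumscribed.",
    "Mitotic figures are inconspicuous.",
)
_CCS_ELEMENTS = (
    "Histologic type", "Histologic grade", "Tumour size", "Margins",
    "Lymphovascular invasion", "Perineural invasion", "Pathologic stage",
    "Lymph nodes examined", "Lymph nodes involved", "Treatment effect",
    "Tumour site", "Tumour focality", "Specimen integrity",
    "Distance to closest margin", "Extramural venous invasion",
    "Ancillary studies", "Regional nodes status", "Distant metastasis",
    "Specimen laterality", "Procedure", "Additional findings",
    "Comment", "Depth of invasion", "Resection completeness",
)
_CCS_VALUES = ("adenocarcinoma", "grade 2 of 3", "negative", "positive",
               "not identified", "2.3 cm", "pT2", "0 of 12", "complete",
               "see comment")
_SURNAMES = ("Smith", "Jones", "Chen", "Patel", "Garcia", "Mueller",
             "Tremblay", "Okafor", "Rossi", "Tanaka")

_GROSS_PHRASES = (
    "The specimen is received in formalin.",
    "Representative sections are submitted.",
    "The specimen is serially sectioned.",
)

_DX_BASE_LINES = {"L86x0": 2, "L861_3": 3, "L864": 4, "L865": 6, "L866": 9}


def _year_days_by_week(year: int) -> dict[tuple[int, int], list[_dt.date]]:
    days: dict[tuple[int, int], list[_dt.date]] = {}
    d = _dt.date(year, 1, 1)
    one = _dt.timedelta(days=1)
    while d.year == year:
        cal = d.isocalendar()
        days.setdefault((cal[0], cal[1]), []).append(d)
        d += one
    return days


class _Generator:
    def __init__(self, spec: CorpusSpec):
        self.spec = spec
        # Allowed signing days per (roster index, year), drawn from a
        # dedicated stream so case order cannot perturb the roster.
        self._allowed_days: dict[tuple[int, int], list[_dt.date]] = {}
        y0, y1 = spec.years
        for year in range(y0, y1 + 1):
            by_week = _year_days_by_week(year)
            labels = sorted(by_week)
            for idx, entry in enumerate(spec.roster):
                rng = np.random.default_rng([spec.seed, 2, idx, year])
                k = min(entry.weeks_per_year, len(labels))
                chosen = rng.choice(len(labels), size=k, replace=False)
                days: list[_dt.date] = []
                for li in sorted(chosen):
                    days.extend(by_week[labels[li]])
                self._allowed_days[(idx, year)] = days

    # -- one case ---------------------------------------------------------

    def generate_case(self, year: int, case_index: int) -> tuple[str, GroundTruth]:
        spec = self.spec
        rng = np.random.default_rng([spec.seed, 1, case_index])
        case_id = f"S{year}-{case_index:06d}"

        mix = spec.tier_mix[year]
        main_code = str(rng.choice(MIX_LABELS, p=[mix[k] for k in MIX_LABELS]))
        stratum = _CODE_TO_STRATUM[main_code]

        # pathologist + sign-out date within their allowed weeks
        ridx = int(rng.integers(len(spec.roster)))
        days = self._allowed_days[(ridx, year)]
        signout = days[int(rng.integers(len(days)))]
        pathologist = spec.roster[ridx].pathologist_id

        # parts and their codes
        counts, probs = _N_PARTS_P[stratum]
        n_parts = int(rng.choice(counts, p=probs))
        part_codes: list[str] = []
        if stratum == "L86x0":
            part_codes = [""]
        else:
            part_codes.append(main_code)
            for _ in range(n_parts - 1):
                if stratum in ("L865", "L866"):
                    extra = str(rng.choice([main_code, "L864"]))
                else:
                    rank = MIX_LABELS.index(main_code)
                    extra = str(rng.choice(MIX_LABELS[: rank + 1]))
                part_codes.append(extra)

        source_lines: list[str] = []
        fragment_counts: list[int] = []
        core_counts: list[int] = []
        block_count = 0
        for i, code in enumerate(part_codes):
            letter = chr(ord("A") + i)
            frag, core = 1, 0
            if code in ("L861", "L862", "L863"):
                label = str(rng.choice(_SMALL_RESECTION_LABELS))
                frag = int(rng.choice(_FRAG_P[0], p=[0.75, 0.15, 0.07, 0.03]))
            elif code == "L864":
                if rng.random() < 0.25:
                    label = "prostate biopsy"
                    core = int(rng.integers(2, 7))
                    frag = 0
                else:
                    label = str(rng.choice(_BIOPSY_LABELS))
                    frag = int(rng.choice(_FRAG_P[0], p=_FRAG_P[1]))
            elif code == "L865":
                label = str(rng.choice(_MID_RESECTION_LABELS))
            elif code == "L866":
                label = str(rng.choice(_LARGE_RESECTION_LABELS))
            else:  # cytology, no tier code
                label = str(rng.choice(_CYTO_LABELS))
            # container line text
            if core > 0:
                suffix = f", {core} cores"
            elif frag > 1:
                if rng.random() < 0.25 and frag <= 10:
                    word = ("one two three four five six seven eight nine ten"
                            .split()[frag - 1])
                    suffix = f", {word} fragments"
                else:
                    suffix = f" x{frag}"
            else:
                suffix = ""
            source_lines.append(f"{letter}. {label}{suffix}")
            fragment_counts.append(frag)
            core_counts.append(core)
            if code:
                b0, lam = spec.blocks_model[code]
                block_count += int(b0) + int(rng.poisson(lam))

        # ancillary work: IHC comes in panels on a minority of cases, with
        # the per-year mean HR/case following the configured intensity.
        w = _IHC_TIER_WEIGHT
        norm = sum(mix[k] * w[_CODE_TO_STRATUM[k]] for k in MIX_LABELS)
        p_panel = 0.0
        if norm > 0:
            p_panel = min(1.0, spec.ihc_model[year] * w[stratum] / (norm * _IHC_PANEL_MEAN))
        hr = (2 + int(rng.poisson(2.5))) if rng.random() < p_panel else 0
        ss = int(rng.poisson(_SS_LAMBDA[stratum]))
        mol = int(rng.random() < {"L864": 0.05, "L865": 0.06, "L866": 0.10}.get(stratum, 0.0))
        fs = 0
        if stratum == "L865" and rng.random() < 0.07:
            fs = 1
        elif stratum == "L866" and rng.random() < 0.12:
            fs = int(rng.integers(1, 3))
        cellblock = stratum == "L864" and main_code == "L864" and rng.random() < 0.08
        if cellblock:
            block_count += 1
        p_syn = spec.synoptic_rate[year]
        if stratum == "L865":
            p_syn *= _L865_MALIGNANT_FRACTION
        synoptic = stratum in ("L865", "L866") and rng.random() < p_syn

        c = spec.consult_rates
        u = rng.random()
        if u < c.informal_two:
            informal_doctors = 2
        elif u < c.informal_two + c.informal_one:
            informal_doctors = 1
        else:
            informal_doctors = 0
        formal = rng.random() < c.formal

        # free-text sections
        y0, y1 = spec.years
        tfrac = 0.0 if y1 == y0 else (year - y0) / (y1 - y0)
        dx_base = _DX_BASE_LINES[stratum]
        n_dx = max(1, dx_base + int(rng.poisson(0.8))
                   + int(round(dx_base * 0.15 * tfrac)))
        dx_lines = [str(rng.choice(_DX_PHRASES)) for _ in range(n_dx)]
        if informal_doctors == 1:
            name = str(rng.choice(_SURNAMES))
            dx_lines.append(f"The case was reviewed with Dr. {name} who concurs.")
        elif informal_doctors == 2:
            n1, n2 = (str(s) for s in rng.choice(_SURNAMES, size=2, replace=False))
            dx_lines.append(f"Reviewed with Dr. {n1} and Dr. {n2} who concur.")

        n_micro = int(rng.poisson(max(0.2, 1.8 - 0.7 * tfrac)))
        micro_lines = [str(rng.choice(_MICRO_PHRASES)) for _ in range(n_micro)]

        ccs_lines: list[str] = []
        if synoptic:
            n_ccs = 14 + int(rng.poisson(3.0)) + int(round(6 * tfrac))
            n_ccs = min(n_ccs, len(_CCS_ELEMENTS))
            elems = rng.choice(len(_CCS_ELEMENTS), size=n_ccs, replace=False)
            ccs_lines = [
                f"{_CCS_ELEMENTS[e]}: {rng.choice(_CCS_VALUES)}"
                for e in sorted(elems)
            ]

        gross_lines = [str(rng.choice(_GROSS_PHRASES))]

        # procedure lines: one tier line per coded container, in container
        # order, then cytology/ancillary codes.
        proc_lines = [f"{code} x1" for code in part_codes if code]
        if stratum == "L86x0":
            proc_lines.append("L805 x1")
        if cellblock:
            proc_lines.append("L805 x1")
        for code, n in (("HR", hr), ("SS", ss), ("MOL", mol), ("FS", fs)):
            if n > 0:
                proc_lines.append(f"{code} x{n}")
        if block_count > 0:
            proc_lines.append(f"BLK x{block_count}")

        out = [f"CASE: {case_id}",
               f"SIGNED: {signout.isoformat()} BY {pathologist}",
               "SOURCE OF SPECIMEN:"]
        out.extend(source_lines)
        out.append("GROSS PATHOLOGY:")
        out.extend(gross_lines)
        out.append("DIAGNOSIS:")
        out.extend(dx_lines)
        if micro_lines:
            out.append("MICROSCOPIC:")
            out.extend(micro_lines)
        if ccs_lines:
            out.append("CANCER CARE SUMMARY:")
            out.extend(ccs_lines)
        if formal:
            out.append("CONSULTATION:")
            out.append("The case was submitted for formal departmental consultation.")
            out.append("The consultant agrees with the favoured interpretation.")
        out.append("PATHOLOGY PROCEDURES:")
        out.extend(proc_lines)
        text = "\n".join(out) + "\n"

        dx_l, dx_c = _count_lines_chars(dx_lines)
        mi_l, mi_c = _count_lines_chars(micro_lines)
        cc_l, cc_c = _count_lines_chars(ccs_lines)
        truth = GroundTruth(
            case_id=case_id,
            year=year,
            stratum=stratum,
            part_codes=part_codes,
            fragment_counts=fragment_counts,
            core_counts=core_counts,
            block_count=block_count,
            hr_count=hr,
            ss_count=ss,
            mol_count=mol,
            fs_count=fs,
            cellblock=cellblock,
            synoptic=synoptic,
            informal_doctors=informal_doctors,
            formal_consult=formal,
            signout_date=signout,
            pathologist_id=pathologist,
            dx_lines=dx_l, micro_lines=mi_l, ccs_lines=cc_l,
            dx_chars=dx_c, micro_chars=mi_c, ccs_chars=cc_c,
        )
        return text, truth


def generate_corpus(spec: CorpusSpec) -> tuple[list[str], list[GroundTruth]]:
    """Generate the full corpus for ``spec``.

    Returns one report text and one :class:`GroundTruth` per case, ordered
    by year then case index.  Identical spec+seed pairs produce
    byte-identical output.
    """
    gen = _Generator(spec)
    texts: list[str] = []
    truths: list[GroundTruth] = []
    y0, y1 = spec.years
    case_index = 0
    for year in range(y0, y1 + 1):
        for _ in range(spec.cases_per_year):
            text, truth = gen.generate_case(year, case_index)
            texts.append(text)
            truths.append(truth)
            case_index += 1
    return texts, truths


def ground_truth_frame(truths: Iterable[GroundTruth]) -> pd.DataFrame:
    """Ground-truth records as a DataFrame (list fields '|'-joined)."""
    rows = []
    for t in truths:
        row = {}
        for f in GROUND_TRUTH_COLUMNS:
            v = getattr(t, f)
            if isinstance(v, list):
                v = "|".join(str(x) for x in v)
            elif isinstance(v, bool):
                v = int(v)
            elif isinstance(v, _dt.date):
                v = v.isoformat()
            row[f] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def emit_fixture(spec: CorpusSpec, path: str | Path) -> list[Path]:
    """Write the corpus to ``path``: one ``.txt`` per report, a
    ``ground_truth.csv`` table and the spec itself (``corpus_spec.yaml``)
    for provenance.  Returns the written paths."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    texts, truths = generate_corpus(spec)
    written: list[Path] = []
    for text, truth in zip(texts, truths):
        p = root / f"{truth.case_id}.txt"
        p.write_text(text, encoding="utf-8")
        written.append(p)
    gt_path = root / "ground_truth.csv"
    ground_truth_frame(truths).to_csv(gt_path, index=False)
    written.append(gt_path)
    spec_path = root / "corpus_spec.yaml"
    spec_path.write_text(
        yaml.safe_dump(spec.model_dump(mode="json"), sort_keys=True),
        encoding="utf-8",
    )
    written.append(spec_path)
    return written
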