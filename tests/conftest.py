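"""Shared fixtures: the seed-pinned default corpus, its parsed and scored
forms, and small builders for hand-constructed reports and corpus specs."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings

import pathworkload as pw
from pathworkload.report_parser import PathologyReport, SpecimenPart
from pathworkload.synthetic_corpus import MIX_LABELS

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> pw.ScoringConfig:
    return pw.default_config()


@pytest.fixture(scope="session")
def corpus():
    """The study-conditions corpus: nine years, 2,000 cases/year, seed 1."""
    spec = pw.default_corpus_spec(cases_per_year=2000, seed=1)
    texts, truths = pw.generate_corpus(spec)
    return spec, texts, truths


@pytest.fixture(scope="session")
def parsed_reports(corpus):
    _, texts, _ = corpus
    return [pw.parse_report(t) for t in texts]


@pytest.fixture(scope="session")
def records(corpus, config):
    _, texts, _ = corpus
    return pw.score_corpus(texts, config)


def make_mix(**probs: float) -> dict[str, float]:
    """A tier-mix vector with the named labels set and the rest zero."""
    mix = {k: 0.0 for k in MIX_LABELS}
    mix.update(probs)
    return mix


def make_spec(
    mix: dict[str, float],
    cases_per_year: int = 1,
    seed: int = 7,
    years: tuple[int, int] = (2014, 2014),
    **overrides,
) -> pw.CorpusSpec:
    """A one-mix corpus spec covering ``years`` (same mix every year)."""
    span = range(years[0], years[1] + 1)
    kwargs = dict(
        years=years,
        cases_per_year=cases_per_year,
        tier_mix={y: dict(mix) for y in span},
        ihc_model={y: 0.8 for y in span},
        synoptic_rate={y: 0.4 for y in span},
        roster=pw.synthetic_corpus.default_roster(),
        seed=seed,
    )
    kwargs.update(overrides)
    return pw.CorpusSpec(**kwargs)


def build_report(
    parts: list[SpecimenPart] | None = None,
    events: list[tuple[str, int]] | None = None,
    sections: dict[str, list[str]] | None = None,
    signout: dt.date = dt.date(2015, 6, 1),
    case_id: str = "T-1",
    pathologist: str = "P01",
) -> PathologyReport:
    """Directly assemble a parsed report for scorer unit tests."""
    report = PathologyReport(
        case_id=case_id,
        signout_date=signout,
        pathologist_id=pathologist,
        sections=sections or {},
        procedure_events=list(events or []),
        parts=list(parts or []),
    )
    report.block_count = report.event_count("BLK")
    return report
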