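"""L4E scoring chain: base points, discount, consults, multipliers, cap."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathworkload as pw
from pathworkload.errors import ScoringError
from pathworkload.report_parser import SpecimenPart

from conftest import build_report


@pytest.fixture()
def simple_config() -> pw.ScoringConfig:
    """Round-number tables so chains are hand-checkable."""
    cfg = pw.default_config()
    cfg.l4e.base = {"L861": 0.5, "L862": 0.5, "L863": 0.5,
                    "L864": 1.0, "L865": 4.0, "L866": 10.0, "L805": 1.0}
    cfg.l4e.per_extra_fragment = 0.1
    cfg.l4e.per_extra_core = 0.1
    cfg.l4e.per_block = 0.2
    return cfg


class TestBaseL4E:
    def test_single_part_is_its_base_value(self, simple_config):
        rep = build_report(parts=[SpecimenPart("A. biopsy", "L864")])
        assert pw.base_l4e(rep.parts, rep, simple_config) == 1.0

    def test_two_identical_parts_double(self, simple_config):
        part = SpecimenPart("A. biopsy", "L864", fragment_count=3)
        one = build_report(parts=[part])
        two = build_report(parts=[part, part])
        assert pw.base_l4e(two.parts, two, simple_config) == pytest.approx(
            2 * pw.base_l4e(one.parts, one, simple_config)
        )

    def test_fragment_core_and_block_increments(self, simple_config):
        rep = build_report(
            parts=[
                SpecimenPart("A", "L864", fragment_count=4),          # 1.0 + 0.3
                SpecimenPart("B", "L864", fragment_count=0, core_count=6),  # 1.0 + 0.5
                SpecimenPart("C", "L866"),                            # 10.0
            ],
            events=[("BLK", 10)],
        )
        # block increment applies once, per recorded block, on excision cases
        assert pw.base_l4e(rep.parts, rep, simple_config) == pytest.approx(
            1.3 + 1.5 + 10.0 + 0.2 * 10
        )

    def test_no_block_increment_without_excision_part(self, simple_config):
        rep = build_report(parts=[SpecimenPart("A", "L864")], events=[("BLK", 7)])
        assert pw.base_l4e(rep.parts, rep, simple_config) == 1.0

    def test_cytology_code_event_scores_base(self, simple_config):
        rep = build_report(parts=[SpecimenPart("A. urine")], events=[("L805", 1)])
        assert pw.base_l4e(rep.parts, rep, simple_config) == 1.0

    def test_unknown_code_raises_naming_it(self, simple_config):
        rep = build_report(parts=[SpecimenPart("A", "L869")])
        with pytest.raises(ScoringError, match="L869"):
            pw.base_l4e(rep.parts, rep, simple_config)

    def test_random_part_lists_match_naive_sum(self, simple_config):
        """Brute-force oracle: per-part summation done independently."""
        rng = np.random.default_rng(123)
        codes = ["L861", "L862", "L863", "L864", "L865", "L866"]
        for _ in range(200):
            parts = []
            expected = 0.0
            has_excision = False
            for _ in range(rng.integers(0, 6)):
                code = codes[rng.integers(len(codes))]
                frag = int(rng.integers(0, 5))
                core = int(rng.integers(0, 5))
                parts.append(SpecimenPart("X", code, frag, core))
                expected += simple_config.l4e.base[code]
                if code in ("L865", "L866"):
                    has_excision = True
                else:
                    expected += 0.1 * max(0, frag - 1) + 0.1 * max(0, core - 1)
            blocks = int(rng.integers(0, 20))
            if has_excision:
                expected += 0.2 * blocks
            rep = build_report(parts=parts, events=[("BLK", blocks)] if blocks else [])
            assert pw.base_l4e(rep.parts, rep, simple_config) == pytest.approx(expected)


class TestMicroOnlyDiscount:
    @pytest.mark.parametrize("base, expected", [
        (12.0, 10.8),   # >10: 10% off
        (4.0, 3.8),     # <10: 5% off
        (0.0, 0.0),
        (10.0, 9.5),    # boundary gets the milder 5% discount
    ])
    def test_discount_rates(self, base, expected, config):
        assert pw.micro_only_discount(base, config) == pytest.approx(expected)


class TestInformalConsultPoints:
    @pytest.mark.parametrize("dx, micro, expected", [
        ("reviewed with Dr. Smith", "", 0.5),
        ("Dr. Smith and Dr. Jones concur", "", 1.0),
        ("no consult mentioned", "sections unremarkable", 0.0),
        ("seen by DR. Patel", "", 0.5),
        ("Dr. Smith agrees", "also shown to Dr. Smith", 0.5),  # same individual
        ("Dr. Smith", "Dr. Chen", 1.0),  # across both sections
    ])
    def test_unique_doctor_counting(self, dx, micro, expected, config):
        assert pw.informal_consult_points(dx, micro, config) == expected


class TestScoreL4E:
    def test_hand_computed_chain(self, simple_config):
        """Base 12 (>10 so 10% off -> 10.8), + 2 IHC x 0.5 + synoptic 3,
        no consults, teaching x1.3: (10.8 + 4.0) x 1.3 = 19.24."""
        rep = build_report(
            parts=[SpecimenPart("A", "L866")],
            events=[("L866", 1), ("BLK", 10), ("HR", 2)],
            sections={"CANCER CARE SUMMARY": ["Histologic type: adenocarcinoma"]},
        )
        out = pw.score_l4e(rep, simple_config)
        assert out.base == pytest.approx(12.0)
        assert out.discounted_base == pytest.approx(10.8)
        assert out.ancillary == pytest.approx(4.0)
        assert out.informal_consult_points == 0.0
        assert not out.formal_consult_applied
        assert out.teaching_applied
        assert out.final == pytest.approx(19.24)

    def test_formal_consult_multiplier(self, simple_config):
        rep = build_report(
            parts=[SpecimenPart("A", "L864")],
            sections={"CONSULTATION": ["formal consultation rendered"]},
        )
        out = pw.score_l4e(rep, simple_config)
        assert out.formal_consult_applied
        assert out.final == pytest.approx(1.0 * 0.95 * 1.5 * 1.3)

    def test_cap_at_50(self, simple_config):
        rep = build_report(
            parts=[SpecimenPart("A", "L866")] * 5,
            events=[("BLK", 40), ("HR", 20)],
        )
        out = pw.score_l4e(rep, simple_config)
        assert out.capped
        assert out.final == 50.0

    def test_empty_case_scores_zero(self, simple_config):
        assert pw.score_l4e(build_report(), simple_config).final == 0.0

    def test_multiplier_order_commutes(self, simple_config):
        rep = build_report(
            parts=[SpecimenPart("A", "L865")],
            sections={"CONSULTATION": ["consult"]},
        )
        out = pw.score_l4e(rep, simple_config)
        subtotal = out.discounted_base + out.ancillary + out.informal_consult_points
        assert (subtotal * 1.5) * 1.3 == pytest.approx((subtotal * 1.3) * 1.5)
        assert out.final == pytest.approx(subtotal * 1.5 * 1.3)

    def test_zero_config_scores_zero(self, parsed_reports):
        zero = pw.zero_config()
        for rep in parsed_reports[:50]:
            assert pw.score_l4e(rep, zero).final == 0.0

    @given(
        blocks=st.integers(0, 30), ihc=st.integers(0, 20),
        more_blocks=st.integers(0, 10), more_ihc=st.integers(0, 10),
    )
    def test_monotone_in_counts_below_cap(self, blocks, ihc, more_blocks, more_ihc):
        cfg = pw.default_config()
        cfg.caps.l4e_max = 1e9  # effectively uncapped
        def score(b, h):
            rep = build_report(
                parts=[SpecimenPart("A", "L866")],
                events=[("BLK", b), ("HR", h)],
            )
            return pw.score_l4e(rep, cfg).final
        assert score(blocks + more_blocks, ihc + more_ihc) >= score(blocks, ihc) - 1e-12
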