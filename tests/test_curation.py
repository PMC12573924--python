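import math

import pytest
from hypothesis import given, strategies as st

from cifaudit import curation as cur
from cifaudit.cif_io import ABSENT, RawItemSet
from cifaudit.curation import (
    DEFAULT_RULES,
    ParsedValue,
    ValidityRule,
    apply_validity,
    audit_corpus,
    load_rules,
    parse_value,
)


class TestParseValue:
    def test_plain_numeric(self):
        pv = parse_value("0.0460")
        assert pv.status == "numeric" and pv.value == 0.046 and pv.su is None

    def test_su_on_last_digit(self):
        pv = parse_value("0.046(2)")
        assert pv.status == "numeric"
        assert pv.value == pytest.approx(0.046)
        assert pv.su == pytest.approx(0.002)

    def test_su_spanning_multiple_digits(self):
        pv = parse_value("0.71073(10)")
        assert pv.su == pytest.approx(0.00010)

    def test_bounded(self):
        pv = parse_value("<0.001")
        assert pv.status == "bounded" and pv.bound_text == "<0.001"

    def test_greater_than_bound(self):
        assert parse_value(">100").status == "bounded"

    @pytest.mark.parametrize("raw", ["?", ".", "", None, ABSENT])
    def test_missing(self, raw):
        assert parse_value(raw).status == "missing"

    @pytest.mark.parametrize("raw", ["abc", "1.2.3", "0.05 approx", "ca 0.05", "--1"])
    def test_malformed(self, raw):
        assert parse_value(raw).status == "malformed"

    def test_exponent_notation(self):
        pv = parse_value("1.000000e-03")
        assert pv.status == "numeric" and pv.value == pytest.approx(0.001)

    def test_integer_and_sign(self):
        assert parse_value("42").value == 42.0
        assert parse_value("-0.481").value == pytest.approx(-0.481)
        assert parse_value("+1.5").value == 1.5

    def test_exactly_one_status(self):
        for raw in ("0.05", "<1", "?", "junk text"):
            pv = parse_value(raw)
            assert sum([pv.status == s for s in
                        ("numeric", "bounded", "missing", "malformed")]) == 1


class TestApplyValidity:
    def test_r_out_of_range_high(self):
        ok, reason = apply_validity(cur.TAG_R, parse_value("1.2"))
        assert not ok and reason == "out-of-range"

    def test_theta_91_rejected(self):
        ok, reason = apply_validity(cur.TAG_THETA, parse_value("91"))
        assert not ok and reason == "out-of-range"

    def test_positive_rho_min_rejected(self):
        ok, reason = apply_validity(cur.TAG_RHO_MIN, parse_value("0.3"))
        assert not ok and reason == "out-of-range"

    def test_r_accepted(self):
        ok, reason = apply_validity(cur.TAG_R, parse_value("0.046"))
        assert ok and reason is None

    def test_bounded_rejected_as_unreadable(self):
        ok, reason = apply_validity(cur.TAG_SHIFT, parse_value("<0.01"))
        assert not ok and reason == "bounded-unreadable"

    def test_missing_and_malformed_reasons(self):
        assert apply_validity(cur.TAG_R, parse_value("?"))[1] == "missing"
        assert apply_validity(cur.TAG_R, parse_value("junk text"))[1] == "malformed"

    @pytest.mark.parametrize(
        "tag,boundary",
        [
            (cur.TAG_R, "1.0"), (cur.TAG_R, "0"), (cur.TAG_WR, "1.0"),
            (cur.TAG_SHIFT, "15.0"), (cur.TAG_SHIFT, "0.0"),
            (cur.TAG_RHO_MAX, "118"), (cur.TAG_RHO_MIN, "0"),
            (cur.TAG_RHO_MIN, "-118"), (cur.TAG_GOOF, "20"),
            (cur.TAG_THETA, "90.0"), (cur.TAG_THETA, "0"),
        ],
    )
    def test_strict_open_bounds(self, tag, boundary):
        ok, reason = apply_validity(tag, parse_value(boundary))
        assert not ok and reason == "out-of-range"

    def test_unknown_tag_is_configuration_error(self):
        with pytest.raises(KeyError):
            apply_validity("_no_such_tag", parse_value("1.0"))

    def test_rule_override(self, tmp_path):
        cfg = tmp_path / "rules.json"
        cfg.write_text('{"_refine_ls_r_factor_gt": [0.0, 0.5]}')
        rules = load_rules(cfg)
        assert not apply_validity(cur.TAG_R, parse_value("0.6"), rules)[0]
        assert apply_validity(cur.TAG_R, parse_value("0.4"), rules)[0]
        # untouched tags keep defaults
        assert rules[cur.TAG_THETA] == DEFAULT_RULES[cur.TAG_THETA]

    def test_rule_requires_ordered_interval(self):
        with pytest.raises(ValueError):
            ValidityRule("_x", 1.0, 1.0)


def _raw(ident, **tag_values):
    values = {t: ABSENT for t in cur.TAGS}
    values.update(tag_values)
    return RawItemSet(identifier=ident, values=values)


class TestAuditCorpus:
    def test_completeness_90_percent(self):
        sets = [_raw(f"e{i}", **{cur.TAG_R: "0.05"}) for i in range(9)]
        sets.append(_raw("e9", **{cur.TAG_R: "?"}))
        result, _ = audit_corpus(sets)
        assert result.completeness_percent(cur.TAG_R) == pytest.approx(90.0)

    def test_bounded_shift_counts_non_numeric(self):
        result, recs = audit_corpus([_raw("e0", **{cur.TAG_SHIFT: "<0.01"})])
        t = result.tallies[cur.TAG_SHIFT]
        assert t.non_numeric == 1 and t.accepted == 0
        assert recs[0].shift_su is None
        assert recs[0].states[cur.TAG_SHIFT] == "bounded-unreadable"

    def test_generator_quota_is_oracle(self, small_audit, small_spec):
        _, result, _, _ = small_audit
        t = result.tallies[cur.TAG_GOOF]
        q = small_spec.quotas[cur.TAG_GOOF]
        assert t.non_numeric == q["malformed"]
        assert t.missing == q["missing"]
        assert t.out_of_range == q["out_of_range"]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            audit_corpus([])

    def test_accounting_identity_on_synthetic(self, small_audit):
        _, result, _, _ = small_audit
        for t in result.tallies.values():
            assert t.numeric + t.missing + t.non_numeric == t.total
            assert t.out_of_range <= t.numeric
            assert t.accepted == t.numeric - t.out_of_range

    def test_brute_force_recount_oracle(self, small_corpus):
        """Tallies equal a direct per-entry recount on the raw texts."""
        from cifaudit.cif_io import extract_items, read_cif_text

        files, _ = small_corpus
        entries = [read_cif_text(text, name) for name, text in files]
        raw = [extract_items(e, cur.TAGS) for e in entries]
        result, _ = audit_corpus(raw)
        for tag in cur.METRIC_TAGS:
            counts = {"numeric": 0, "missing": 0, "bounded": 0, "malformed": 0,
                      "oor": 0}
            rule = DEFAULT_RULES[tag]
            for rs in raw:
                pv = parse_value(rs.values[tag])
                counts[pv.status] += 1
                if pv.status == "numeric" and not (rule.lower < pv.value < rule.upper):
                    counts["oor"] += 1
            t = result.tallies[tag]
            assert (t.numeric, t.missing, t.bounded, t.malformed, t.out_of_range) == (
                counts["numeric"], counts["missing"], counts["bounded"],
                counts["malformed"], counts["oor"],
            )

    def test_idempotence_of_accepted_values(self, small_audit):
        """Re-auditing the accepted values accepts all of them unchanged."""
        _, _, records, _ = small_audit
        for tag in cur.METRIC_TAGS:
            field = cur.MetricRecord._FIELD_BY_TAG[tag]
            sets = [
                _raw(r.identifier, **{tag: repr(getattr(r, field))})
                for r in records
                if getattr(r, field) is not None
            ]
            result, again = audit_corpus(sets)
            t = result.tallies[tag]
            assert t.accepted == t.total == len(sets)
            for orig, new in zip(
                [getattr(r, field) for r in records if getattr(r, field) is not None],
                [getattr(r, field) for r in again],
            ):
                assert new == pytest.approx(orig)

    def test_zmax_attached_from_atom_sites(self, small_audit):
        _, _, records, gt = small_audit
        z = {row.identifier: row.z_max for row in gt.itertuples()}
        for rec in records:
            assert rec.z_max == z[rec.identifier]

    def test_count_tags_extracted(self, small_audit):
        _, _, records, _ = small_audit
        assert all(isinstance(r.n_parameters, int) for r in records)
        assert all(r.n_restraints is not None for r in records)

    def test_export_roundtrip(self, small_audit, tmp_path):
        _, result, _, _ = small_audit
        result.to_csv(tmp_path / "tallies.csv")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "tallies.csv")
        assert set(df["tag"]) == set(cur.METRIC_TAGS)
        payload = json.loads(result.to_json())
        assert len(payload) == len(cur.METRIC_TAGS)


@given(
    st.lists(
        st.one_of(
            st.just(ABSENT),
            st.sampled_from(["?", ".", "<0.01", "junk", "0.05", "1.5", "-0.2",
                             "0.046(2)", "", "1.2.3"]),
        ),
        min_size=1,
        max_size=60,
    )
)
def test_accounting_identity_property(raws):
    sets = [
        RawItemSet(identifier=f"e{i}", values={cur.TAG_R: r})
        for i, r in enumerate(raws)
    ]
    result, _ = audit_corpus(sets)
    t = result.tallies[cur.TAG_R]
    assert t.numeric + t.missing + t.non_numeric == t.total == len(raws)
    assert t.out_of_range <= t.numeric
    assert t.accepted == t.numeric - t.out_of_range
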