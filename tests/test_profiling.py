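"""Classification against a monoclonal reference and aggregate error statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import cdr3_only_model, truth_cdr3_errors
from cdr3err.extract import CDR3Record
from cdr3err.profiling import (
    SubstitutionMatrix,
    classify,
    lane_anova,
    lane_cv,
    per_nt_substitution_rates,
    substitution_matrix,
    summarize,
)
from cdr3err.sequtil import NT_INDEX
from cdr3err.simulate import ErrorModel, simulate_reads
from cdr3err.extract import extract_all


def _rec(seq, q=40, lane=1, sample="s1", orientation="forward", read_id="r"):
    return CDR3Record(read_id, seq, np.full(len(seq), q, dtype=np.int16), orientation, lane, sample)


def _brute_force_subs(ref, seq):
    return tuple((i, ref[i], seq[i]) for i in range(len(ref)) if ref[i] != seq[i])


class TestClassify:
    def test_identity_is_correct(self):
        assert classify("ACGACG", "ACGACG").category == "correct"
        assert classify("ACGACG", "ACGACG").n_subs == 0

    @pytest.mark.parametrize("positions", [(4,), (4, 17), (0, 1, 35)])
    def test_substitutions_found_at_exact_positions(self, template36, positions):
        ref = template36.cdr3
        seq = list(ref)
        for p in positions:
            seq[p] = "A" if ref[p] != "A" else "C"
        seq = "".join(seq)
        cl = classify(seq, ref)
        assert cl.category == "substitution"
        assert cl.n_subs == len(positions)
        assert cl.sub_list == _brute_force_subs(ref, seq)

    def test_length_classes(self, template36):
        ref = template36.cdr3
        assert classify(ref[:-3], ref).category == "truncated"
        assert classify(ref + "GCC", ref).category == "elongated"
        assert classify("", ref).category == "truncated"
        assert classify("", ref).n_subs is None

    def test_matches_simulator_truth_for_indel_free_reads(self, noisy_mono_run):
        """On simulated reads the classifier must reproduce the injected error
        lists exactly (the ground truth is the independent oracle)."""
        template = noisy_mono_run["template"]
        truth = noisy_mono_run["truth"].set_index("read_id")
        checked_subs = checked_indels = 0
        for rec in noisy_mono_run["records"]:
            row = truth.loc[rec.read_id]
            cl = classify(rec, template.cdr3)
            if row["indels"]:
                assert cl.category == ("truncated" if row["indels"].startswith("del") else "elongated")
                checked_indels += 1
                continue
            expected = truth_cdr3_errors(row["errors"], template)
            assert list(cl.sub_list) == expected
            assert cl.n_subs == len(expected)
            checked_subs += 1
        assert checked_subs > 1000 and checked_indels > 3


class TestSummarize:
    def test_all_correct_input_is_error_free_at_every_cutoff(self, template36):
        records = [_rec(template36.cdr3) for _ in range(10)]
        out = summarize(records, template36.cdr3)
        assert all(s.error_percent == 0.0 for s in out.values())
        assert all(s.n_unique_error == 0 for s in out.values())

    def test_quality_separated_errors_vanish_at_q30(self, template36):
        ref = template36.cdr3
        bad = ref[:5] + ("A" if ref[5] != "A" else "C") + ref[6:]
        records = [_rec(ref, q=35) for _ in range(8)] + [_rec(bad, q=12) for _ in range(2)]
        out = summarize(records, ref, (0, 30))
        assert out[0].error_percent == pytest.approx(20.0)
        assert out[30].error_percent == 0.0
        assert out[30].pct_error_excluded == pytest.approx(100.0)

    def test_error_percent_matches_closed_form(self, template36, flanks36):
        """With uniform per-position error probability e over the CDR3 the
        expected error fraction is 1-(1-e)^L (binomial complement oracle)."""
        rate = 1e-3
        model = cdr3_only_model(template36, rate)
        reads, _ = simulate_reads(template36, model, 20_000, seed=31)
        records, _ = extract_all(reads, flanks36)
        out = summarize(records, template36.cdr3, (0,))
        e_pos = 3 * rate
        expected = 100 * (1 - (1 - e_pos) ** 36)
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / len(records))
        assert abs(out[0].error_percent - expected) <= 3 * se

    def test_spectrum_fractions_sum_to_one(self, noisy_mono_run):
        out = summarize(noisy_mono_run["records"], noisy_mono_run["template"].cdr3, (0,))
        spectrum = out[0].spectrum
        assert spectrum and abs(sum(spectrum.values()) - 1.0) < 1e-9
        assert out[0].multi_error_freq[1] < 1.0

    def test_unique_errors_pooled_and_per_sample(self, template36):
        ref = template36.cdr3
        bad1 = "A" + ref[1:] if ref[0] != "A" else "C" + ref[1:]
        bad2 = ref[:-1] + ("A" if ref[-1] != "A" else "C")
        records = [
            _rec(ref, sample="s1"),
            _rec(bad1, sample="s1"),
            _rec(bad1, sample="s2"),
            _rec(bad2, sample="s2"),
        ]
        out = summarize(records, ref, (0,))[0]
        assert out.n_unique_error == 2  # pooled uniqueness by nt string
        assert out.unique_error_by_sample == {"s1": 1, "s2": 2}


class TestSubstitutionMatrix:
    def test_single_event_rate(self, template36):
        ref = template36.cdr3
        alt = "A" if ref[0] != "A" else "C"
        records = [_rec(alt + ref[1:])] + [_rec(ref) for _ in range(9)]
        sm = substitution_matrix(records, ref, by=())
        assert sm.rate(0, alt) == pytest.approx(0.1)
        assert sm.total_substitution_events() == 1
        assert (sm.data["denominator"] == 10).all()

    def test_counts_conserve_substitution_events(self, noisy_mono_run):
        template = noisy_mono_run["template"]
        records = noisy_mono_run["records"]
        sm = substitution_matrix(records, template.cdr3, by=("lane", "direction"))
        n_subs = sum(
            cl.n_subs
            for cl in (classify(r, template.cdr3) for r in records)
            if cl.category == "substitution"
        )
        assert sm.total_substitution_events() == n_subs

    def test_boosted_cell_is_argmax(self, template36, flanks36):
        pos, alt_nt = 7, None
        ref = template36.cdr3
        alt_nt = "A" if ref[pos] != "A" else "C"
        m = np.full((len(template36), 4), 1e-4)
        m[template36.cdr3_start + pos, NT_INDEX[alt_nt]] = 4e-3
        reads, truth = simulate_reads(template36, ErrorModel(sub_rate=m), 30_000, seed=33)
        records, _ = extract_all(reads, flanks36)
        sm = substitution_matrix(records, ref, by=())
        assert sm.argmax() == (pos, ref[pos], alt_nt)
        # cross-check against the simulator's own truth tally
        token = f"{template36.cdr3_start + pos}:{ref[pos]}>{alt_nt}"
        truth_hits = truth["errors"].str.contains(token, regex=False).sum()
        assert truth_hits > 50


class TestPerNtRates:
    def test_absent_origin_base_flagged_undefined(self):
        ref = "AACCTTAACCTT"  # no G
        records = [_rec(ref) for _ in range(5)]
        sm = substitution_matrix(records, ref, by=("direction",))
        rates = per_nt_substitution_rates(sm)
        g_rows = rates[rates["from_nt"] == "G"]
        assert (~g_rows["defined"]).all()
        assert g_rows["rate"].isna().all()

    def test_transition_boosted_model_yields_transition_dominance(self, template36, flanks36):
        from cdr3err.simulate import transition_enriched

        m = np.full((len(template36), 4), 1e-4)
        m = transition_enriched(m, template36.sequence, boost=20.0, cap=2.5e-3)
        reads, _ = simulate_reads(template36, ErrorModel(sub_rate=m), 40_000, seed=34)
        records, _ = extract_all(reads, flanks36)
        sm = substitution_matrix(records, template36.cdr3, by=("direction",))
        rates = per_nt_substitution_rates(sm)
        pooled = rates.groupby(["from_nt", "to_nt"])["rate"].mean().sort_values(ascending=False)
        top4 = set(pooled.index[:4])
        assert top4 == {("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")}


def _matrix_from_rates(rates_by_lane_sample, position=0, from_nt="A", to_nt="C"):
    """Hand-built SubstitutionMatrix with given per-(lane, sample) rates for one cell."""
    rows = []
    for (lane, sample), rate in rates_by_lane_sample.items():
        rows.append((lane, sample, position, from_nt, to_nt, int(rate * 1000), 1000, rate))
    df = pd.DataFrame(
        rows,
        columns=["lane", "sample_path", "position", "from_nt", "to_nt", "count", "denominator", "rate"],
    )
    return SubstitutionMatrix(reference="A", by=("lane", "sample_path"), data=df)


class TestLaneCV:
    def test_identical_rates_give_zero_cv(self):
        sm = _matrix_from_rates({(1, "a"): 0.1, (1, "b"): 0.1, (2, "a"): 0.1, (2, "b"): 0.1})
        out = lane_cv(sm)
        assert out.lane_cv_mean == pytest.approx(0.0)

    def test_two_sample_cv_hand_value(self):
        # rates r and 3r: sd = sqrt(2) r, mean = 2r, CV = 0.7071 (sample sd)
        sm = _matrix_from_rates({(1, "a"): 0.1, (1, "b"): 0.3})
        out = lane_cv(sm)
        assert out.lane_cv_mean == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_lane_segregated_cv_below_pooled_when_lanes_differ(self):
        sm = _matrix_from_rates(
            {(1, "a"): 0.10, (1, "b"): 0.11, (2, "a"): 0.30, (2, "b"): 0.33}
        )
        out = lane_cv(sm)
        assert out.lane_cv_mean < out.pooled_cv_mean

    def test_zero_mean_cells_excluded_and_counted(self):
        sm = _matrix_from_rates({(1, "a"): 0.0, (1, "b"): 0.0})
        out = lane_cv(sm)
        assert np.isnan(out.lane_cv_mean)
        assert out.n_undefined_lane == 1


class TestLaneAnova:
    @staticmethod
    def _hand_f(groups):
        """Textbook one-way fixed-effects ANOVA, as the independent oracle."""
        all_values = [x for g in groups for x in g]
        grand = sum(all_values) / len(all_values)
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
        df_b = len(groups) - 1
        df_w = len(all_values) - len(groups)
        return (ssb / df_b) / (ssw / df_w)

    def test_matches_hand_computed_f_statistic(self):
        groups = [(0.1, 0.2, 0.3), (0.2, 0.3, 0.4), (0.3, 0.4, 0.5)]
        rates = {}
        for lane, g in enumerate(groups, start=1):
            for i, r in enumerate(g):
                rates[(lane, f"s{i}")] = r
        out = lane_anova(_matrix_from_rates(rates))
        assert out.table["F"].iloc[0] == pytest.approx(self._hand_f(groups))
        assert out.table["F"].iloc[0] == pytest.approx(3.0)

    def test_constant_rates_give_p_one(self):
        rates = {(lane, s): 0.2 for lane in (1, 2) for s in ("a", "b")}
        out = lane_anova(_matrix_from_rates(rates))
        assert out.table["p"].iloc[0] == 1.0
        assert out.fraction_significant == 0.0

    def test_type_one_error_calibrated_without_lane_effect(self, template36, flanks36):
        """With no injected lane effect, about 5% of cells reach p < 0.05."""
        from cdr3err.simulate import preset_study_design

        model = cdr3_only_model(template36, 2e-3)
        reads, _ = simulate_reads(
            template36, model, 27_000, seed=35, design=preset_study_design(35)
        )
        records, _ = extract_all(reads, flanks36)
        sm = substitution_matrix(records, template36.cdr3, by=("lane", "sample_path"))
        out = lane_anova(sm)
        assert 0.005 < out.fraction_significant < 0.15
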