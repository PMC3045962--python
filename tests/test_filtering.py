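"""Clone tables, Hamming-1 neighbor search, mismatch culling, direction skew."""

import numpy as np
import pandas as pd
import pytest

from cdr3err.extract import CDR3Record
from cdr3err.filtering import (
    CloneTable,
    build_clone_table,
    cull_monoclonal,
    cull_polyclonal,
    direction_skew_screen,
    hamming1_pairs,
    single_mismatch_neighbors,
)
from cdr3err.simulate import ErrorModel, random_polyclonal_templates, simulate_reads
from cdr3err.extract import FlankSpec, extract_all


def _rec(seq, orientation="forward", lane=1, read_id="r"):
    return CDR3Record(read_id, seq, np.full(len(seq), 40, dtype=np.int16), orientation, lane, "s1")


def _table(counts: dict[str, int]) -> CloneTable:
    rows = {
        "cdr3_nt": list(counts),
        "total_count": list(counts.values()),
        "forward_count": [c // 2 for c in counts.values()],
        "reverse_count": [c - c // 2 for c in counts.values()],
    }
    return CloneTable(pd.DataFrame(rows))


class TestBuildCloneTable:
    def test_direction_and_lane_counts(self):
        records = [
            _rec("AAA", "forward", 1),
            _rec("AAA", "forward", 2),
            _rec("AAA", "reverse", 1),
        ]
        table = build_clone_table(records)
        row = table.df.iloc[0]
        assert (row["total_count"], row["forward_count"], row["reverse_count"]) == (3, 2, 1)
        assert (row["lane_1"], row["lane_2"]) == (2, 1)

    def test_empty_input(self):
        table = build_clone_table([])
        assert len(table) == 0
        assert table.total_reads == 0

    def test_totals_match_simulator_truth(self, flanks36):
        templates = random_polyclonal_templates(5, seed=40)
        reads, truth = simulate_reads(
            templates, ErrorModel(), 3000, seed=41, abundances=[0.4, 0.3, 0.15, 0.1, 0.05]
        )
        records, _ = extract_all(reads, FlankSpec.from_template(templates[0]))
        table = build_clone_table(records)
        by_template = truth.groupby("template").size()
        for t in templates:
            assert table.count(t.cdr3) == by_template[t.name]


def _brute_force_neighbors(counts):
    seqs = list(counts)
    out = {s: [] for s in seqs}
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1:
                if counts[a] > counts[b]:
                    out[a].append(b)
                elif counts[b] > counts[a]:
                    out[b].append(a)
    return {s: sorted(v) for s, v in out.items()}


class TestNeighborSearch:
    def test_worked_example(self):
        table = _table({"AAA": 10, "AAT": 2, "TTT": 5})
        nbrs = single_mismatch_neighbors(table)
        assert nbrs["AAA"] == ["AAT"]
        assert nbrs["TTT"] == []
        assert nbrs["AAT"] == []

    def test_different_lengths_never_neighbors(self):
        table = _table({"AAAA": 10, "AAA": 1})
        nbrs = single_mismatch_neighbors(table)
        assert nbrs["AAAA"] == [] and nbrs["AAA"] == []

    def test_equal_counts_mutually_non_neighbors(self):
        table = _table({"AAA": 5, "AAC": 5})
        nbrs = single_mismatch_neighbors(table)
        assert nbrs["AAA"] == [] and nbrs["AAC"] == []

    def test_indexed_search_equals_all_pairs_scan(self):
        rng = np.random.default_rng(42)
        seqs = {
            "".join(rng.choice(list("ACGT"), size=8)): int(rng.integers(1, 50))
            for _ in range(900)
        }
        table = _table(seqs)
        counts = table.counts
        assert single_mismatch_neighbors(table) == _brute_force_neighbors(counts)

    def test_pairs_unique(self):
        seqs = ["AAA", "AAC", "ACA", "CAA", "AAG"]
        pairs = list(hamming1_pairs(seqs))
        assert len(pairs) == len(set(tuple(sorted(p)) for p in pairs))


class TestCullMonoclonal:
    def test_cutoff_zero_removes_nothing(self):
        table = _table({"AAA": 100, "AAT": 1})
        report = cull_monoclonal(table, "AAA", 0.0)
        assert len(report.culled) == 0
        assert len(report.kept) == 2

    def test_cutoff_one_removes_all_distance1_at_or_below_index(self):
        table = _table({"AAA": 10, "AAT": 10, "ATA": 11, "TAA": 3, "TTT": 1})
        report = cull_monoclonal(table, "AAA", 1.0)
        # equal count removed (inclusive <=); higher count kept; distance>1 kept
        assert set(report.culled["sequence"]) == {"AAT", "TAA"}

    def test_hand_worked_residual(self, template36):
        ref = template36.cdr3
        d1 = "A" + ref[1:] if ref[0] != "A" else "C" + ref[1:]
        d2 = list(ref)
        d2[3] = "A" if ref[3] != "A" else "C"
        d2[7] = "A" if ref[7] != "A" else "C"
        d2 = "".join(d2)
        table = _table({ref: 1000, d1: 5, d2: 3})
        report = cull_monoclonal(table, ref, 0.01)
        assert report.culled["sequence"].tolist() == [d1]  # 5 <= 10
        assert report.residual_error_fraction == pytest.approx(3 / 1003)

    def test_never_removes_true_sequence(self):
        table = _table({"AAA": 2, "AAT": 2})
        report = cull_monoclonal(table, "AAA", 1.0)
        assert "AAA" in report.kept

    def test_residual_monotone_in_cutoff(self, noisy_mono_run):
        table = build_clone_table(noisy_mono_run["records"])
        ref = noisy_mono_run["template"].cdr3
        residuals = [
            cull_monoclonal(table, ref, c).residual_error_fraction
            for c in (0.0, 1e-4, 1e-3, 1e-2, 0.1, 1.0)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(residuals, residuals[1:]))

    def test_absent_true_sequence_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            cull_monoclonal(_table({"AAA": 1}), "CCC", 0.5)


class TestCullPolyclonal:
    def test_single_clone_table_has_zero_tallies(self):
        report = cull_polyclonal(_table({"AAA": 100}))
        assert all(v == 0 for v in report.per_cutoff_totals.values())
        assert report.global_tally == 0
        assert report.top_k_used == 1

    def test_tally_monotone_in_cutoff(self, noisy_mono_run):
        table = build_clone_table(noisy_mono_run["records"])
        report = cull_polyclonal(table, cutoffs=(0.001, 0.003, 0.01, 0.03))
        totals = [report.per_cutoff_totals[c] for c in (0.001, 0.003, 0.01, 0.03)]
        assert totals == sorted(totals)

    def test_single_assignment_no_double_counting(self):
        # B (count 1) is a distance-1 neighbor of both A and C indexes;
        # it must be attributed to only one of them
        table = _table({"AAA": 100, "CAA": 90, "AAC": 1})
        # AAC is d1 of AAA only; craft a shared neighbor instead:
        table = _table({"AAA": 100, "AAG": 90, "AAT": 1})
        report = cull_polyclonal(table, cutoffs=(0.05,), top_k=2)
        assert report.per_cutoff_totals[0.05] == 1

    def test_strict_inequality_against_cutoff(self):
        # count 1 vs index 100 at cutoff 0.01: 1 < 1.0 is false -> not tallied
        table = _table({"AAA": 100, "AAT": 1})
        report = cull_polyclonal(table, cutoffs=(0.01, 0.011), top_k=1)
        assert report.per_cutoff_totals[0.01] == 0
        assert report.per_cutoff_totals[0.011] == 1

    def test_global_tally_counts_all_ordered_pairs(self):
        table = _table({"AAA": 10, "AAT": 5, "AAG": 5, "TTT": 1})
        # AAA>AAT, AAA>AAG (AAT/AAG equal counts -> no edge; TTT far)
        report = cull_polyclonal(table)
        assert report.global_tally == 2


class TestDirectionSkewScreen:
    def test_extreme_forward_bias_flagged_outside(self):
        df = pd.DataFrame(
            {
                "cdr3_nt": ["AAA", "CCC"],
                "total_count": [1000, 50],
                "forward_count": [500, 50],
                "reverse_count": [500, 0],
            }
        )
        result = direction_skew_screen(CloneTable(df), min_reads=20)
        row = result.table.set_index("cdr3_nt").loc["CCC"]
        assert not row["within"]

    def test_expected_count_within(self):
        df = pd.DataFrame(
            {
                "cdr3_nt": ["AAA", "CCC"],
                "total_count": [1000, 100],
                "forward_count": [520, 52],
                "reverse_count": [480, 48],
            }
        )
        result = direction_skew_screen(CloneTable(df), p_fwd=0.52, min_reads=20)
        assert result.table["within"].all()

    def test_small_counts_not_assessed(self):
        df = pd.DataFrame(
            {
                "cdr3_nt": ["AAA", "CCC"],
                "total_count": [100, 5],
                "forward_count": [50, 5],
                "reverse_count": [50, 0],
            }
        )
        result = direction_skew_screen(CloneTable(df), min_reads=20)
        assert result.table["cdr3_nt"].tolist() == ["AAA"]

    def test_coverage_of_direction_neutral_clones(self):
        """~98% of direction-neutral clonotypes fall within the boundaries."""
        rng = np.random.default_rng(55)
        n_clones, reads_each, p = 600, 100, 0.5
        fwd = rng.binomial(reads_each, p, size=n_clones)
        df = pd.DataFrame(
            {
                "cdr3_nt": [f"{'ACGT'[i % 4] * 4}{i:04d}".replace("0", "A").replace("1", "C").replace("2", "G").replace("3", "T").replace("4", "A").replace("5", "C").replace("6", "G").replace("7", "T").replace("8", "A").replace("9", "C") for i in range(n_clones)],
                "total_count": reads_each,
                "forward_count": fwd,
                "reverse_count": reads_each - fwd,
            }
        )
        result = direction_skew_screen(CloneTable(df), p_fwd=p, min_reads=20)
        assert result.fraction_within >= 0.96

    def test_invalid_p_fwd_rejected(self):
        with pytest.raises(ValueError):
            direction_skew_screen(_table({"AAAA": 100}), p_fwd=1.0)
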