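"""Formula kernels against counting oracles; matrix composition; clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import methmark as mm
from methmark.features import (
    cluster_signatures,
    correlate_features,
    cpg_oe,
    feature_matrix,
    gc_content,
    log2_fold_change,
    rpkm_signal,
)
from methmark.synthetic import MarkReads

dna = st.text(alphabet="ACGT", min_size=2, max_size=60)


class TestSequenceKernels:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 0.0), ("GCGC", 1.0), ("ACGT", 0.5)]
    )
    def test_gc_examples(self, seq, expected):
        assert gc_content(seq) == expected

    @pytest.mark.parametrize(
        "seq,expected",
        [("CGCGCG", 2.0), ("AAAA", 0.0), ("CATG", 0.0)],
    )
    def test_cpg_oe_examples(self, seq, expected):
        # CGCGCG: 3 CpG * 6 / (3 C * 3 G) = 2; degenerate cases return 0
        assert cpg_oe(seq) == pytest.approx(expected)

    @given(dna)
    def test_gc_matches_counting_oracle(self, seq):
        assert gc_content(seq) == (seq.count("C") + seq.count("G")) / len(seq)

    @given(dna)
    def test_cpg_oe_matches_counting_oracle(self, seq):
        n_c, n_g, n_cpg = seq.count("C"), seq.count("G"), seq.count("CG")
        expected = 0.0 if n_c * n_g == 0 else n_cpg * len(seq) / (n_c * n_g)
        assert cpg_oe(seq) == pytest.approx(expected)


class TestRPKM:
    def test_zero_reads_floor_is_one_over_length(self):
        for n in (10**5, 10**7, 10**9):
            assert rpkm_signal(0, 1000, n) == pytest.approx(0.001)

    def test_textbook_value(self):
        # 1000 reads over 1 kb in a 10M-read library -> ~100 RPKM
        assert rpkm_signal(1000, 1000, 10**7) == pytest.approx(100.0, rel=1e-4)

    def test_linearity_far_from_floor(self):
        a = rpkm_signal(500, 2000, 10**6)
        b = rpkm_signal(1000, 2000, 10**6)
        assert b / a == pytest.approx(2.0, rel=1e-3)

    def test_scale_consistency(self):
        # multiplying Reads and N by c leaves rpkm unchanged (p scales with N)
        assert rpkm_signal(50, 1000, 10**6) == pytest.approx(rpkm_signal(500, 1000, 10**7))

    def test_fixed_pseudocount_mode(self):
        assert rpkm_signal(0, 1000, 10**6, "fixed:1") == pytest.approx(1e9 / (10**6 * 1000))

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm_signal(0, 1000, 0)

    @given(st.integers(0, 10**5), st.integers(1, 10**5), st.integers(1, 10**9))
    def test_matches_direct_formula(self, reads, length, n):
        expected = (reads + n / 1e9) * 1e9 / (n * length)
        assert rpkm_signal(reads, length, n) == pytest.approx(expected)


class TestFoldChange:
    def test_equal_signals_zero(self):
        assert log2_fold_change(3.7, 3.7) == 0.0

    def test_quadrupling_gives_two(self):
        assert log2_fold_change(1.0, 4.0) == pytest.approx(2.0)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))


def track(chrom_starts, n_total=None):
    starts = {c: np.sort(np.asarray(s, dtype=np.int64)) for c, s in chrom_starts.items()}
    n = n_total or sum(len(s) for s in starts.values())
    return MarkReads("X", starts, 36, max(n, 1))


class TestFeatureMatrix:
    def test_no_reads_rpkm_at_floor(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        seqs = {"chr1": "ACGT" * 500}
        fm = feature_matrix(regions, seqs, {"X": track({"chr1": []}, n_total=10**6)})
        assert fm["X"].iloc[0] == pytest.approx(1 / 1000)

    def test_single_region_equals_direct_calls(self):
        seqs = {"chr1": "ACGTTTGCCGCG" * 100}
        tr = track({"chr1": [100, 150, 700]})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [650]})
        fm = feature_matrix(regions, seqs, {"X": tr})
        sub = seqs["chr1"][50:650]
        assert fm["gc_content"].iloc[0] == gc_content(sub)
        assert fm["cpg_oe"].iloc[0] == cpg_oe(sub)
        assert fm["X"].iloc[0] == rpkm_signal(2, 600, tr.n_total)

    def test_read_counted_by_start_position(self):
        tr = track({"chr1": [99, 100, 499, 500]})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [500]})
        fm = feature_matrix(regions, {"chr1": "A" * 1000}, {"X": tr})
        # starts 100 and 499 are inside [100, 500); 99 and 500 are not
        assert fm["X"].iloc[0] == rpkm_signal(2, 400, tr.n_total)

    def test_concatenation_consistency(self):
        rng = np.random.default_rng(0)
        seqs = {"chr1": "".join(rng.choice(list("ACGT"), size=5000))}
        tr = track({"chr1": rng.integers(0, 5000, size=200)})
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000, 3000], "end": [800, 2500, 4000]}
        )
        whole = feature_matrix(regions, seqs, {"X": tr})
        parts = pd.concat(
            [feature_matrix(regions.iloc[[i]], seqs, {"X": tr}) for i in range(3)],
            ignore_index=True,
        )
        pd.testing.assert_frame_equal(whole, parts)

    def test_missing_chrom_reported(self):
        regions = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [10]})
        with pytest.raises(KeyError, match="chrZ"):
            feature_matrix(regions, {"chr1": "ACGT"}, {})


class TestCorrelation:
    def test_perfect_and_inverse_correlation(self):
        rng = np.random.default_rng(1)
        level = rng.random(50)
        m = pd.DataFrame({"same": level, "neg": -level, "flat": np.ones(50)})
        out = correlate_features(m, level, ["same", "neg", "flat"]).set_index("feature")
        assert out.loc["same", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["neg", "pearson_r"] == pytest.approx(-1.0)
        assert not out.loc["flat", "defined"]
        assert np.isnan(out.loc["flat", "pearson_r"])

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            correlate_features(pd.DataFrame({"x": [1, 2]}), [0.1, 0.2], ["x"])

    def test_active_mark_anticorrelated_with_methylation(self, default_bundle):
        fm = default_bundle["features"]
        out = correlate_features(fm, fm["mean_level"], ["H3K4me2"]).set_index("feature")
        assert out.loc["H3K4me2", "pearson_r"] < 0


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]], index=["a", "b", "c"])
        link, _ = cluster_signatures(m)
        assert link[0, 2] == 0.0
        assert sorted(link[0, :2]) == [0, 1]

    def test_nearest_rows_merge_first(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.1], [5.0, 5.0]], index=["a", "b", "c"])
        link, labels = cluster_signatures(m)
        assert sorted(link[0, :2]) == [0, 1]  # a and b join before c
        assert link[0, 2] == pytest.approx(0.1)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_signatures(pd.DataFrame([[1.0, 2.0]]))

    def test_u_signatures_cocluster(self, default_bundle):
        from methmark.features import mean_signal_matrix

        fm = default_bundle["features"]
        cfg = default_bundle["config"]
        sig = mean_signal_matrix(fm, cfg.mark_names, ["pattern", "category"])
        link, labels = cluster_signatures(sig)
        patterns = [lab[0] for lab in labels]
        # leaf order separates U rows from M rows into two blocks
        switches = sum(a != b for a, b in zip(patterns, patterns[1:]))
        assert switches == 1
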