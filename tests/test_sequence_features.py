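"""k-mer featurization, RF-importance selection, Welch screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncprior.io_formats import LabelSet
from lncprior.sequence_features import (
    KmerConfig,
    count_kmer_frequencies,
    kmer_names,
    rank_kmers_by_rf_importance,
    select_top_kmers,
    welch_ttest_kmers,
)

from conftest import fast_cv

# frozen Welch oracle for {0.10,0.12,0.11} vs {0.20,0.22,0.21}, computed by
# direct substitution into the Welch statistic and Welch-Satterthwaite df
WELCH_T = -12.247448713915896
WELCH_DF = 4.0
WELCH_P = 0.0002552167494419263


class TestCounting:
    def test_overlapping_count_normalized_by_length(self):
        table = count_kmer_frequencies({"g": "AAAA"}, ks=(3,))
        assert table.loc["g", "AAA"] == 0.5
        assert table.drop(columns="AAA").loc["g"].sum() == 0.0

    def test_full_feature_space_for_3_and_4_mers(self):
        table = count_kmer_frequencies({"g": "ACGTACGTACGT"}, ks=(3, 4))
        assert table.shape[1] == 320
        assert list(table.columns) == kmer_names((3, 4))

    def test_per_k_frequency_sum_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        table = count_kmer_frequencies({"g": seq}, ks=(3, 4))
        assert table.loc["g", [c for c in table.columns if len(c) == 3]].sum() == pytest.approx(998 / 1000, abs=1e-12)
        assert table.loc["g", [c for c in table.columns if len(c) == 4]].sum() == pytest.approx(997 / 1000, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=200), st.sampled_from([1, 2, 3]))
    def test_sum_identity_property(self, seq, k):
        table = count_kmer_frequencies({"g": seq}, ks=(k,))
        assert table.loc["g"].sum() == pytest.approx((len(seq) - k + 1) / len(seq), abs=1e-12)

    def test_n_windows_skipped_but_length_kept(self):
        table = count_kmer_frequencies({"g": "AANAA"}, ks=(2,))
        # windows: AA, AN, NA, AA -> only the two AA windows count; L = 5
        assert table.loc["g", "AA"] == pytest.approx(2 / 5)
        assert table.loc["g"].sum() == pytest.approx(2 / 5)

    def test_too_short_sequence_excluded(self, caplog):
        table = count_kmer_frequencies({"long": "ACGTACGT", "short": "ACG"}, ks=(4,))
        assert list(table.index) == ["long"]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KmerConfig(ks=(5,))
        with pytest.raises(ValueError):
            KmerConfig(top_m=400)


@pytest.fixture(scope="module")
def ranked_strong(strong_bundle):
    table = count_kmer_frequencies(strong_bundle.transcripts, ks=(3, 4))
    ranked = rank_kmers_by_rf_importance(table, strong_bundle.labels,
                                         repetitions=10, seed=11)
    return table, ranked


class TestImportanceRanking:
    def test_planted_kmers_recovered_in_top_ranks(self, strong_bundle, ranked_strong):
        # the 5 planted 4-mers must lead the ranking; their substring
        # 3-mers (also genuinely enriched) may interleave, so check the
        # top 10 and that the very top is a planted k-mer
        _, ranked = ranked_strong
        top10 = {kmer for kmer, _ in ranked[:10]}
        assert set(strong_bundle.config.informative_kmers) <= top10
        assert ranked[0][0] in strong_bundle.config.informative_kmers

    def test_importances_average_to_one(self, ranked_strong):
        _, ranked = ranked_strong
        assert len(ranked) == 320
        assert sum(imp for _, imp in ranked) == pytest.approx(1.0, abs=1e-6)

    def test_ordering_invariant_to_column_permutation(self, strong_bundle):
        table = count_kmer_frequencies(
            dict(list(strong_bundle.transcripts.items())[:200]), ks=(3,)
        )
        labels = LabelSet(
            positives=strong_bundle.labels.positives & set(table.index),
            negatives=strong_bundle.labels.negatives & set(table.index),
        )
        rng = np.random.default_rng(1)
        shuffled = table[table.columns[rng.permutation(table.shape[1])]]
        a = rank_kmers_by_rf_importance(table, labels, repetitions=2, seed=5)
        b = rank_kmers_by_rf_importance(shuffled, labels, repetitions=2, seed=5)
        assert [k for k, _ in a] == [k for k, _ in b]

    def test_permuted_labels_leave_planted_kmer_unremarkable(self, strong_bundle, ranked_strong):
        table, _ = ranked_strong
        rng = np.random.default_rng(2)
        labeled = sorted(strong_bundle.labels.labeled)
        perm = list(rng.permutation(labeled))
        permuted = LabelSet(positives=frozenset(perm[:150]),
                            negatives=frozenset(perm[150:]))
        ranked = rank_kmers_by_rf_importance(table, permuted, repetitions=3, seed=6)
        importances = dict(ranked)
        median = float(np.median(list(importances.values())))
        for kmer in strong_bundle.config.informative_kmers:
            assert importances[kmer] < 3 * median

    def test_labeled_genes_missing_from_table_rejected(self, ranked_strong):
        table, _ = ranked_strong
        with pytest.raises(ValueError, match="missing"):
            rank_kmers_by_rf_importance(
                table,
                LabelSet(positives={"ghost"}, negatives=set(table.index[:2])),
                repetitions=1, seed=0,
            )


class TestTopKmerSelection:
    def test_grid_of_one_returns_single_top_column(self, strong_bundle, ranked_strong):
        table, ranked = ranked_strong
        m, reduced, _ = select_top_kmers(ranked, table, strong_bundle.labels, [1],
                                         fast_cv(seed=3))
        assert m == 1 and list(reduced.columns) == [ranked[0][0]]

    def test_selection_not_worse_than_near_full_table(self, strong_bundle, ranked_strong):
        table, ranked = ranked_strong
        m, _, auc_table = select_top_kmers(ranked, table, strong_bundle.labels,
                                           [5, 25, 319], fast_cv(seed=4))
        assert auc_table.loc[m, "mean_roc_auc"] >= auc_table.loc[319, "mean_roc_auc"]

    def test_full_grid_is_identity(self, strong_bundle, ranked_strong):
        table, ranked = ranked_strong
        m, reduced, _ = select_top_kmers(ranked, table, strong_bundle.labels, [320],
                                         fast_cv(seed=5, repetitions=1))
        assert m == 320 and set(reduced.columns) == set(table.columns)

    def test_empty_grid_rejected(self, strong_bundle, ranked_strong):
        table, ranked = ranked_strong
        with pytest.raises(ValueError):
            select_top_kmers(ranked, table, strong_bundle.labels, [], fast_cv())


class TestWelch:
    def test_hand_computed_oracle(self):
        table = pd.DataFrame({"AAA": [0.10, 0.12, 0.11, 0.20, 0.22, 0.21]},
                             index=list("abcdef"))
        labels = LabelSet(positives={"a", "b", "c"}, negatives={"d", "e", "f"})
        report = welch_ttest_kmers(table, labels, ["AAA"])
        assert report.loc["AAA", "t"] == pytest.approx(WELCH_T, abs=1e-9)
        assert report.loc["AAA", "p"] == pytest.approx(WELCH_P, abs=1e-9)
        assert bool(report.loc["AAA", "significant"]) is True

    def test_identical_values_flagged_with_p_one(self):
        table = pd.DataFrame({"AAA": [0.5] * 6}, index=list("abcdef"))
        labels = LabelSet(positives={"a", "b", "c"}, negatives={"d", "e", "f"})
        report = welch_ttest_kmers(table, labels)
        assert report.loc["AAA", "p"] == 1.0
        assert report.loc["AAA", "t"] == 0.0
        assert bool(report.loc["AAA", "zero_variance"]) is True

    def test_planted_kmers_mostly_significant(self, strong_bundle, ranked_strong):
        table, _ = ranked_strong
        report = welch_ttest_kmers(table, strong_bundle.labels,
                                   list(strong_bundle.config.informative_kmers))
        assert report["significant"].all()
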