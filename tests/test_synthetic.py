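import numpy as np
import pytest
from scipy import stats

from dnaspectra import (
    CodingModel,
    F56F11_4A_LAYOUT,
    GeneLayout,
    classify_coding,
    coding_like_sequence,
    default_coding_model,
    labeled_dataset,
    mosaic_gene,
    periodic_sequence,
    random_sequence,
    tbp_se,
    to_indicators,
    voss_spectrum,
)


class TestPeriodicSequence:
    def test_concatenation(self):
        assert periodic_sequence("CACCCG", 2).symbols == "CACCCGCACCCG"

    def test_length(self):
        assert periodic_sequence("ACGTGC", 50).n == 300

    def test_period3_spectrum_concentrates_at_third(self):
        spec = voss_spectrum(to_indicators(periodic_sequence("ATG", 100)))
        k = spec.bin_nearest(1 / 3)
        assert spec.values[k] == pytest.approx(spec.values[1:].sum())

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            periodic_sequence("", 3)
        with pytest.raises(ValueError):
            periodic_sequence("ACG", 0)
        with pytest.raises(Exception):
            periodic_sequence("ACGU", 2)


class TestRandomSequence:
    def test_uniform_counts_within_binomial_bounds(self):
        seq = random_sequence((0.25, 0.25, 0.25, 0.25), 1000, seed=0)
        counts = [seq.symbols.count(b) for b in "ACGT"]
        sd = np.sqrt(1000 * 0.25 * 0.75)
        assert all(abs(c - 250) < 4 * sd for c in counts)

    def test_degenerate_composition(self):
        assert random_sequence((1, 0, 0, 0), 20, seed=1).symbols == "A" * 20

    def test_seeded_reproducibility(self):
        a = random_sequence((0.25, 0.25, 0.25, 0.25), 100, seed=7)
        b = random_sequence((0.25, 0.25, 0.25, 0.25), 100, seed=7)
        assert a.symbols == b.symbols

    def test_invalid_composition(self):
        with pytest.raises(ValueError):
            random_sequence((0.5, 0.5, 0.5, 0.5), 10, seed=0)


class TestCodingModel:
    def test_effective_matrix_rows_sum_to_one(self):
        for eps in (0.0, 0.4, 1.0):
            m = default_coding_model(eps)
            assert np.allclose(m.effective_matrix.sum(axis=1), 1.0)
            assert np.all(m.effective_matrix >= 0)

    def test_invalid_matrix(self):
        with pytest.raises(ValueError):
            CodingModel(matrix=np.ones((3, 4)))
        with pytest.raises(ValueError):
            CodingModel(matrix=np.full((3, 4), 0.25), epsilon=1.5)


class TestCodingLikeSequence:
    def test_length_is_three_times_codons(self):
        seq = coding_like_sequence(default_coding_model(1.0), 40, seed=0)
        assert seq.n == 120

    def test_start_atg(self):
        seq = coding_like_sequence(default_coding_model(1.0), 10, seed=0, start_atg=True)
        assert seq.symbols.startswith("ATG")

    def test_epsilon_zero_is_positionally_uniform(self):
        """At zero bias the positional base counts pass a chi-square null test."""
        seq = coding_like_sequence(default_coding_model(0.0), 500, seed=3)
        idx = np.array(["ACGT".index(c) for c in seq.symbols])
        for j in range(3):
            counts = np.bincount(idx[j::3], minlength=4)
            p = stats.chisquare(counts).pvalue
            assert p > 0.001

    def test_full_bias_classified_coding(self):
        """Strong period-3 bias yields a TBP call in >= 95/100 replicates."""
        model = default_coding_model(1.0)
        hits = 0
        for rep in range(100):
            seq = coding_like_sequence(model, 200, seed=10_000 + rep)
            call = classify_coding(tbp_se(to_indicators(seq)).spectrum)
            hits += call == "coding"
        assert hits >= 95


class TestMosaicGene:
    def test_default_layout_matches_benchmark_coordinates(self):
        assert F56F11_4A_LAYOUT.total_length == 7990
        assert F56F11_4A_LAYOUT.exons == (
            (928, 1039), (2528, 2857), (4114, 4377), (5465, 5644), (7255, 7605)
        )
        seq, truth = mosaic_gene(F56F11_4A_LAYOUT, seed=0)
        assert seq.n == 7990
        assert truth == list(F56F11_4A_LAYOUT.exons)

    def test_all_exon_layout_is_coding_like(self):
        layout = GeneLayout(
            total_length=300, exons=((1, 300),), model=default_coding_model(1.0)
        )
        seq, _ = mosaic_gene(layout, seed=4)
        assert classify_coding(tbp_se(to_indicators(seq)).spectrum) == "coding"

    def test_seeded_reproducibility(self):
        a, _ = mosaic_gene(F56F11_4A_LAYOUT, seed=11)
        b, _ = mosaic_gene(F56F11_4A_LAYOUT, seed=11)
        assert a.symbols == b.symbols

    def test_invalid_layout(self):
        with pytest.raises(ValueError):
            GeneLayout(total_length=100, exons=((50, 150),))
        with pytest.raises(ValueError):
            GeneLayout(total_length=100, exons=((10, 40), (30, 60)))


class TestLabeledDataset:
    def test_counts_and_labels(self):
        seqs, labels = labeled_dataset(10, 10, default_coding_model(1.0), seed=0)
        assert len(seqs) == 20
        assert labels.count("coding") == 10 and labels.count("noncoding") == 10
        assert all(s.n >= 200 for s in seqs)

    def test_seeded_reproducibility(self):
        a, _ = labeled_dataset(5, 5, default_coding_model(0.5), seed=9)
        b, _ = labeled_dataset(5, 5, default_coding_model(0.5), seed=9)
        assert [s.symbols for s in a] == [s.symbols for s in b]

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            labeled_dataset(1, 1, default_coding_model(1.0), length=150, seed=0)
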