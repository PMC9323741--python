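import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnaspectra import (
    DnaSequence,
    Mapping,
    eiip_mapping,
    energy_spectrum,
    fold_one_sided,
    indicator_dft,
    map_to_signal,
    mapped_one_sided,
    qpsk_mapping,
    to_indicators,
    voss_spectrum,
)
from dnaspectra.spectral import uniform_mapping

dna_text = st.text(alphabet="ACGT", min_size=2, max_size=80)
M1 = Mapping(a=1, c=0.5, g=-0.5, t=-1, name="M1")


def _ind(text):
    return to_indicators(DnaSequence("s", text))


class TestIndicatorDft:
    def test_dc_bin_is_base_counts(self):
        dft = indicator_dft(_ind("ACGGTTTA"))
        assert np.allclose(dft[:, 0], [2, 1, 2, 3])

    @pytest.mark.parametrize("repeats", [1, 4, 9])
    def test_cacccg_second_harmonic(self, repeats):
        """Hand DFT of one CACCCG period at f=1/3, scaled by repeat count."""
        ind = _ind("CACCCG" * repeats)
        k = ind.n // 3
        xk = indicator_dft(ind)[:, k]
        expected = repeats * np.array(
            [np.exp(-2j * np.pi / 3), 1.0, np.exp(-4j * np.pi / 3), 0.0]
        )
        assert np.allclose(xk, expected)

    def test_constant_indicator_has_no_ac_content(self):
        dft = indicator_dft(_ind("AAAA"))
        assert np.allclose(dft[0, 1:], 0.0)


class TestFixedMappings:
    def test_qpsk_constellation(self):
        m = qpsk_mapping()
        assert (m.a, m.c, m.g, m.t) == (1 + 1j, -1 - 1j, -1 + 1j, 1 - 1j)

    def test_eiip_values(self):
        m = eiip_mapping()
        assert (m.a, m.c, m.g, m.t) == (0.126, 0.134, 0.0806, 0.1335)
        assert m.is_real


class TestMapToSignal:
    def test_substitution(self):
        sig = map_to_signal(_ind("ACGT"), Mapping(a=1, c=2, g=3, t=4))
        assert np.allclose(sig, [1, 2, 3, 4])

    def test_m1_period_values(self):
        sig = map_to_signal(_ind("ACGTGC"), M1)
        assert np.allclose(sig, [1, 0.5, -0.5, -1, -0.5, 0.5])

    def test_zero_mapping(self):
        assert np.allclose(map_to_signal(_ind("ACGT"), Mapping(0, 0, 0, 0)), 0)


class TestEnergySpectrum:
    def test_uniform_mapping_concentrates_at_dc(self):
        spec = energy_spectrum(_ind("ACGTGCA"), uniform_mapping())
        n = 7
        assert spec.values[0] == pytest.approx(n**2)
        assert np.allclose(spec.values[1:], 0.0)

    def test_matches_signal_dft(self):
        """Quadratic form on indicator DFTs equals the DFT of the mapped signal."""
        ind = _ind("ACGGTCATGC")
        m = qpsk_mapping()
        direct = np.abs(np.fft.fft(map_to_signal(ind, m))) ** 2
        assert np.allclose(energy_spectrum(ind, m).values, direct)

    @settings(deadline=None, derandomize=True)
    @given(dna_text, st.integers(0, 2**31 - 1))
    def test_parseval(self, text, seed):
        """Spectral energy = N x time-domain energy, for any mapping."""
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        m = Mapping(*w)
        ind = _ind(text)
        sig = map_to_signal(ind, m)
        spec = energy_spectrum(ind, m)
        expected = ind.n * float(np.sum(np.abs(sig) ** 2))
        assert spec.total_energy() == pytest.approx(expected, rel=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(dna_text)
    def test_real_mapping_symmetry(self, text):
        spec = energy_spectrum(_ind(text), eiip_mapping())
        assert np.allclose(spec.values[1:], spec.values[1:][::-1])


class TestFolding:
    def test_real_mapping_doubles_inner_bins(self):
        ind = _ind("ACGTTGCAT")  # odd N: no Nyquist bin
        two = energy_spectrum(ind, eiip_mapping())
        one = fold_one_sided(two)
        assert np.allclose(one.values[1:], 2 * two.values[1 : one.n_bins])

    def test_energy_conserved(self):
        for text in ("ACGTGCAC", "ACGTGCACT"):  # even and odd N
            two = energy_spectrum(_ind(text), qpsk_mapping())
            one = fold_one_sided(two)
            assert one.total_energy() == pytest.approx(two.total_energy())
            assert np.all(one.values >= 0)

    def test_qpsk_cacccg_equal_peak_content(self, cacccg300):
        """Complex-mapping asymmetry disappears after folding: the 1/6 and 1/3
        peaks of the CACCCG toy carry identical one-sided content."""
        one = mapped_one_sided(cacccg300, qpsk_mapping())
        assert one.values[50] == pytest.approx(one.values[100], rel=1e-9)


class TestVossSpectrum:
    def test_total_energy_is_n_squared(self):
        ind = _ind("ACGTTGACGTC")
        assert voss_spectrum(ind).total_energy() == pytest.approx(ind.n**2)

    def test_homopolymer_is_dc_only(self):
        one = voss_spectrum(_ind("AAAA"))
        assert one.values[0] == pytest.approx(16.0)
        assert np.allclose(one.values[1:], 0.0)

    def test_period3_concentrates_at_third(self):
        one = voss_spectrum(_ind("ATG" * 100))
        nondc = one.values[1:]
        k = one.bin_nearest(1 / 3)
        assert one.values[k] == pytest.approx(nondc.sum())


class TestOneSidedSpectrum:
    def test_frequency_grid_and_peaks(self):
        one = voss_spectrum(_ind("ATG" * 10))
        assert one.frequencies[0] == 0.0
        assert one.frequencies[-1] == pytest.approx(0.5)
        assert one.peak_frequency() == pytest.approx(1 / 3)

    def test_table_export(self):
        table = voss_spectrum(_ind("ACGTAC")).to_table()
        header, *rows = table.strip().splitlines()
        assert header.split("\t") == ["bin", "normalized_frequency", "energy"]
        assert len(rows) == 4  # floor(6/2)+1
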