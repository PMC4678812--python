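import numpy as np
import pytest
from scipy.stats import binomtest

from _oracles import nb_conditional_pvalue
from sirspread import diffacc
from sirspread.sio import ConfigurationError


class TestNormalize:
    def test_equal_libraries(self):
        factors = diffacc.normalize(None, np.array([1e6, 1e6, 1e6]), "total-count")
        assert (factors == 1e6).all()

    def test_total_count_per_million_factor_two(self):
        factors = diffacc.normalize(None, np.array([1e6, 2e6]), "total-count")
        assert factors[1] / factors[0] == 2.0

    def test_zero_library_rejected(self):
        with pytest.raises(ConfigurationError):
            diffacc.normalize(None, np.array([1e6, 0.0]), "total-count")

    def test_median_of_ratios_toy_matrix(self):
        # 4-window toy: sample 2 is exactly 3x sample 1, no DE
        counts = np.array([[10, 30], [20, 60], [40, 120], [5, 15]], dtype=float)
        factors = diffacc.normalize(counts, np.array([75.0, 225.0]),
                                    "median-of-ratios")
        assert factors[1] / factors[0] == pytest.approx(3.0)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)


class TestEqualize:
    def test_equal_libraries_unchanged(self):
        counts = np.array([[3, 5], [0, 2]])
        assert (diffacc.equalize_counts(counts, np.array([100.0, 100.0])) == counts).all()

    def test_rescales_to_geometric_mean(self):
        counts = np.array([[100, 100]])
        out = diffacc.equalize_counts(counts, np.array([1e6, 4e6]))
        # geometric mean 2e6: sample 1 doubled, sample 2 halved
        assert out.tolist() == [[200, 50]]


class TestDispersion:
    def test_identical_replicates_moments_zero(self):
        counts = np.tile(np.array([[7], [13], [40]]), (1, 4))
        groups = np.array(["A", "A", "B", "B"])
        est = diffacc.estimate_common_dispersion(counts, groups, method="moments")
        assert est.phi == 0.0

    @pytest.mark.parametrize("method", ["moments", "qcml"])
    def test_poisson_counts_give_small_phi(self, method, rng):
        counts = rng.poisson(100.0, size=(2000, 4))
        groups = np.array(["A", "A", "B", "B"])
        est = diffacc.estimate_common_dispersion(counts, groups, method=method)
        assert est.phi <= 0.02

    @pytest.mark.parametrize("method", ["moments", "qcml"])
    def test_nb_parameter_recovery(self, method, rng):
        phi, mu = 0.2, 100.0
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(2000, 4))
        groups = np.array(["A", "A", "B", "B"])
        est = diffacc.estimate_common_dispersion(counts, groups, method=method)
        assert 0.15 <= est.phi <= 0.25

    def test_all_filtered_is_error(self):
        counts = np.zeros((5, 4), dtype=int)
        groups = np.array(["A", "A", "B", "B"])
        with pytest.raises(ConfigurationError):
            diffacc.estimate_common_dispersion(counts, groups)


class TestExactNbTest:
    def test_poisson_closed_form(self):
        # (0,0) vs (5,5), phi=0: conditional law Binomial(10, 1/2)
        p = diffacc.exact_nb_test([0, 0], [5, 5], phi=0.0)
        assert p == pytest.approx(2 * 1 / 2**10, rel=1e-9)

    def test_balanced_split_p_one(self):
        assert diffacc.exact_nb_test([3, 3], [3, 3], phi=0.0) == pytest.approx(1.0)

    def test_zero_total_p_one(self):
        assert diffacc.exact_nb_test([0, 0], [0, 0], phi=0.5) == 1.0

    def test_negative_phi_rejected(self):
        with pytest.raises(ConfigurationError):
            diffacc.exact_nb_test([1], [2], phi=-0.1)

    @pytest.mark.parametrize("phi", [0.0, 0.5, 2.0])
    def test_enumeration_oracle_small_totals(self, phi):
        cases = [([0, 1], [4, 3]), ([2, 2], [2, 2]), ([6, 6], [0, 0]),
                 ([0, 0], [5, 7]), ([1, 2], [3, 4]), ([5], [1, 1, 1])]
        for counts_a, counts_b in cases:
            expected = nb_conditional_pvalue(counts_a, counts_b, phi)
            got = diffacc.exact_nb_test(counts_a, counts_b, phi)
            assert got == pytest.approx(expected, rel=1e-6), (counts_a, counts_b, phi)

    def test_symmetry(self):
        for phi in (0.0, 0.3, 1.5):
            a, b = [7, 2], [1, 0]
            assert diffacc.exact_nb_test(a, b, phi) == pytest.approx(
                diffacc.exact_nb_test(b, a, phi), rel=1e-12)

    def test_poisson_limit_matches_exact_binomial(self):
        # phi=0, equal libraries: the test is an exact binomial test on the
        # group-A sum, two-sided by mass
        for t in range(1, 13):
            for s in range(t + 1):
                ours = diffacc.exact_nb_test([s], [t - s], phi=0.0)
                ref = binomtest(s, t, 0.5).pvalue
                assert ours == pytest.approx(ref, rel=1e-9), (s, t)

    def test_monotonicity_on_extreme_splits(self):
        for phi in (0.0, 0.5):
            prev = None
            for s in range(6, 13):  # increasingly extreme splits of t=12
                p = diffacc.exact_nb_test([s], [12 - s], phi)
                if prev is not None:
                    assert p <= prev + 1e-12
                prev = p


class TestNullCalibration:
    def test_type_i_error_rate(self, rng):
        phi, mu = 0.2, 50.0
        r = 1.0 / phi
        n_windows = 2000
        counts = rng.negative_binomial(r, r / (r + mu), size=(n_windows, 4))
        pvals = np.array([diffacc.exact_nb_test(row[:2], row[2:], phi)
                          for row in counts])
        frac = (pvals < 0.05).mean()
        assert 0.02 <= frac <= 0.08  # wider gate than acceptance (smaller n)


class TestCallSignificant:
    def make_frame(self, pvals):
        import pandas as pd
        return pd.DataFrame({
            "chrom": "c", "start": 0, "end": 300, "size": 21,
            "mean_control": 1.0, "mean_case": 2.0, "log2_fc": 1.0,
            "p_value": pvals, "p_adjusted": pvals,
            "significant": False, "direction": "up_in_mutant"})

    def test_raw_threshold(self):
        df = diffacc.call_significant(self.make_frame([0.049, 0.051]),
                                      diffacc.DiffConfig(alpha=0.05))
        assert df["significant"].tolist() == [True, False]

    def test_all_p_one(self):
        df = diffacc.call_significant(self.make_frame([1.0] * 5))
        assert not df["significant"].any()

    def test_bh_keeps_strong_signals(self):
        pvals = [1e-6] * 5 + list(np.linspace(0.2, 1.0, 95))
        df = diffacc.call_significant(self.make_frame(pvals),
                                      diffacc.DiffConfig(adjust="BH"))
        assert df["significant"].tolist()[:5] == [True] * 5
        assert df["significant"].sum() == 5

    def test_bh_stepup_by_hand(self):
        # hand BH on p = (0.01, 0.02, 0.04, 0.8): adj = (0.04, 0.04, 0.0533..., 0.8)
        adj = diffacc.bh_adjust(np.array([0.01, 0.02, 0.04, 0.8]))
        assert adj == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_na_never_significant(self):
        df = diffacc.call_significant(self.make_frame([np.nan, 0.01]))
        assert df["significant"].tolist() == [False, True]


def test_test_windows_end_to_end(small_sim):
    from sirspread.windows import count_reads, make_windows
    reference = small_sim["reference"]
    chrom_lengths = {c: len(s) for c, s in reference.genome.items()}
    windows = make_windows(chrom_lengths)
    all_reads = [r for s in sorted(small_sim["reads"])
                 for r in small_sim["reads"][s]]
    samples = sorted(small_sim["reads"])
    matrix = count_reads(all_reads, windows, samples=samples)
    control = [s for s in samples if s.startswith("SKI2_RDR6")]
    case = [s for s in samples if s.startswith("ski2_RDR6")]
    df = diffacc.test_windows(matrix, control, case)
    assert df["p_value"].dropna().between(0, 1).all()
    sig = df[df["significant"]]
    assert len(sig) > 0
    assert (sig["direction"] != "").all()
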