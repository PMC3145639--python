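"""Frequency matrices, pseudo-counts, both PWM styles, and the TSV dialect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinspec.alphabet import AA20, AA_INDEX, SERINE_THREONINE
from kinspec.errors import NoPrediction, PwmFormatError
from kinspec.evaluation import baseline_matrices
from kinspec.pwm import (
    BackgroundFrequencies,
    FrequencyMatrix,
    PositionWeightMatrix,
    build_frequency_matrix,
    new_style_pwm,
    old_style_pwm,
    pseudo_count_frequencies,
    read_pwm,
    write_pwm,
)


def _random_sites(rng, n):
    out = []
    for _ in range(n):
        h = list(rng.choice(list(AA20), size=7))
        h[3] = str(rng.choice(["S", "T"]))
        out.append("".join(h))
    return out


class TestFrequencyMatrix:
    def test_identical_heptamers(self):
        F = build_frequency_matrix(["RRASLPE"] * 3)
        assert F.n_sites == 3
        assert (F.counts.sum(axis=0) == 3).all()
        for j, a in enumerate("RRASLPE"):
            col = F.counts[:, j]
            assert col[AA_INDEX[a]] == 3 and col.sum() == 3

    def test_column_sums_equal_n_for_random_site_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            F = build_frequency_matrix(_random_sites(rng, n))
            assert (F.counts.sum(axis=0) == n).all()

    def test_below_min_sites_signals_no_prediction(self):
        with pytest.raises(NoPrediction) as exc:
            build_frequency_matrix(["RRASLPE"] * 2, min_sites=3)
        assert exc.value.n_found == 2


heptamers = st.lists(
    st.tuples(
        st.text(alphabet=AA20, min_size=3, max_size=3),
        st.sampled_from("ST"),
        st.text(alphabet=AA20, min_size=3, max_size=3),
    ).map(lambda t: t[0] + t[1] + t[2]),
    min_size=3,
    max_size=40,
)


@given(heptamers)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_count_conservation_and_stochastic_columns(sites):
    """Counts are conserved and pseudo-counted columns are stochastic for
    arbitrary heptamer collections."""
    bg = BackgroundFrequencies(b=np.full(20, 0.05), kinase_type=SERINE_THREONINE)
    F = build_frequency_matrix(sites)
    assert (F.counts.sum(axis=0) == len(sites)).all()
    f = pseudo_count_frequencies(F, bg)
    np.testing.assert_allclose(f.sum(axis=0), 1.0, atol=1e-9)
    assert (f > 0).all() and (f < 1).all()


class TestPseudoCounts:
    def test_hand_computed_cases(self, uniform_bg):
        # one column all A (count 4 of 4), b = 0.05
        F = build_frequency_matrix(["AAASAAA"] * 4)
        f = pseudo_count_frequencies(F, uniform_bg)
        a = AA_INDEX["A"]
        assert f[a, 0] == pytest.approx((4 + 2 * 0.05) / 6, abs=1e-12)  # 0.68333...
        assert f[AA_INDEX["C"], 0] == pytest.approx(0.1 / 6, abs=1e-12)  # 0.01666...

    def test_columns_sum_to_one_for_random_fixtures(self, uniform_bg):
        rng = np.random.default_rng(1)
        for _ in range(100):
            F = build_frequency_matrix(_random_sites(rng, int(rng.integers(3, 30))))
            f = pseudo_count_frequencies(F, uniform_bg)
            np.testing.assert_allclose(f.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("n", [100, 10_000])
    def test_large_n_convergence_to_count_fraction(self, uniform_bg, n):
        rng = np.random.default_rng(2)
        counts = rng.multinomial(n, np.full(20, 0.05), size=7).T
        F = FrequencyMatrix(counts=counts, n_sites=n)
        f = pseudo_count_frequencies(F, uniform_bg)
        assert np.abs(f - counts / n).max() < 2 / np.sqrt(n)


class TestStyles:
    def test_new_style_equals_pseudo_counted_frequencies(self, uniform_bg):
        rng = np.random.default_rng(3)
        F = build_frequency_matrix(_random_sites(rng, 25))
        pwm = new_style_pwm(F, uniform_bg)
        np.testing.assert_array_equal(
            pwm.weights, pseudo_count_frequencies(F, uniform_bg)
        )
        assert pwm.style == "new"

    def test_background_column_becomes_uniform_in_old_style(self):
        # counts exactly proportional to the background in every column
        b = np.full(20, 0.05)
        bg = BackgroundFrequencies(b=b, kinase_type=SERINE_THREONINE)
        counts = np.full((20, 7), 1, dtype=int)  # f == b == 0.05 after pc
        F = FrequencyMatrix(counts=counts, n_sites=20)
        pwm = old_style_pwm(F, bg)
        np.testing.assert_allclose(pwm.weights, 0.05, atol=1e-12)

    def test_single_enriched_residue_takes_all_weight(self, uniform_bg):
        # all 10 sites have A at position -3: only A's log-odds is positive
        F = build_frequency_matrix(["AAASAAA"] * 10)
        pwm = old_style_pwm(F, uniform_bg)
        assert pwm.weights[AA_INDEX["A"], 0] == pytest.approx(1.0, abs=1e-12)
        assert pwm.weights[:, 0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_both_styles_column_stochastic_on_random_fixtures(self, uniform_bg):
        rng = np.random.default_rng(4)
        for _ in range(100):
            F = build_frequency_matrix(_random_sites(rng, int(rng.integers(3, 30))))
            for build in (new_style_pwm, old_style_pwm):
                pwm = build(F, uniform_bg)
                np.testing.assert_allclose(pwm.column_sums(), 1.0, atol=1e-9)

    def test_information_content_zero_for_uniform(self):
        m1, _, _ = baseline_matrices()
        np.testing.assert_allclose(m1.information_content(), 0.0, atol=1e-12)


class TestPwmTsv:
    def test_round_trip_baseline(self, tmp_path):
        _, m2, _ = baseline_matrices()
        path = tmp_path / "m2.tsv"
        write_pwm(m2, path)
        back = read_pwm(path)
        assert back.style == "baseline"
        np.testing.assert_allclose(back.weights, m2.weights, atol=1e-12)

    def test_round_trip_arbitrary_weights(self, tmp_path):
        rng = np.random.default_rng(5)
        w = rng.dirichlet(np.ones(20), size=7).T
        pwm = PositionWeightMatrix(weights=w, style="new", metadata={"n_sites": 9})
        path = tmp_path / "p.tsv"
        write_pwm(pwm, path)
        back = read_pwm(path)
        np.testing.assert_allclose(back.weights, w, atol=1e-12)
        assert back.metadata["n_sites"] == 9

    def test_missing_row_is_an_error(self, tmp_path):
        m1, _, _ = baseline_matrices()
        path = tmp_path / "m1.tsv"
        write_pwm(m1, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop row Y
        with pytest.raises(PwmFormatError, match="20 rows"):
            read_pwm(path)

    def test_reversed_column_order_is_an_error(self, tmp_path):
        m1, _, _ = baseline_matrices()
        path = tmp_path / "m1.tsv"
        write_pwm(m1, path)
        text = path.read_text().replace(
            "\t-3\t-2\t-1\t0\t+1\t+2\t+3", "\t+3\t+2\t+1\t0\t-1\t-2\t-3"
        )
        path.write_text(text)
        with pytest.raises(PwmFormatError, match="column headers"):
            read_pwm(path)
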