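"""Internal-consistency coefficients, split-half permutation reliability,
and correlation tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdproc import (
    cronbach_alpha,
    interitem_spearman,
    mcdonald_omega,
    parameter_correlations,
    reliability_report,
    score_pdp,
    spearman_brown,
    splithalf_reliability,
)
from pdproc.psychometrics import DegenerateDataError
from .conftest import make_matrix


def one_factor_data(rng, n, loadings):
    """Gaussian items with a single common factor and given loadings."""
    loadings = np.asarray(loadings)
    factor = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, len(loadings)))
    return factor * loadings + noise * np.sqrt(1 - loadings**2)


class TestCronbachAlpha:
    def test_two_identical_items(self, rng):
        x = rng.standard_normal(100)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_equicorrelated_matches_prophecy_formula(self, rng):
        """For standardized items, alpha equals m*rbar/(1+(m-1)*rbar) with
        rbar the observed mean inter-item correlation."""
        m = 6
        x = one_factor_data(rng, 5000, np.full(m, np.sqrt(0.4)))
        z = (x - x.mean(0)) / x.std(0)
        rbar = np.corrcoef(z.T)[np.triu_indices(m, 1)].mean()
        assert cronbach_alpha(z) == pytest.approx(
            m * rbar / (1 + (m - 1) * rbar), abs=1e-10
        )

    def test_independent_items_near_zero(self, rng):
        assert abs(cronbach_alpha(rng.standard_normal((20_000, 8)))) < 0.05

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = one_factor_data(rng, 500, [0.7, 0.5, 0.6, 0.3])
        expected = pingouin.cronbach_alpha(pd.DataFrame(x))[0]
        assert cronbach_alpha(x) == pytest.approx(expected, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(np.ones((10, 4)))


class TestMcdonaldOmega:
    def test_equicorrelated_closed_form(self, rng):
        """All pairwise r = 0.5 over m = 10 items gives loadings sqrt(0.5)
        and omega = 50/55 ~ 0.909; recovery within ±0.02 at n = 10,000."""
        x = one_factor_data(rng, 10_000, np.full(10, np.sqrt(0.5)))
        assert mcdonald_omega(x) == pytest.approx(50 / 55, abs=0.02)

    def test_independent_items_near_zero(self, rng):
        assert mcdonald_omega(rng.standard_normal((5000, 6))) < 0.1

    def test_omega_vs_alpha_tau_equivalence(self, rng):
        """omega >= alpha under unequal loadings; omega ~ alpha when items
        are parallel."""
        unequal = one_factor_data(rng, 20_000, [0.9, 0.9, 0.8, 0.2, 0.1, 0.1])
        assert mcdonald_omega(unequal) >= cronbach_alpha(unequal) - 1e-3
        equal = one_factor_data(rng, 20_000, np.full(6, 0.6))
        assert mcdonald_omega(equal) == pytest.approx(cronbach_alpha(equal), abs=0.02)

    def test_constant_item_rejected(self, rng):
        x = rng.standard_normal((100, 4))
        x[:, 2] = 3.0
        with pytest.raises(DegenerateDataError):
            mcdonald_omega(x)


class TestSpearmanBrown:
    @pytest.mark.parametrize("r, expected", [(0.0, 0.0), (1.0, 1.0), (1 / 3, 0.5), (0.5, 2 / 3)])
    def test_values(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_undefined_at_minus_one(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0)

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_monotone_and_maps_unit_interval(self, a, b):
        lo, hi = sorted((a, b))
        assert spearman_brown(lo) <= spearman_brown(hi) + 1e-12
        if 0 <= hi <= 1:
            assert 0 <= spearman_brown(hi) <= 1


class TestSplitHalf:
    def test_perfectly_consistent_responders(self, rng):
        """If each responder answers every item of a set identically, both
        halves yield identical scores and the corrected estimate is 1."""
        c_level = (rng.random(60) < 0.6).astype(int)
        ic_level = (rng.random(60) < 0.4).astype(int)
        m = make_matrix(np.tile(c_level[:, None], 6), np.tile(ic_level[:, None], 6))
        rep = splithalf_reliability(m, n_iter=50, seed=0)
        assert rep.splithalf_u.mean == pytest.approx(1.0)
        assert rep.splithalf_u.sd == pytest.approx(0.0, abs=1e-12)

    def test_no_signal_data_centers_on_zero(self, rng):
        """Random halves of random data are independent; corrected
        estimates average ~0 for both U and D."""
        m = make_matrix(
            (rng.random((4000, 10)) < 0.5).astype(int),
            (rng.random((4000, 10)) < 0.5).astype(int),
        )
        rep = splithalf_reliability(m, n_iter=300, seed=1)
        assert abs(rep.splithalf_u.mean) < 0.05
        assert abs(rep.splithalf_d.mean) < 0.05
        assert not rep.unreliable

    def test_odd_k_splits_four_versus_five(self, rng):
        m = make_matrix(
            (rng.random((200, 9)) < 0.5).astype(int),
            (rng.random((200, 9)) < 0.5).astype(int),
        )
        rep = splithalf_reliability(m, n_iter=20, seed=3)
        assert rep.n_iterations == 20
        assert rep.splithalf_u.values.size + rep.splithalf_u.n_dropped == 20

    def test_invariant_to_pair_and_participant_order(self, rng):
        c = (rng.random((150, 6)) < 0.5).astype(int)
        ic = (rng.random((150, 6)) < 0.5).astype(int)
        m = make_matrix(c, ic)
        base = splithalf_reliability(m, n_iter=40, seed=9)
        col = [3, 1, 5, 0, 2, 4]
        shuffled = make_matrix(
            c[:, col], ic[:, col], labels=tuple(f"d{i + 1}" for i in col)
        )
        rep = splithalf_reliability(shuffled, n_iter=40, seed=9)
        assert np.allclose(base.splithalf_u.values, rep.splithalf_u.values)
        rows = rng.permutation(150)
        rep2 = splithalf_reliability(make_matrix(c[rows], ic[rows]), n_iter=40, seed=9)
        assert np.allclose(base.splithalf_u.values, rep2.splithalf_u.values)

    def test_degenerate_data_drops_everything_and_flags(self):
        m = make_matrix(np.zeros((20, 4)), np.zeros((20, 4)))
        rep = splithalf_reliability(m, n_iter=10, seed=0)
        assert rep.splithalf_u.n_dropped == 10
        assert rep.unreliable

    def test_full_report_includes_alpha_and_omega(self, random_matrix):
        rep = reliability_report(random_matrix, n_iter=50, seed=4)
        assert rep.alpha is not None and abs(rep.alpha) < 0.2
        assert rep.omega is not None
        assert rep.alpha_unreversed is not None
        d = rep.to_dict(include_values=False)
        assert set(d) >= {"alpha", "omega", "splithalf_u", "splithalf_d"}


class TestParameterCorrelations:
    def test_self_correlation_and_perfect_line(self):
        scores = pd.DataFrame({"U": [0.0, 1.0, 2.0], "TS": [0.0, 1.0, 2.0]})
        table = parameter_correlations(scores, columns=("U", "TS"))
        assert table.r.loc["U", "U"] == 1.0
        assert table.r.loc["U", "TS"] == pytest.approx(1.0)

    def test_pairwise_deletion_of_missing_d(self, random_matrix):
        scores = score_pdp(random_matrix)
        scores.loc[scores.index[:50], "D"] = np.nan
        table = parameter_correlations(scores)
        assert table.n.loc["U", "D"] == len(scores) - 50
        assert table.n.loc["U", "TS"] == len(scores)

    def test_zero_variance_cell_undefined(self):
        scores = pd.DataFrame({"U": [0.1, 0.2, 0.3, 0.4], "TS": [0.5] * 4})
        table = parameter_correlations(scores, columns=("U", "TS"))
        assert np.isnan(table.r.loc["U", "TS"])
        assert "undef" in table.annotated().loc["U", "TS"]

    def test_spearman_invariant_under_monotone_transform(self, rng):
        u = rng.random(200)
        ts = rng.random(200)
        a = parameter_correlations(
            pd.DataFrame({"U": u, "TS": ts}), method="spearman", columns=("U", "TS")
        )
        b = parameter_correlations(
            pd.DataFrame({"U": np.exp(3 * u), "TS": ts**3}),
            method="spearman",
            columns=("U", "TS"),
        )
        assert a.r.loc["U", "TS"] == pytest.approx(b.r.loc["U", "TS"])

    def test_stars_convention(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        scores = pd.DataFrame({"U": x, "TS": x + 0.5 * rng.standard_normal(n)})
        table = parameter_correlations(scores, columns=("U", "TS"))
        assert table.stars.loc["U", "TS"] == "***"


class TestInterItemSpearman:
    def test_duplicated_item_correlates_perfectly(self, rng):
        c = (rng.random((100, 3)) < 0.5).astype(int)
        m = make_matrix(c, np.column_stack([c[:, 0], c[:, 1], c[:, 2]]))
        res = interitem_spearman(m)
        assert res.matrix.loc["C_d1", "IC_d1"] == pytest.approx(1.0)

    def test_independent_items_median_near_null(self, rng):
        m = make_matrix(
            (rng.random((10_000, 5)) < 0.5).astype(int),
            (rng.random((10_000, 5)) < 0.5).astype(int),
        )
        res = interitem_spearman(m)
        assert res.median_abs < 0.02  # null |r| scale at n = 10,000

    def test_within_pair_exceeds_between_pair_on_mimic_data(self):
        from pdproc import PatternSpec, generate_empirical_mimic

        m = generate_empirical_mimic(PatternSpec(n_participants=4000, seed=6))
        res = interitem_spearman(m)
        within = np.array(
            [res.matrix.loc[f"C_{p}", f"IC_{p}"] for p in m.pair_labels]
        )
        mask = ~np.eye(len(res.matrix), dtype=bool)
        for p in m.pair_labels:
            i = list(res.matrix.index).index(f"C_{p}")
            j = list(res.matrix.index).index(f"IC_{p}")
            mask[i, j] = mask[j, i] = False
        between = np.abs(res.matrix.to_numpy()[mask])
        assert within.mean() > np.nanmean(between) + 0.1

    def test_constant_item_flagged_undefined(self, rng):
        c = (rng.random((50, 3)) < 0.5).astype(int)
        ic = (rng.random((50, 3)) < 0.5).astype(int)
        c[:, 1] = 1
        res = interitem_spearman(make_matrix(c, ic))
        assert "C_d2" in res.undefined_items
        assert res.matrix.loc["C_d2"].isna().all()
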