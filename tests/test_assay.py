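"""Agonist calling, normalization and Hill-fit behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from tastekit.assay import (
    NormalizationError,
    ResponseSummary,
    fit_hill,
    grand_mean_profile,
    holm_adjust,
    normalize_profile,
    summarize_responses,
)
from tastekit.assay import test_agonists as call_agonists
from tastekit.simulate import (
    UNTRANSFECTED,
    HillParams,
    ReceptorSimParams,
    generate_plate_dataset,
    LigandDef,
)
from conftest import make_records


class TestSummaries:
    def test_closed_form_mean_and_se(self):
        (s,) = summarize_responses(make_records("r", [("suc", 100.0)], [4.0, 6.0]))
        assert s.mean == 5.0 and s.se == pytest.approx(1.0)
        (s3,) = summarize_responses(
            make_records("r", [("suc", 100.0)], [5.0, 5.0, 5.0])
        )
        assert s3.mean == 5.0 and s3.se == 0.0

    def test_single_replicate_flagged_untestable(self):
        (s,) = summarize_responses(make_records("r", [("suc", 100.0)], [7.0]))
        assert s.n == 1 and math.isnan(s.se) and not s.testable

    def test_empty_input(self):
        assert summarize_responses([]) == []

    def test_mix_order_is_canonical(self):
        a = make_records("r", [("a", 1.0), ("b", 2.0)], [1.0, 2.0])
        b = make_records("r", [("b", 2.0), ("a", 1.0)], [3.0, 4.0])
        (s,) = summarize_responses(a + b)
        assert s.n == 4


def _holm_oracle(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[i]))
        out[i] = running
    return out


class TestHolm:
    def test_worked_example(self):
        assert np.allclose(
            holm_adjust([0.01, 0.04, 0.30]), [0.03, 0.08, 0.30]
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_matches_bruteforce_and_statsmodels(self, pvals):
        mine = holm_adjust(pvals)
        assert np.allclose(mine, _holm_oracle(pvals))
        assert np.allclose(mine, multipletests(pvals, method="holm")[1])


def _summary(rid, mix, values):
    arr = np.asarray(values, dtype=float)
    return ResponseSummary(
        rid, mix, arr.size, float(arr.mean()),
        float(arr.std(ddof=1) / math.sqrt(arr.size)),
    )


class TestAgonistCalls:
    def test_identical_samples_give_half_p(self):
        mix = (("suc", 100.0),)
        t = _summary("r", mix, [10.0, 11.0, 12.0, 13.0])
        u = _summary(UNTRANSFECTED, mix, [10.0, 11.0, 12.0, 13.0])
        (res,) = call_agonists([t], [u])
        assert res.p_raw == pytest.approx(0.5)
        assert not res.is_agonist

    def test_missing_control_skipped(self):
        t = _summary("r", (("suc", 100.0),), [10.0, 12.0])
        (res,) = call_agonists([t], [])
        assert math.isnan(res.p_raw) and not res.is_agonist

    def test_adjusted_never_below_raw(self, rng):
        mix_p = []
        trans, ctrl = [], []
        for i in range(8):
            mix = ((f"l{i}", 100.0),)
            trans.append(_summary("r", mix, rng.normal(1, 1, 6)))
            ctrl.append(_summary(UNTRANSFECTED, mix, rng.normal(0, 1, 6)))
        for res in call_agonists(trans, ctrl):
            assert res.p_adj >= res.p_raw
            assert res.is_agonist == (res.p_adj < 0.05)

    def test_null_p_values_are_roughly_uniform(self, rng):
        # one-tailed Welch p under equal means should be (super-)uniform
        from scipy import stats

        pvals = []
        for _ in range(400):
            mix = (("x", 1.0),)
            t = _summary("r", mix, rng.normal(0, 1, 6))
            u = _summary(UNTRANSFECTED, mix, rng.normal(0, 1, 6))
            pvals.append(call_agonists([t], [u])[0].p_raw)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            call_agonists([], [], alpha=1.5)


class TestNormalization:
    def test_worked_example(self):
        t = [
            _summary("r", (("sucrose", 100.0),), [180.0, 180.0]),
            _summary("r", (("sucralose", 100.0),), [120.0, 120.0]),
        ]
        u = [
            _summary(UNTRANSFECTED, (("sucrose", 100.0),), [20.0, 20.0]),
            _summary(UNTRANSFECTED, (("sucralose", 100.0),), [20.0, 20.0]),
        ]
        prof = normalize_profile(t, u)
        assert prof.values["sucrose"] == pytest.approx(1.6)
        assert prof.values["sucralose"] == 1.0

    def test_scale_invariance(self, rng):
        base = {"sucralose": 150.0, "sucrose": 120.0, "glycine": 60.0}
        u = [_summary(UNTRANSFECTED, (), [20.0, 20.0])]

        def profile(scale):
            t = [
                _summary("r", ((name, 100.0),), [20.0 + scale * v] * 2)
                for name, v in base.items()
            ]
            return normalize_profile(t, u).values

        p1, p3 = profile(1.0), profile(3.0)
        for name in base:
            assert p1[name] == pytest.approx(p3[name])

    def test_reference_below_background_raises(self):
        t = [_summary("r", (("sucralose", 100.0),), [10.0, 10.0])]
        u = [_summary(UNTRANSFECTED, (("sucralose", 100.0),), [20.0, 20.0])]
        with pytest.raises(NormalizationError, match="r'"):
            normalize_profile(t, u)

    def test_batch_scale_cancels_in_simulation(self, small_panel, small_params):
        # near-noiseless wells with large batch effects: the normalized
        # profile must equal the noise-free signal ratio
        params = {
            "rx": ReceptorSimParams(
                hill=small_params["rx"].hill,
                baseline=5.0,
                batch_scale_sd=0.8,
                noise_sd=1e-6,
            )
        }
        recs = generate_plate_dataset(
            small_panel, params, n_replicates=6, n_batches=3, seed=11
        )
        t_sum = summarize_responses(
            [r for r in recs if r.receptor_id == "rx"]
        )
        u_sum = summarize_responses(
            [r for r in recs if r.receptor_id == UNTRANSFECTED]
        )
        prof = normalize_profile(t_sum, u_sum)
        hp = params["rx"].hill
        base = params["rx"].baseline
        expect = lambda name: (base + hp[name].response(100.0)) / (
            base + hp["sucralose"].response(100.0)
        )
        for name in ("sucrose", "glycine"):
            assert prof.values[name] == pytest.approx(expect(name), rel=1e-6)


class TestGrandMean:
    def test_mean_and_missing_handling(self):
        from tastekit.assay import NormalizedProfile

        p1 = NormalizedProfile("a", {"sucrose": 1.2, "glycine": 0.4})
        p2 = NormalizedProfile("b", {"sucrose": 1.8})
        out = grand_mean_profile([p1, p2])
        assert out.loc["sucrose", "grand_mean"] == pytest.approx(1.5)
        assert out.loc["glycine", "n"] == 1
        assert out.loc["sucrose", "n"] == 2

    def test_identical_profiles_have_zero_se(self):
        from tastekit.assay import NormalizedProfile

        profs = [
            NormalizedProfile(r, {"sucrose": 1.2, "glycine": 0.4})
            for r in ("a", "b", "c")
        ]
        out = grand_mean_profile(profs)
        assert np.allclose(out["se"], 0.0)

    def test_requires_two_profiles(self):
        from tastekit.assay import NormalizedProfile

        with pytest.raises(ValueError):
            grand_mean_profile([NormalizedProfile("a", {"x": 1.0})])


class TestHillFit:
    def test_exact_recovery_on_noiseless_curve(self):
        conc = np.array([0.5, 1, 2, 5, 10, 20, 50, 100], dtype=float)
        resp = 50 * conc / (10 + conc)  # B=0, E=50, EC50=10, h=1
        fit = fit_hill(list(zip(conc, resp)))
        assert fit.converged
        assert fit.e_max == pytest.approx(50, rel=1e-3)
        assert fit.ec50 == pytest.approx(10, rel=1e-3)
        assert fit.h == pytest.approx(1, rel=1e-3)
        assert fit.baseline == pytest.approx(0, abs=1e-2)

    def test_flat_series(self):
        conc = [1.0, 3.0, 10.0, 30.0, 100.0]
        fit = fit_hill([(c, 7.0) for c in conc])
        assert fit.converged
        assert fit.e_max == pytest.approx(0.0, abs=1e-3)
        assert fit.baseline == pytest.approx(7.0, abs=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_hill([(1.0, 2.0), (1.0, 2.1), (2.0, 3.0)])
        with pytest.raises(ValueError, match="finite"):
            fit_hill([(1.0, np.nan), (2.0, 1.0), (3.0, 1.0), (4.0, 1.0)])
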