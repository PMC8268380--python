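"""Marginal-effect formula and path decomposition invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from crcpath import published
from crcpath.effects import (MarginalEffect, PathEffect, PathSummary,
                             build_paths, from_printed_tables, marginal_effect)
from crcpath.glm import OLSFit, TermEstimate


class TestMarginalEffect:
    @pytest.mark.parametrize("beta,p,expected,tol", [
        (0.43, 0.046, 0.0190, 5e-4),          # obesity -> infection
        (0.83, 912 / 42_046, 0.0176, 3e-4),   # infection -> death
        (0.51, 505 / 42_055, 0.006, 3e-4),    # obesity -> wound disruption
    ])
    def test_published_values(self, beta, p, expected, tol):
        assert marginal_effect(beta, p).value == pytest.approx(expected, abs=tol)

    def test_vanishes_at_boundary(self):
        assert marginal_effect(5.0, 1e-9).value == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_prevalence_outside_open_interval_rejected(self, p):
        with pytest.raises(ValueError, match="prevalence"):
            marginal_effect(0.5, p)

    @given(beta=st.floats(-5, 5), p=st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=200, deadline=None)
    def test_formula_bound_and_sign(self, beta, p):
        me = marginal_effect(beta, p)
        assert me.value == beta * p * (1 - p)
        assert abs(me.value) <= abs(beta) / 4 + 1e-15
        # sign is preserved unless the product underflows to zero
        assert np.sign(me.value) == np.sign(beta) or me.value == 0.0

    def test_agrees_with_numerical_derivative(self):
        """beta*P*(1-P) equals the central-difference derivative of the
        logistic mean evaluated where the predicted probability is P."""
        for beta, p in [(0.43, 0.046), (2.45, 0.022), (-0.6, 0.3)]:
            eta0 = logit(p)
            h = 1e-6
            num = (expit(eta0 + beta * h) - expit(eta0 - beta * h)) / (2 * h)
            assert marginal_effect(beta, p).value == pytest.approx(
                num, abs=1e-6 * abs(beta))


def _ols(terms_dict, outcome="los_days"):
    terms = {"const": TermEstimate(0.0, 0.0, 1.0, 0.0, 0.0)}
    terms.update({k: TermEstimate(v, 0.0, 0.0, v, v)
                  for k, v in terms_dict.items()})
    return OLSFit(outcome=outcome, terms=terms, n_used=10, r2=0.1, adj_r2=0.1)


def _summary(a_vals, b_vals, los_vals, chg_vals):
    meds = list(a_vals)
    # at p = 1/2, beta = 4*value reproduces the requested edge exactly
    expo = {m: marginal_effect(4 * a_vals[m], 0.5, m) for m in meds}
    mort = {m: marginal_effect(4 * b_vals[m], 0.5, m) for m in meds}
    return build_paths(expo, mort, _ols(los_vals), _ols(chg_vals, "total_charges"))


class TestPaths:
    def test_products_and_totals_exact(self):
        s = _summary({"x": 0.02, "y": 0.01}, {"x": 0.5, "y": 0.25},
                     {"x": 10.0, "y": 4.0}, {"x": 100.0, "y": 50.0})
        assert s.effect("x").prod_mortality == 0.02 * 0.5
        assert s.totals["mortality"] == pytest.approx(0.02 * 0.5 + 0.01 * 0.25)
        assert s.totals["los"] == pytest.approx(0.2 + 0.04)
        assert s.totals["charges"] == pytest.approx(2.0 + 0.5)
        assert s.dominant["mortality"] == "x"

    def test_zero_exposure_edge_contributes_nothing(self):
        s = _summary({"x": 0.0, "y": 0.01}, {"x": 9.0, "y": 1.0},
                     {"x": 99.0, "y": 1.0}, {"x": 99.0, "y": 1.0})
        e = s.effect("x")
        assert e.prod_mortality == e.prod_los == e.prod_charges == 0.0

    def test_totals_invariant_to_mediator_order(self):
        a = {"x": 0.02, "y": 0.01, "z": 0.005}
        b = {"x": 0.5, "y": 0.25, "z": 0.1}
        l = {"x": 1.0, "y": 2.0, "z": 3.0}
        c = {"x": 5.0, "y": 6.0, "z": 7.0}
        rev = lambda d: dict(reversed(d.items()))
        s1 = _summary(a, b, l, c)
        s2 = _summary(rev(a), rev(b), rev(l), rev(c))
        assert s1.totals == pytest.approx(s2.totals)

    def test_perturbation_linearity(self):
        """Shifting one exposure edge by delta shifts each total by exactly
        delta times the matching outcome edge."""
        a = {"x": 0.02, "y": 0.01}
        b, l, c = {"x": 0.5, "y": 0.25}, {"x": 10.0, "y": 4.0}, {"x": 7.0, "y": 3.0}
        delta = 1e-3
        s0 = _summary(a, b, l, c)
        a2 = dict(a, x=a["x"] + delta)
        s1 = _summary(a2, b, l, c)
        assert s1.totals["mortality"] - s0.totals["mortality"] == pytest.approx(
            delta * b["x"], rel=1e-9)
        assert s1.totals["los"] - s0.totals["los"] == pytest.approx(
            delta * l["x"], rel=1e-9)
        assert s1.totals["charges"] - s0.totals["charges"] == pytest.approx(
            delta * c["x"], rel=1e-9)

    def test_mediator_mismatch_rejected(self):
        expo = {"x": marginal_effect(0.04, 0.5, "x")}
        mort = {"y": marginal_effect(0.04, 0.5, "y")}
        with pytest.raises(ValueError, match="mismatch"):
            build_paths(expo, mort, _ols({"x": 1.0}), _ols({"x": 1.0}))


class TestReplay:
    def test_published_tables_reproduce_figure_totals(self):
        t3, t4, t5 = published.replay_tables()
        s = from_printed_tables(t3, t4, t5)
        assert s.totals["mortality"] * 1e5 == pytest.approx(66.65, abs=0.05)
        assert s.totals["los"] == pytest.approx(0.317, abs=0.005)
        assert s.totals["charges"] == pytest.approx(2_384.34, abs=1.0)
        assert s.dominant == {"mortality": "infection", "los": "infection",
                              "charges": "infection"}

    def test_all_dpdx_zero_gives_zero_totals(self):
        t3, t4, t5 = published.replay_tables()
        t3 = {m: dict(e, dpdx=0.0) for m, e in t3.items()}
        s = from_printed_tables(t3, t4, t5)
        assert s.totals == {"mortality": 0.0, "los": 0.0, "charges": 0.0}

    def test_beta_p_pairs_used_when_dpdx_absent(self):
        t3, t4, t5 = published.replay_tables()
        t3 = {m: {"beta": e["beta"], "p": e["p"]} for m, e in t3.items()}
        s = from_printed_tables(t3, t4, t5)
        # infection edge recomputed from beta: 0.43 * 0.046 * 0.954
        assert s.effect("infection").a == pytest.approx(0.018866, abs=1e-5)

    def test_missing_mediator_rejected(self):
        t3, t4, t5 = published.replay_tables()
        t3.pop("shock")
        with pytest.raises(ValueError, match="mediator"):
            from_printed_tables(t3, t4, t5)

    def test_serializations(self, tmp_path):
        t3, t4, t5 = published.replay_tables()
        s = from_printed_tables(t3, t4, t5)
        s.to_json(tmp_path / "paths.json")
        el = s.edge_list()
        assert len(el["edges"]) == 4 * len(s.effects)
        table = s.format_table()
        assert "TOTAL" in table and "infection" in table
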