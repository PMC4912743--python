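"""Per-site regression screen: OLS fits, Bonferroni, best-fit replacement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from prefscan import (
    AMINO_ACIDS,
    DescriptorTable,
    DescriptorCatalog,
    FitModel,
    ScreenConfig,
    SiteFit,
    SiteRecord,
    bonferroni,
    fit_descriptor,
    replace_if_better,
    response_values,
    screen_site,
    screen_table,
    gen_null_table,
    gen_planted_table,
    load_catalog,
)
from prefscan.reporting import sequence_map


def _site_from_response(y, metric="ddg"):
    """Build a SiteRecord whose response (higher = favored) equals y."""
    y = np.asarray(y, dtype=float)
    if metric == "ddg":
        wt = int(np.argmax(y))
        prefs = dict(zip(AMINO_ACIDS, (-(y - y[wt])).tolist()))
        return SiteRecord(AMINO_ACIDS[wt], 1, prefs)
    return SiteRecord(AMINO_ACIDS[int(np.argmax(y))], 1,
                      dict(zip(AMINO_ACIDS, y.tolist())))


# ---------------------------------------------------------------------------
# response_values


def test_response_negates_ddg():
    prefs = dict.fromkeys(AMINO_ACIDS, 0.0)
    prefs["A"] = 1.0
    site = SiteRecord("L", 1, prefs)
    resp = response_values(site, "ddg")
    assert resp["L"] == 0.0 and resp["A"] == -1.0


def test_response_identity_for_preferences():
    prefs = dict(zip(AMINO_ACIDS, np.linspace(0, 1, 20).tolist()))
    site = SiteRecord("Y", 1, prefs)
    assert response_values(site, "preference") == prefs


def test_favored_substitution_scores_above_wildtype():
    prefs = dict.fromkeys(AMINO_ACIDS, 0.0)
    prefs["V"] = -2.0  # stabilising substitution
    resp = response_values(SiteRecord("L", 1, prefs), "ddg")
    assert resp["V"] == 2.0 > resp["L"]


# ---------------------------------------------------------------------------
# fit_descriptor


def test_perfect_linear_dependence(catalog):
    desc = catalog.get("hydrophobicity")
    response = {a: 2.0 * v + 1.0 for a, v in desc.values.items()}
    model = fit_descriptor(response, desc, order=1)
    assert model.r == pytest.approx(1.0)
    assert model.rmse == pytest.approx(0.0, abs=1e-10)
    assert model.p_raw < 1e-12
    assert model.slope == pytest.approx(2.0)


def test_constant_response_is_degenerate(catalog):
    desc = catalog.get("volume")
    model = fit_descriptor(dict.fromkeys(AMINO_ACIDS, 3.0), desc)
    assert model.p_raw == 1.0
    assert model.slope == 0.0


def test_linear_p_matches_correlation_t_test(catalog):
    """Overall-F route agrees with the closed-form correlation test."""
    rng = np.random.default_rng(23)
    desc = catalog.get("volume")
    x = desc.as_array()
    for _ in range(20):
        y = rng.normal(size=20)
        model = fit_descriptor(dict(zip(AMINO_ACIDS, y.tolist())), desc)
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(18.0) / np.sqrt(1.0 - r * r)
        p_oracle = 2.0 * stats.t.sf(abs(t), 18)
        assert model.p_raw == pytest.approx(p_oracle, rel=1e-10)


def test_p_value_agrees_with_permutation_oracle(catalog):
    """Noisy hydrophobicity-shaped response: parametric p within Monte-Carlo
    error of a label-shuffle permutation p."""
    desc = catalog.get("hydrophobicity")
    x = desc.as_array()
    rng = np.random.default_rng(42)
    y = x + rng.normal(0.0, 0.5 * np.std(x), size=20)
    model = fit_descriptor(dict(zip(AMINO_ACIDS, y.tolist())), desc)

    n_perm = 20_000
    perms = np.tile(y, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    xc = x - x.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_perm = (pc @ xc) / (np.linalg.norm(pc, axis=1) * np.linalg.norm(xc))
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    p_perm = (np.sum(np.abs(r_perm) >= r_obs) + 1) / (n_perm + 1)
    mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(model.p_raw - p_perm) <= 3 * mc_sd + 1e-12


def test_quadratic_never_worse_than_nested_linear(catalog):
    rng = np.random.default_rng(31)
    for desc in catalog.by_set(1):
        y = rng.normal(size=20)
        resp = dict(zip(AMINO_ACIDS, y.tolist()))
        lin = fit_descriptor(resp, desc, order=1)
        quad = fit_descriptor(resp, desc, order=2)
        assert quad.rmse <= lin.rmse + 1e-12


# ---------------------------------------------------------------------------
# bonferroni / replace_if_better


@pytest.mark.parametrize("p,n,expected", [
    (0.001, 8, 0.008),
    (0.2, 10, 1.0),
    (0.37, 1, 0.37),
])
def test_bonferroni(p, n, expected):
    assert bonferroni(p, n) == pytest.approx(expected)


def _fit(rmse, order=1, n=20, residue=1, descriptor="d"):
    return SiteFit(residue, descriptor,
                   FitModel(order, (0.0,) * (order + 1), r=0.5, rmse=rmse,
                            p_raw=0.001, p_adj=0.01, n_points=n),
                   trend="positive")


def test_equal_rmse_keeps_incumbent():
    inc, cha = _fit(0.5, descriptor="a"), _fit(0.5, descriptor="b")
    assert replace_if_better(inc, cha, 0.05) is inc


def test_replacement_decision_matches_f_distribution_oracle():
    """rmse halved on 20-point linear fits: F = 4 on (18, 18) df."""
    inc, cha = _fit(1.0, descriptor="a"), _fit(0.5, descriptor="b")
    # independent tail probability via the regularized incomplete beta
    f = 4.0
    d1 = d2 = 18
    sf = special.betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * f))
    decision = replace_if_better(inc, cha, f_alpha=0.05)
    assert sf < 0.05  # the oracle says the improvement is significant
    assert decision is cha
    # and with a cutoff tighter than the tail probability, incumbent survives
    assert replace_if_better(inc, cha, f_alpha=sf * 0.5) is inc


def test_marginal_improvement_keeps_incumbent():
    inc, cha = _fit(1.0, descriptor="a"), _fit(0.95, descriptor="b")
    assert replace_if_better(inc, cha, 0.05) is inc


# ---------------------------------------------------------------------------
# screen_site / screen_table


def test_planted_descriptor_wins_screen(catalog):
    desc = catalog.get("volume")
    y = 0.8 * desc.as_array()
    site = _site_from_response(y)
    cfg = ScreenConfig(selected_sets={1}, metric_kind="ddg")
    retained, best = screen_site(site, catalog, cfg)
    assert best is not None
    assert best.descriptor_id == "volume"
    assert best.trend == "positive"
    assert any(f.descriptor_id == "volume" for f in retained)


def test_negative_slope_classified_negative_trend(catalog):
    desc = catalog.get("flexibility")
    site = _site_from_response(-1.2 * desc.as_array())
    cfg = ScreenConfig(selected_sets={1}, metric_kind="ddg")
    _, best = screen_site(site, catalog, cfg)
    assert best.descriptor_id == "flexibility"
    assert best.trend == "negative"


def test_non_significant_fits_never_enter_best(catalog):
    rng = np.random.default_rng(2)
    cfg = ScreenConfig(selected_sets={1}, metric_kind="ddg")
    for _ in range(20):
        site = _site_from_response(rng.normal(size=20))
        retained, best = screen_site(site, catalog, cfg)
        if best is not None:
            assert best in retained
        for fit in retained:
            assert fit.model.p_adj <= cfg.alpha


def test_conserved_site_is_degenerate(catalog):
    y = np.zeros(20)
    y[0] = 5.0  # two distinct response values only
    site = _site_from_response(y)
    cfg = ScreenConfig(selected_sets={1}, metric_kind="ddg")
    retained, best = screen_site(site, catalog, cfg)
    assert retained == [] and best is None


def test_p_adj_at_least_p_raw_and_alpha_monotonicity(catalog):
    rng = np.random.default_rng(12)
    desc = catalog.get("hydrophobicity")
    x = desc.as_array()
    site = _site_from_response(x + rng.normal(0, np.std(x), 20))
    loose = ScreenConfig(alpha=0.5, selected_sets={1}, metric_kind="ddg")
    tight = ScreenConfig(alpha=0.01, selected_sets={1}, metric_kind="ddg")
    retained_loose, _ = screen_site(site, catalog, loose)
    retained_tight, _ = screen_site(site, catalog, tight)
    for fit in retained_loose:
        assert fit.model.p_adj >= fit.model.p_raw
    keys = {(f.descriptor_id, f.model.order) for f in retained_tight}
    assert keys <= {(f.descriptor_id, f.model.order) for f in retained_loose}


@given(a=st.floats(min_value=0.05, max_value=20.0),
       b=st.floats(min_value=-50.0, max_value=50.0),
       flip=st.booleans())
@settings(max_examples=30, deadline=None)
def test_affine_invariance_of_fit_statistics(a, b, flip):
    catalog = load_catalog()
    desc = catalog.get("volume")
    scale = -a if flip else a
    transformed = DescriptorTable("t", "T", 1,
                                  {k: scale * v + b
                                   for k, v in desc.values.items()})
    rng = np.random.default_rng(99)
    y = dict(zip(AMINO_ACIDS,
                 (desc.as_array() + rng.normal(0, 30, 20)).tolist()))
    m0 = fit_descriptor(y, desc)
    m1 = fit_descriptor(y, transformed)
    assert m1.r == pytest.approx(m0.r, abs=1e-9)
    assert m1.rmse == pytest.approx(m0.rmse, rel=1e-6, abs=1e-9)
    assert m1.p_raw == pytest.approx(m0.p_raw, rel=1e-6, abs=1e-12)
    sign0 = np.sign(m0.slope)
    sign1 = np.sign(m1.slope)
    assert sign1 == (-sign0 if flip else sign0)


def test_quadratic_screen_doubles_bonferroni_divisor(catalog):
    desc = catalog.get("volume")
    x = desc.as_array()
    rng = np.random.default_rng(4)
    site = _site_from_response(x + rng.normal(0, np.std(x) / 3, 20))
    lin_cfg = ScreenConfig(alpha=1.0, selected_sets={1}, metric_kind="ddg")
    quad_cfg = ScreenConfig(alpha=1.0, selected_sets={1}, metric_kind="ddg",
                            quadratic=True)
    retained_lin, _ = screen_site(site, catalog, lin_cfg)
    retained_quad, _ = screen_site(site, catalog, quad_cfg)
    by_id = {(f.descriptor_id, f.model.order): f for f in retained_quad}
    for fit in retained_lin:
        twin = by_id[(fit.descriptor_id, 1)]
        assert twin.model.p_adj == pytest.approx(
            min(1.0, 2.0 * fit.model.p_adj), rel=1e-12)


def test_screen_table_is_deterministic(catalog):
    table1, _ = gen_planted_table(20, "p_sheet", 1.0, 0.3, seed=6)
    table2, _ = gen_planted_table(20, "p_sheet", 1.0, 0.3, seed=6)
    cfg = ScreenConfig(selected_sets={1}, metric_kind="ddg")
    rep1 = screen_table(table1, catalog, cfg)
    rep2 = screen_table(table2, catalog, cfg)
    assert sequence_map(rep1) == sequence_map(rep2)


def test_null_table_family_wise_error_controlled(catalog):
    """Fraction of pure-noise sites with any retained Set-1 fit stays below
    alpha plus 3 binomial standard deviations."""
    table = gen_null_table(300, 1.0, seed=101)
    cfg = ScreenConfig(alpha=0.05, selected_sets={1}, metric_kind="ddg")
    report = screen_table(table, catalog, cfg)
    frac = len(report.best_fits) / len(table)
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(table))
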