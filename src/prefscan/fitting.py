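"""Per-site descriptor screening with family-wise error control.

For each site the 20 amino acid responses (preferences, or negated ddG so
that higher always means more favored) are regressed on each descriptor
scale by ordinary least squares.  Raw p-values come from the overall
regression F-test (for a linear fit this equals the two-sided t-test on the
slope); they are Bonferroni-adjusted by the number of models screened per
site.  Among the significant fits, the best descriptor is chosen by scanning
in catalog order (Set 1 first) and replacing the incumbent only when a
challenger's residual RMSE is significantly smaller by an F-test — so a
composite or discrete descriptor displaces a simple one only when it truly
fits better.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import stats

from .descriptors import DescriptorCatalog, DescriptorTable
from .preference_io import (
    AMINO_ACIDS,
    PreferenceTable,
    SiteRecord,
    fill_kstar,
)


@dataclass
class ScreenConfig:
    """Screening parameters.

    alpha : family-wise (Bonferroni-adjusted) p-value cutoff per site.
    selected_sets : which descriptor sets to screen (scan order is 1 -> 4).
    quadratic : also fit order-2 polynomials (doubles the Bonferroni divisor).
    r_min / rmse_max : optional extra retention limits on |r| and RMSE.
    f_alpha : significance level of the RMSE-decrease F-test used when the
        best descriptor for a site is challenged by a later one.
    k_low / k_high : tolerance thresholds flagging unexplained sites whose
        k* is extreme (fewer than ~4, or more than ~16, effective amino acids).
    """

    alpha: float = 0.05
    selected_sets: frozenset[int] = frozenset({1})
    quadratic: bool = False
    r_min: float | None = None
    rmse_max: float | None = None
    f_alpha: float = 0.05
    k_low: float = 4.0
    k_high: float = 16.0
    pseudocount: float = 1.0
    metric_kind: str = "preference"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 < self.f_alpha <= 1:
            raise ValueError(f"f_alpha must be in (0, 1], got {self.f_alpha}")
        if not self.k_low < self.k_high:
            raise ValueError("k_low must be below k_high")
        self.selected_sets = frozenset(self.selected_sets)
        if not self.selected_sets <= {1, 2, 3, 4}:
            raise ValueError(f"selected_sets must be within {{1,2,3,4}}, "
                             f"got {sorted(self.selected_sets)}")


@dataclass(frozen=True)
class FitModel:
    """One ordinary-least-squares fit of response on a descriptor."""

    order: int                      # 1 (linear) or 2 (quadratic)
    coefficients: tuple[float, ...]  # (intercept, slope[, quadratic])
    r: float                        # Pearson r between response and fitted
    rmse: float                     # sqrt(mean squared residual)
    p_raw: float
    p_adj: float
    n_points: int

    @property
    def n_coefficients(self) -> int:
        return self.order + 1

    @property
    def slope(self) -> float:
        return self.coefficients[1]


@dataclass(frozen=True)
class SiteFit:
    residue_number: int
    descriptor_id: str
    model: FitModel
    trend: str  # "positive" (higher descriptor values preferred) or "negative"


def response_values(site: SiteRecord, metric_kind: str) -> dict[str, float]:
    """Response on the "higher = more favored" scale, always.

    ddG values are negated (favored substitutions, ddG < 0, map to positive
    responses); direct preferences pass through unchanged.
    """
    if metric_kind == "ddg":
        return {a: -v for a, v in site.preferences.items()}
    if metric_kind == "preference":
        return dict(site.preferences)
    raise ValueError(f"unknown metric_kind {metric_kind!r}")


def fit_descriptor(response: dict[str, float], descriptor: DescriptorTable,
                   order: int = 1) -> FitModel:
    """OLS of the 20 responses on descriptor values (and square if order 2).

    p_raw is the overall regression F-test p-value (identical to the
    two-sided slope t-test when order is 1).  A constant response yields a
    degenerate model with p_raw = 1 that can never be retained.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    y = np.array([response[a] for a in AMINO_ACIDS], dtype=float)
    x = descriptor.as_array()
    return _ols(y, x, order)


def _ols(y: np.ndarray, x: np.ndarray, order: int) -> FitModel:
    n = y.size
    if np.ptp(y) == 0:
        coeffs = (float(y[0]),) + (0.0,) * order
        return FitModel(order, coeffs, r=0.0, rmse=0.0, p_raw=1.0, p_adj=1.0,
                        n_points=n)
    cols = [np.ones(n), x] + ([x * x] if order == 2 else [])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = sst - sse
    p_terms = order                     # regressors beyond the intercept
    df_resid = n - p_terms - 1
    if df_resid <= 0 or sst == 0:
        p_raw = 1.0
    elif sse <= 0:
        p_raw = 0.0                     # exact fit
    else:
        f_stat = (ssr / p_terms) / (sse / df_resid)
        p_raw = float(stats.f.sf(f_stat, p_terms, df_resid))
    rmse = float(np.sqrt(sse / n))
    sd_f = float(np.std(fitted))
    if sd_f == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(y, fitted)[0, 1])
    return FitModel(order, tuple(float(b) for b in beta), r=r, rmse=rmse,
                    p_raw=min(max(p_raw, 0.0), 1.0), p_adj=1.0, n_points=n)


def bonferroni(p_raw: float, n_descriptors: int) -> float:
    """Family-wise adjusted p-value: min(1, n * p)."""
    if n_descriptors < 1:
        raise ValueError("n_descriptors must be >= 1")
    return min(1.0, n_descriptors * p_raw)


def _trend(model: FitModel, descriptor: DescriptorTable,
           response: dict[str, float]) -> str:
    """Trend sign: does the fit favor high or low descriptor values?

    For a linear model this is the slope sign; for a quadratic one the
    Pearson correlation between fitted values and descriptor values is used
    (quadratic fits retained here are curved yet near-monotonic).
    """
    if model.order == 1:
        return "positive" if model.slope >= 0 else "negative"
    x = descriptor.as_array()
    b = model.coefficients
    fitted = b[0] + b[1] * x + b[2] * x * x
    if np.std(fitted) == 0:
        return "positive" if model.slope >= 0 else "negative"
    rho = float(np.corrcoef(fitted, x)[0, 1])
    return "positive" if rho >= 0 else "negative"


def replace_if_better(incumbent: SiteFit, challenger: SiteFit,
                      f_alpha: float = 0.05) -> SiteFit:
    """Keep the incumbent unless the challenger's RMSE decrease is significant.

    Both fits must already satisfy the adjusted p cutoff.  The challenger
    wins iff its RMSE is smaller and the variance ratio
    F = (rmse_inc / rmse_chal)^2 exceeds the upper f_alpha critical value of
    the F distribution on (n - q_inc, n - q_chal) degrees of freedom, q being
    the number of fitted coefficients.  Ties favor the incumbent, i.e. the
    earlier (simpler) descriptor in scan order.
    """
    inc, cha = incumbent.model, challenger.model
    if cha.rmse >= inc.rmse:
        return incumbent
    if cha.rmse == 0.0:
        return challenger  # perfect fit always displaces an imperfect one
    f = (inc.rmse / cha.rmse) ** 2
    df1 = inc.n_points - inc.n_coefficients
    df2 = cha.n_points - cha.n_coefficients
    crit = stats.f.isf(f_alpha, df1, df2)
    return challenger if f > crit else incumbent


def _nested_f_improves(linear: FitModel, quad: FitModel, f_alpha: float) -> bool:
    """Extra-sum-of-squares F-test: is the quadratic term worth keeping?"""
    n = linear.n_points
    sse_lin = linear.rmse ** 2 * n
    sse_quad = quad.rmse ** 2 * n
    df2 = n - quad.n_coefficients
    if sse_quad <= 0:
        return sse_lin > 0
    f = (sse_lin - sse_quad) / (sse_quad / df2)
    return float(stats.f.sf(f, 1, df2)) < f_alpha


def screen_site(site: SiteRecord, catalog: DescriptorCatalog,
                config: ScreenConfig,
                metric_kind: str | None = None
                ) -> tuple[list[SiteFit], SiteFit | None]:
    """Screen one site against all descriptors in the selected sets.

    Returns every retained fit (adjusted p <= alpha and within the optional
    |r| / RMSE limits) and the best fit chosen by the ordered
    replace-if-better scan, or None when nothing is retained.  Sites whose
    response has fewer than 3 distinct values are degenerate for regression
    and yield no fits.
    """
    metric = metric_kind or config.metric_kind
    tables = [t for t in catalog.tables if t.set_id in config.selected_sets]
    if not tables:
        raise ValueError("no descriptors in the selected sets")
    n_models = len(tables) * (2 if config.quadratic else 1)

    response = response_values(site, metric)
    y = np.array([response[a] for a in AMINO_ACIDS])
    if np.unique(y).size < 3:
        return [], None

    retained: list[SiteFit] = []
    best: SiteFit | None = None
    for desc in tables:
        for model in _candidate_models(response, desc, config):
            model = dc_replace(model, p_adj=bonferroni(model.p_raw, n_models))
            if model.p_adj > config.alpha:
                continue
            if config.r_min is not None and abs(model.r) < config.r_min:
                continue
            if config.rmse_max is not None and model.rmse > config.rmse_max:
                continue
            fit = SiteFit(site.residue_number, desc.descriptor_id, model,
                          trend=_trend(model, desc, response))
            retained.append(fit)
            best = fit if best is None else replace_if_better(best, fit,
                                                              config.f_alpha)
    return retained, best


def _candidate_models(response: dict[str, float], desc: DescriptorTable,
                      config: ScreenConfig) -> list[FitModel]:
    linear = fit_descriptor(response, desc, order=1)
    if not config.quadratic:
        return [linear]
    quad = fit_descriptor(response, desc, order=2)
    # Offer the quadratic only when the extra term genuinely helps; the
    # nested comparison keeps the simpler model otherwise.
    if _nested_f_improves(linear, quad, config.f_alpha):
        return [linear, quad]
    return [linear]


def screen_table(table: PreferenceTable, catalog: DescriptorCatalog,
                 config: ScreenConfig):
    """Screen every site of a table; returns an AnalysisReport.

    Missing k* values are computed from the preferences first.  The result is
    deterministic given inputs and configuration.
    """
    from .reporting import AnalysisReport, classify_sites  # avoid import cycle

    fill_kstar(table)
    all_fits: list[SiteFit] = []
    best_fits: dict[int, SiteFit] = {}
    for site in table.sites:
        retained, best = screen_site(site, catalog, config, table.metric_kind)
        all_fits.extend(retained)
        if best is not None:
            best_fits[site.residue_number] = best
    report = AnalysisReport(table=table, catalog=catalog, config=config,
                            all_fits=all_fits, best_fits=best_fits)
    report.classes = classify_sites(report, config.k_low, config.k_high)
    return report
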