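"""Maximum-likelihood fitting and AIC candidate-set model selection.

Every combination of the optional parameter groups (elevation form of the
peak day, elevation slope of the duration, and the three yearly effect
groups) defines one candidate model; the full candidate set has
3 * 2^4 = 48 members.  Each candidate is fitted by bounded quasi-Newton
maximization of the negative-binomial log-likelihood on a transformed
parameter scale (logs for positive parameters, Y-1 free values per yearly
group with the last year set to minus their sum, which enforces the
sum-to-zero constraint exactly).  Candidates are then compared by AIC:
a model is retained when its AIC is within 6 of the minimum and no model
with strictly fewer parameters has a lower AIC; inference is based on the
simplest retained model, and a parameter group has *strong support* when
it is active in every retained model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, psi

from .errors import InsufficientDataError, SelectionError
from .model_core import (
    MEAN_FLOOR,
    PARAMETER_GROUPS,
    POISSON_PHI_THRESHOLD,
    ElevationScaler,
    ModelSpec,
    ParameterSet,
    SurveyDataset,
    _nb_logpmf,
)

__all__ = [
    "FitResult",
    "SelectionResult",
    "enumerate_candidates",
    "fit",
    "fit_candidates",
    "select",
    "DELTA_AIC_WINDOW",
]

logger = logging.getLogger(__name__)

#: Retention window: candidates within this many AIC units of the minimum
#: stay in the candidate set (subject to the simpler-model rule).
DELTA_AIC_WINDOW = 6.0

_PENALTY = 1e12  # returned by the objective for infeasible parameter regions


@dataclass
class FitResult:
    """One fitted candidate model."""

    spec: ModelSpec
    params: ParameterSet
    log_likelihood: float
    n_params: int
    aic: float
    converged: bool
    n_restarts_used: int
    scaler: ElevationScaler

    @property
    def label(self) -> str:
        return self.spec.label


@dataclass
class SelectionResult:
    """Outcome of AIC candidate-set selection over all fitted candidates."""

    all_fits: list[FitResult]
    retained: list[FitResult]
    inference_fit: FitResult
    strong_support: dict[str, bool] = field(default_factory=dict)

    @property
    def min_aic(self) -> float:
        return min(f.aic for f in self.all_fits)


def enumerate_candidates() -> list[ModelSpec]:
    """All 48 combinations of optional parameter groups.

    The quadratic elevation form nests the linear term by construction, so
    no invalid (h2 without h1) combination is generated.
    """
    specs = []
    for form, g, q, r, u in itertools.product(
        ("constant", "linear", "quadratic"),
        (False, True),
        (False, True),
        (False, True),
        (False, True),
    ):
        specs.append(
            ModelSpec(
                elevation_peak_form=form,
                duration_elevation=g,
                year_peak=q,
                year_duration=r,
                year_abundance=u,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Parameter-vector packing.  Layout (S sites, Y years):
#   [log n_1 .. log n_S, d*/DAY_SCALE, log s_d, log phi,
#    h1?, h2?, g?, Q_1..Q_{Y-1}/DAY_SCALE?, R_1..R_{Y-1}?, U_1..U_{Y-1}?]
# Optional blocks appear only when active in the spec.  Day-valued
# parameters are divided by DAY_SCALE in the packed vector so all
# coordinates have comparable curvature (L-BFGS-B has no internal
# scaling).
# ---------------------------------------------------------------------------

_DAY_SCALE = 25.0


class _FitContext:
    """Precomputed arrays for one dataset, shared across all candidate
    specs so the likelihood stays cheap inside the optimizer."""

    def __init__(self, data: SurveyDataset, scaler: ElevationScaler):
        self.data = data
        self.scaler = scaler
        self.sites = data.sites
        self.years = data.years
        frame = data.frame
        site_index = {s: i for i, s in enumerate(self.sites)}
        year_index = {y: i for i, y in enumerate(self.years)}
        self.site_idx = frame["site_id"].map(site_index).to_numpy()
        self.year_idx = frame["year"].map(year_index).to_numpy()
        self.day = frame["day"].to_numpy(dtype=float)
        self.count = frame["count"].to_numpy(dtype=float)
        elev = np.array([data.site_elevations[s] for s in self.sites])
        self.z_site = scaler.transform(elev)
        self.z = self.z_site[self.site_idx]
        # Count-weighted day moments seed d* and s_d.
        total = self.count.sum()
        if total > 0:
            mu = float(np.sum(self.count * self.day) / total)
            sd = float(np.sqrt(np.sum(self.count * (self.day - mu) ** 2) / total))
        else:
            mu, sd = float(np.mean(self.day)), 14.0
        self.init_peak_day = mu
        self.init_duration_sd = max(sd, 3.0)
        peaks = np.ones(len(self.sites))
        for i in range(len(self.sites)):
            mask = self.site_idx == i
            if mask.any():
                peaks[i] = max(float(self.count[mask].max()), 1.0)
        self.init_site_peaks = peaks


def _layout(spec: ModelSpec, n_sites: int, n_years: int):
    """Slice positions of each block in the packed vector."""
    pos = n_sites + 3
    layout = {"peaks": slice(0, n_sites), "d": n_sites, "sd": n_sites + 1,
              "phi": n_sites + 2}
    for name, active in (
        ("h1", spec.h1_active),
        ("h2", spec.h2_active),
        ("g", spec.duration_elevation),
    ):
        if active:
            layout[name] = pos
            pos += 1
    for name, active in (
        ("Q", spec.year_peak),
        ("R", spec.year_duration),
        ("U", spec.year_abundance),
    ):
        if active:
            layout[name] = slice(pos, pos + n_years - 1)
            pos += n_years - 1
    layout["size"] = pos
    return layout


def _year_effects(x, sl) -> np.ndarray:
    free = x[sl]
    return np.concatenate([free, [-free.sum()]])


def _make_nll(ctx: _FitContext, spec: ModelSpec, layout):
    """Negative log-likelihood (up to the count-only constant) with its
    analytic gradient on the transformed parameter scale.

    The gradient uses the chain rule through the per-record mean
    ``nbar``: every mean-dependent block reduces to weighted sums of
    ``G = nbar * d(ll)/d(nbar)``, with records whose mean sits on the
    floor excluded (the floored objective is flat there).  Sum-to-zero
    yearly groups are differentiated through the last-year-equals-minus-
    sum construction.
    """
    n_sites = len(ctx.sites)
    n_years = len(ctx.years)
    zeros_y = np.zeros(n_years)
    site_idx, year_idx = ctx.site_idx, ctx.year_idx
    day, count, z = ctx.day, ctx.count, ctx.z
    z2 = z * z
    n_free = max(n_years - 1, 0)

    def _sum_zero_grad(per_year: np.ndarray) -> np.ndarray:
        return per_year[:n_free] - per_year[-1]

    def nll_grad(x: np.ndarray):
        grad = np.zeros_like(x)
        peaks = np.exp(x[layout["peaks"]])
        d_star = x[layout["d"]] * _DAY_SCALE
        s_d = np.exp(x[layout["sd"]])
        phi = np.exp(x[layout["phi"]])
        h1 = x[layout["h1"]] if "h1" in layout else 0.0
        h2 = x[layout["h2"]] if "h2" in layout else 0.0
        g = x[layout["g"]] if "g" in layout else 0.0
        Q = _year_effects(x, layout["Q"]) * _DAY_SCALE if "Q" in layout else zeros_y
        R = _year_effects(x, layout["R"]) if "R" in layout else zeros_y
        U = _year_effects(x, layout["U"]) if "U" in layout else zeros_y

        width = 1.0 + g * ctx.z_site
        if np.any(width <= 1e-6):
            return _PENALTY, grad
        elev_factor = 1.0 + h1 * z + h2 * z2
        dbar = d_star * elev_factor
        s_eff = s_d * width[site_idx] * np.exp(R[year_idx])
        dev = (day - dbar - Q[year_idx]) / s_eff
        raw = peaks[site_idx] * np.exp(U[year_idx]) * np.exp(-0.5 * dev * dev)
        nbar = np.maximum(raw, MEAN_FLOOR)
        floored = raw < MEAN_FLOOR

        if phi < POISSON_PHI_THRESHOLD:
            ll = np.sum(count * np.log(nbar) - nbar)  # gammaln(n+1) is constant
            G = count - nbar  # nbar * dll/dnbar for the Poisson
            grad_phi = 0.0
        else:
            a = nbar / phi
            log1p_phi = np.log1p(phi)
            psi_diff = psi(count + a) - psi(a) - log1p_phi
            ll = np.sum(
                gammaln(count + a) - gammaln(a) - a * log1p_phi
            ) - np.log1p(1.0 / phi) * count.sum()
            G = a * psi_diff
            grad_phi = -float(
                np.sum(-G - a * (phi / (1.0 + phi)) + count / (1.0 + phi))
            )
        if not np.isfinite(ll):
            return _PENALTY, grad

        G = np.where(floored, 0.0, G)
        grad[layout["phi"]] = grad_phi

        # d(ll)/d(theta) for mean-dependent blocks; all sums are over
        # records, negated at the end since we minimise -ll.
        grad[layout["peaks"]] = -np.bincount(site_idx, weights=G, minlength=n_sites)
        Gdev_s = G * dev / s_eff
        grad[layout["d"]] = -float(np.sum(Gdev_s * elev_factor)) * _DAY_SCALE
        Gdev2 = G * dev * dev
        grad[layout["sd"]] = -float(np.sum(Gdev2))
        if "h1" in layout:
            grad[layout["h1"]] = -float(np.sum(Gdev_s * d_star * z))
        if "h2" in layout:
            grad[layout["h2"]] = -float(np.sum(Gdev_s * d_star * z2))
        if "g" in layout:
            grad[layout["g"]] = -float(
                np.sum(Gdev2 * z / width[site_idx])
            )
        if "Q" in layout:
            per_year = np.bincount(year_idx, weights=Gdev_s, minlength=n_years)
            grad[layout["Q"]] = -_sum_zero_grad(per_year) * _DAY_SCALE
        if "R" in layout:
            per_year = np.bincount(year_idx, weights=Gdev2, minlength=n_years)
            grad[layout["R"]] = -_sum_zero_grad(per_year)
        if "U" in layout:
            per_year = np.bincount(year_idx, weights=G, minlength=n_years)
            grad[layout["U"]] = -_sum_zero_grad(per_year)
        return -ll, grad

    return nll_grad


def _constant_term(count: np.ndarray) -> float:
    """Count-only part of the log-likelihood dropped inside the optimizer."""
    return float(-np.sum(gammaln(count + 1.0)))


def _bounds(spec: ModelSpec, layout, n_sites: int) -> list[tuple[float, float]]:
    bounds: list[tuple[float, float]] = [(-7.0, 20.0)] * n_sites
    bounds += [
        (1.0 / _DAY_SCALE, 366.0 / _DAY_SCALE),
        (np.log(0.5), np.log(150.0)),
        (-12.0, 8.0),
    ]
    for name in ("h1", "h2", "g"):
        if name in layout:
            bounds.append((-2.0, 2.0))
    for name, (lo, hi) in (
        ("Q", (-60.0 / _DAY_SCALE, 60.0 / _DAY_SCALE)),
        ("R", (-5.0, 5.0)),
        ("U", (-5.0, 5.0)),
    ):
        if name in layout:
            sl = layout[name]
            bounds += [(lo, hi)] * (sl.stop - sl.start)
    return bounds


def _initial_vector(ctx: _FitContext, spec: ModelSpec, layout) -> np.ndarray:
    x0 = np.zeros(layout["size"])
    x0[layout["peaks"]] = np.log(ctx.init_site_peaks)
    x0[layout["d"]] = ctx.init_peak_day / _DAY_SCALE
    x0[layout["sd"]] = np.log(ctx.init_duration_sd)
    x0[layout["phi"]] = 0.0  # phi = 1
    return x0


def _jitter(x0: np.ndarray, ctx: _FitContext, layout, rng: np.random.Generator):
    x = x0.copy()
    n_sites = len(ctx.sites)
    x[layout["peaks"]] += rng.normal(0.0, 0.3, n_sites)
    x[layout["d"]] += rng.normal(0.0, 3.0 / _DAY_SCALE)
    x[layout["sd"]] += rng.normal(0.0, 0.15)
    x[layout["phi"]] += rng.normal(0.0, 0.5)
    for name in ("h1", "h2", "g"):
        if name in layout:
            x[layout[name]] += rng.normal(0.0, 0.01)
    for name, sd in (("Q", 2.0 / _DAY_SCALE), ("R", 0.1), ("U", 0.1)):
        if name in layout:
            sl = layout[name]
            x[sl] += rng.normal(0.0, sd, sl.stop - sl.start)
    return x


def _unpack(x: np.ndarray, ctx: _FitContext, layout) -> ParameterSet:
    years = ctx.years

    def effect_map(name, scale=1.0):
        if name not in layout:
            return {}
        eff = _year_effects(x, layout[name]) * scale
        eff = eff - eff.mean()  # exact sum-to-zero despite float round-off
        return dict(zip(years, eff.tolist()))

    return ParameterSet(
        site_peaks=dict(zip(ctx.sites, np.exp(x[layout["peaks"]]).tolist())),
        peak_day=float(x[layout["d"]]) * _DAY_SCALE,
        duration_sd=float(np.exp(x[layout["sd"]])),
        overdispersion=float(np.exp(x[layout["phi"]])),
        h1=float(x[layout["h1"]]) if "h1" in layout else 0.0,
        h2=float(x[layout["h2"]]) if "h2" in layout else 0.0,
        g=float(x[layout["g"]]) if "g" in layout else 0.0,
        Q=effect_map("Q", _DAY_SCALE),
        R=effect_map("R"),
        U=effect_map("U"),
    )


def fit(
    data: SurveyDataset,
    spec: ModelSpec,
    seed: int,
    n_restarts: int = 5,
    scaler: ElevationScaler | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    Runs ``n_restarts`` bounded L-BFGS-B starts (the first from
    moment-based initial values, the rest jittered with the seeded RNG)
    and keeps the best.  ``converged`` reflects the optimizer's own
    success flag for the winning start.
    """
    data.check_supports(spec)
    if scaler is None:
        scaler = data.scaler()
    ctx = _FitContext(data, scaler)
    return _fit_with_context(ctx, spec, seed, n_restarts, maxiter)


def _fit_with_context(
    ctx: _FitContext,
    spec: ModelSpec,
    seed: int,
    n_restarts: int,
    maxiter: int,
) -> FitResult:
    layout = _layout(spec, len(ctx.sites), len(ctx.years))
    nll = _make_nll(ctx, spec, layout)
    bounds = _bounds(spec, layout, len(ctx.sites))
    x0 = _initial_vector(ctx, spec, layout)
    rng = np.random.default_rng(seed)

    best = None
    best_val = np.inf
    n_done = 0
    for restart in range(max(n_restarts, 1)):
        start = x0 if restart == 0 else _jitter(x0, ctx, layout, rng)
        res = minimize(
            nll,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        n_done += 1
        if res.fun < best_val:
            best, best_val = res, res.fun
    assert best is not None

    params = _unpack(best.x, ctx, layout)
    log_lik = -best_val + _constant_term(ctx.count)
    k = spec.n_params(len(ctx.sites), len(ctx.years))
    if not best.success:
        logger.warning("fit of %s did not converge: %s", spec.label, best.message)
    return FitResult(
        spec=spec,
        params=params,
        log_likelihood=log_lik,
        n_params=k,
        aic=2.0 * k - 2.0 * log_lik,
        converged=bool(best.success),
        n_restarts_used=n_done,
        scaler=ctx.scaler,
    )


def fit_candidates(
    data: SurveyDataset,
    seed: int,
    n_restarts: int = 5,
    specs: list[ModelSpec] | None = None,
    maxiter: int = 500,
) -> list[FitResult]:
    """Fit every candidate the dataset can support.

    Candidates whose preconditions fail (e.g. a quadratic elevation form
    with fewer than three distinct elevations) are skipped with a logged
    warning rather than aborting the whole set.  Each candidate gets an
    independent child seed, so the fits do not share optimizer state.
    """
    if specs is None:
        specs = enumerate_candidates()
    scaler = data.scaler()
    ctx = _FitContext(data, scaler)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    fits = []
    for spec, child in zip(specs, child_seeds):
        try:
            data.check_supports(spec)
        except InsufficientDataError as exc:
            logger.warning("skipping %s: %s", spec.label, exc)
            continue
        fits.append(_fit_with_context(ctx, spec, int(child), n_restarts, maxiter))
    return fits


def select(fits: list[FitResult], delta_aic: float = DELTA_AIC_WINDOW) -> SelectionResult:
    """Apply the AIC retention rule and pick the inference model.

    Retained: converged fits with AIC within ``delta_aic`` of the minimum
    for which no fit with strictly fewer parameters has a lower AIC.
    The inference model is the retained fit with fewest parameters (ties
    broken by lower AIC); a group has strong support when it is active in
    every retained fit.
    """
    converged = [f for f in fits if f.converged]
    dropped = len(fits) - len(converged)
    if dropped:
        logger.warning("%d non-convergent fits excluded from selection", dropped)
    if not converged:
        raise SelectionError("no converged fits to select among")

    min_aic = min(f.aic for f in converged)
    retained = []
    for f in converged:
        if f.aic > min_aic + delta_aic:
            continue
        beaten = any(
            other.n_params < f.n_params and other.aic < f.aic for other in converged
        )
        if not beaten:
            retained.append(f)
    inference = min(retained, key=lambda f: (f.n_params, f.aic))
    strong = {
        group: all(group in f.spec.active_groups() for f in retained)
        for group in PARAMETER_GROUPS
    }
    return SelectionResult(
        all_fits=list(fits),
        retained=retained,
        inference_fit=inference,
        strong_support=strong,
    )
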