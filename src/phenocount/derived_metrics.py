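"""Derived phenology and abundance statistics from fitted parameters.

Fitted yearly effects are turned into the quantities ecologists actually
discuss: the proportional year-on-year abundance change
``rho_y = exp(U_y - U_{y-1})``, the flight-window width ``4 * s_d`` (the
interval holding ~95% of a Gaussian flight period), the elevation at
which a negative quadratic elevation effect plateaus, interspecific
concordance in the direction of yearly change, and the Spearman rank
correlation between yearly phenological shift and abundance change.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .fit_select import FitResult
from .model_core import ElevationScaler

__all__ = [
    "YearlyEffects",
    "ConcordanceResult",
    "relative_abundance_change",
    "flight_window_days",
    "plateau_elevation",
    "concordance",
    "phenology_abundance_correlation",
]

logger = logging.getLogger(__name__)

#: Exact permutation p-values are used up to this many pairs (9! is cheap);
#: larger samples fall back to the asymptotic approximation.
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class YearlyEffects:
    """Per-year fitted effects for one species, with derived rho.

    ``rho[y] = exp(U[y] - U[y-1])`` is defined from the second study year
    onward; the first year has no predecessor and is absent from ``rho``.
    """

    species: str
    Q: dict[int, float] = field(default_factory=dict)
    R: dict[int, float] = field(default_factory=dict)
    U: dict[int, float] = field(default_factory=dict)

    @property
    def rho(self) -> dict[int, float]:
        if not self.U:
            return {}
        return relative_abundance_change(self.U)

    @classmethod
    def from_fit(cls, species: str, fit: FitResult) -> "YearlyEffects":
        p = fit.params
        return cls(species=species, Q=dict(p.Q), R=dict(p.R), U=dict(p.U))


def relative_abundance_change(U: Mapping[int, float]) -> dict[int, float]:
    """Proportional abundance change ``rho_y = exp(U_y - U_{y-1})``.

    Requires at least two consecutive years; a gap in the year sequence is
    an error because the ratio would then span more than one generation.
    The first year has no rho.  Over the whole series the product of the
    rho values telescopes to ``exp(U_last - U_first)``.
    """
    years = sorted(int(y) for y in U)
    if len(years) < 2:
        raise InsufficientDataError("rho needs at least two consecutive years")
    gaps = [b for a, b in zip(years, years[1:]) if b != a + 1]
    if gaps:
        raise InvalidParameterError(
            f"year sequence has gaps before {gaps}; rho requires consecutive years"
        )
    return {
        y: math.exp(U[y] - U[y - 1]) for y in years[1:]
    }


def flight_window_days(s_d_star: float) -> float:
    """Width of the flight window holding ~95% of the flight period.

    For a Gaussian flight curve the interval peak-day +/- 2 standard
    deviations contains 95.45% of the season's activity, so the window
    width is ``4 * s_d``.
    """
    if not s_d_star > 0:
        raise InvalidParameterError(f"duration SD must be > 0, got {s_d_star!r}")
    return 4.0 * s_d_star


def plateau_elevation(
    h1: float, h2: float, scaler: ElevationScaler
) -> float | None:
    """Elevation (m) of maximal phenological delay under a quadratic form.

    The peak-day curve ``d*(1 + h1 z + h2 z^2)`` has an interior maximum
    at ``z = -h1 / (2 h2)`` only when ``h2 < 0``; otherwise there is no
    plateau and ``None`` is returned.
    """
    if h2 >= 0:
        return None
    z_star = -h1 / (2.0 * h2)
    return float(scaler.inverse(z_star))


@dataclass
class ConcordanceResult:
    """Interspecific concordance in the direction of yearly change.

    ``per_year`` maps year -> fraction of species whose sign matches the
    sign of the cross-species mean that year.  ``mean_over_years``
    averages those per-year fractions; ``pooled`` instead pools all
    species-year pairs before taking the fraction.  Both aggregations are
    reported because they differ under unbalanced species coverage.
    """

    per_year: dict[int, float]
    mean_over_years: float
    pooled: float

    def __float__(self) -> float:
        return self.mean_over_years


def concordance(values: Mapping[str, Mapping[int, float]]) -> ConcordanceResult:
    """Fraction of species changing in the community's direction each year.

    ``values`` maps species -> year -> signed change (e.g. Q_y, or
    ``ln rho_y`` for growth vs decline).  A species-year value of exactly
    zero matches neither direction; a year whose cross-species mean is
    exactly zero has no community direction and is dropped with a warning.
    """
    if len(values) < 2:
        raise InsufficientDataError("concordance needs at least two species")
    years = sorted({y for series in values.values() for y in series})
    if not years:
        raise InsufficientDataError("concordance needs at least one year")
    per_year: dict[int, float] = {}
    matched_total = 0
    n_total = 0
    for year in years:
        entries = [series[year] for series in values.values() if year in series]
        direction = np.sign(np.mean(entries))
        if direction == 0:
            logger.warning("year %d has zero community mean; skipped", year)
            continue
        matches = sum(1 for v in entries if np.sign(v) == direction)
        per_year[year] = matches / len(entries)
        matched_total += matches
        n_total += len(entries)
    if not per_year:
        raise InsufficientDataError("no year had a nonzero community direction")
    return ConcordanceResult(
        per_year=per_year,
        mean_over_years=float(np.mean(list(per_year.values()))),
        pooled=matched_total / n_total,
    )


@lru_cache(maxsize=4)
def _permutation_ranks(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)


@lru_cache(maxsize=8)
def _perm_null_parts(ranks: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    """All arrangements of a rank multiset, centred, with their norms.

    Cached because the expensive permutation matrix depends only on the
    sample size and the tie pattern, not on the data values.
    """
    n = len(ranks)
    order = (_permutation_ranks(n) - 1).astype(int)
    perms = np.asarray(ranks)[order]
    centred = perms - perms.mean(axis=1, keepdims=True)
    return centred, np.sum(centred**2, axis=1)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks under ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2) * np.sum(ry**2)))
    if denom == 0:
        raise InvalidParameterError("a variable is constant; rank correlation undefined")
    return float(np.sum(rx * ry) / denom)


def phenology_abundance_correlation(
    Q: Mapping[int, float], rho: Mapping[int, float]
) -> tuple[float, float]:
    """Spearman correlation between yearly peak shift and abundance change.

    Pairs Q_y with rho_y over the years where both are defined (rho drops
    the first study year).  Returns ``(rho_s, p)`` with a two-sided exact
    permutation p-value for small samples (n <= 9), where the full
    permutation null is enumerable; larger samples use the asymptotic
    approximation.  Ties receive average ranks.
    """
    years = sorted(set(Q) & set(rho))
    if len(years) < 4:
        raise InsufficientDataError(
            f"need >= 4 paired years for a rank correlation, got {len(years)}"
        )
    x = np.array([Q[y] for y in years], dtype=float)
    y = np.array([rho[y] for y in years], dtype=float)
    if stats.rankdata(x).std() == 0 or stats.rankdata(y).std() == 0:
        raise InvalidParameterError("constant series; rank correlation undefined")
    r_obs = _spearman_rho(x, y)

    n = len(years)
    if n <= EXACT_PERMUTATION_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        if len(set(x)) < n or len(set(y)) < n:
            logger.warning("ties present; average ranks used in the permutation null")
        # With tied data, permute the observed average ranks of y.
        ry_c, ry_norms = _perm_null_parts(tuple(np.sort(ry).tolist()))
        rx_c = rx - rx.mean()
        denom = np.sqrt(np.sum(rx_c**2) * ry_norms)
        r_null = (ry_c @ rx_c) / denom
        p = float(np.mean(np.abs(r_null) >= abs(r_obs) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return r_obs, p
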