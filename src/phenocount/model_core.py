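"""Seasonal count model: Gaussian flight period with negative-binomial observation error.

The model describes per-visit counts of a univoltine (single annual
generation) species surveyed repeatedly within each season at sites spread
over an elevation gradient.  The expected count at site ``i`` on day ``d``
of year ``y`` factorises into a site/year peak abundance and a phenology
weight bounded in (0, 1]::

    nbar(i, y, d) = N(i, y) * T(i, y, d)
    N(i, y)       = n_i * exp(U_y)
    T(i, y, d)    = exp(-1/2 * ((d - dbar_i - Q_y) / s_{d,i,y})^2)

where the peak day and flight-period duration may vary with normalized site
elevation ``z_i``::

    dbar_i    = d_star * (1 + h1 * z_i + h2 * z_i**2)
    s_{d,i,y} = s_d * (1 + g * z_i) * exp(R_y)

The yearly effect groups ``Q_y`` (days of phenological shift), ``R_y``
(log-scale duration change) and ``U_y`` (log-scale abundance change) each
sum to zero over the study years, so they express deviations from the
multi-year average.  Observed counts are negative-binomial with mean
``nbar`` and variance ``(1 + phi) * nbar``; ``phi >= 0`` is the
overdispersion parameter and ``phi -> 0`` recovers the Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidScalerError,
    MissingSiteError,
)

__all__ = [
    "ElevationScaler",
    "ModelSpec",
    "ParameterSet",
    "SurveyDataset",
    "ELEVATION_FORMS",
    "PARAMETER_GROUPS",
    "normalize_elevation",
    "expected_peak_day",
    "phenology_weight",
    "expected_count",
    "nbd_log_probability",
    "total_log_likelihood",
    "MEAN_FLOOR",
    "POISSON_PHI_THRESHOLD",
]

#: Expected counts are floored at this value before entering the NB pmf so
#: that far-from-season zero counts contribute ~0 log-probability, not NaN.
MEAN_FLOOR = 1e-10

#: Below this overdispersion the exact Poisson log-pmf is used instead of the
#: negative-binomial form, whose shape parameter diverges as phi -> 0.
POISSON_PHI_THRESHOLD = 1e-8

ELEVATION_FORMS = ("constant", "linear", "quadratic")

#: Optional parameter groups that model selection may switch off.
PARAMETER_GROUPS = ("h1", "h2", "g", "Q", "R", "U")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ElevationScaler:
    """Affine map from site elevation in metres to a normalized scale.

    ``center`` is the mean site elevation (so the peak day parameter is
    defined at the mean elevation) and ``scale`` the population standard
    deviation of the site elevations, making the elevation coefficients
    dimensionless and comparable across survey designs.
    """

    center: float
    scale: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise InvalidScalerError(
                f"elevation scale must be positive, got {self.scale!r}"
            )

    @classmethod
    def from_elevations(cls, elevations_m: Iterable[float]) -> "ElevationScaler":
        elev = np.asarray(list(elevations_m), dtype=float)
        if elev.size == 0:
            raise InvalidScalerError("no site elevations provided")
        scale = float(np.std(elev))  # population SD over the site design
        if scale <= 0:
            raise InvalidScalerError(
                "all site elevations are equal; elevation cannot be normalized"
            )
        return cls(center=float(np.mean(elev)), scale=scale)

    def transform(self, elevation_m):
        """Metres -> dimensionless z."""
        return (np.asarray(elevation_m, dtype=float) - self.center) / self.scale

    def inverse(self, z):
        """Dimensionless z -> metres."""
        return self.center + self.scale * np.asarray(z, dtype=float)


def normalize_elevation(elevation_m, scaler: ElevationScaler):
    """Normalize an elevation in metres with the fitted scaler."""
    return scaler.transform(elevation_m)


@dataclass(frozen=True)
class ModelSpec:
    """Which optional parameter groups of the count model are active.

    ``elevation_peak_form`` controls how the peak day depends on elevation
    (``constant``: no dependence; ``linear``: h1; ``quadratic``: h1 and h2
    — the quadratic form always nests the linear term).  The booleans
    switch the duration-elevation slope ``g`` and the three yearly effect
    groups on or off.
    """

    elevation_peak_form: str = "constant"
    duration_elevation: bool = False
    year_peak: bool = False
    year_duration: bool = False
    year_abundance: bool = False

    def __post_init__(self) -> None:
        if self.elevation_peak_form not in ELEVATION_FORMS:
            raise InvalidParameterError(
                f"elevation_peak_form must be one of {ELEVATION_FORMS}, "
                f"got {self.elevation_peak_form!r}"
            )

    @property
    def h1_active(self) -> bool:
        return self.elevation_peak_form in ("linear", "quadratic")

    @property
    def h2_active(self) -> bool:
        return self.elevation_peak_form == "quadratic"

    def active_groups(self) -> set[str]:
        groups = set()
        if self.h1_active:
            groups.add("h1")
        if self.h2_active:
            groups.add("h2")
        if self.duration_elevation:
            groups.add("g")
        if self.year_peak:
            groups.add("Q")
        if self.year_duration:
            groups.add("R")
        if self.year_abundance:
            groups.add("U")
        return groups

    def n_params(self, n_sites: int, n_years: int) -> int:
        """Free-parameter count: one peak per site, the four baseline
        parameters minus the site peaks already counted (d*, s_d, phi),
        the active elevation terms, and Y-1 free values per active yearly
        group (the sum-to-zero constraint removes one)."""
        k = n_sites + 3
        k += int(self.h1_active) + int(self.h2_active) + int(self.duration_elevation)
        per_year = max(n_years - 1, 0)
        k += per_year * (
            int(self.year_peak) + int(self.year_duration) + int(self.year_abundance)
        )
        return k

    @property
    def label(self) -> str:
        bits = [self.elevation_peak_form[:4]]
        for flag, name in (
            (self.duration_elevation, "g"),
            (self.year_peak, "Q"),
            (self.year_duration, "R"),
            (self.year_abundance, "U"),
        ):
            if flag:
                bits.append(name)
        return "+".join(bits)


def _as_sum_zero(effects: Mapping[int, float], name: str) -> dict[int, float]:
    eff = {int(y): float(v) for y, v in effects.items()}
    if eff and abs(sum(eff.values())) > _SUM_TOL:
        raise InvalidParameterError(
            f"yearly effects {name} must sum to zero, got sum={sum(eff.values()):g}"
        )
    return eff


@dataclass
class ParameterSet:
    """Full parameter set of the seasonal count model for one species.

    Inactive optional parameters are simply 0 (coefficients) or empty maps
    (yearly effect groups); a year absent from a group contributes 0.
    """

    site_peaks: dict[str, float]
    peak_day: float
    duration_sd: float
    overdispersion: float
    h1: float = 0.0
    h2: float = 0.0
    g: float = 0.0
    Q: dict[int, float] = field(default_factory=dict)
    R: dict[int, float] = field(default_factory=dict)
    U: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site_peaks = {str(s): float(v) for s, v in self.site_peaks.items()}
        for site, peak in self.site_peaks.items():
            if not peak > 0:
                raise InvalidParameterError(
                    f"site peak for {site!r} must be > 0, got {peak:g}"
                )
        if not self.duration_sd > 0:
            raise InvalidParameterError(
                f"duration_sd must be > 0, got {self.duration_sd:g}"
            )
        if self.overdispersion < 0:
            raise InvalidParameterError(
                f"overdispersion must be >= 0, got {self.overdispersion:g}"
            )
        self.Q = _as_sum_zero(self.Q, "Q")
        self.R = _as_sum_zero(self.R, "R")
        self.U = _as_sum_zero(self.U, "U")

    def q(self, year: int) -> float:
        return self.Q.get(year, 0.0)

    def r(self, year: int) -> float:
        return self.R.get(year, 0.0)

    def u(self, year: int) -> float:
        return self.U.get(year, 0.0)


@dataclass
class SurveyDataset:
    """Per-visit counts of one species with site elevations.

    ``frame`` holds one row per visit with columns ``site_id``, ``year``,
    ``day`` (day-of-year, 1-based) and ``count``; missing visits are simply
    absent rows.  ``site_elevations`` maps every site id appearing in the
    records to its elevation in metres.
    """

    frame: pd.DataFrame
    site_elevations: dict[str, float]

    def __post_init__(self) -> None:
        required = {"site_id", "year", "day", "count"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InvalidParameterError(f"survey frame missing columns {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True).copy()
        self.frame["site_id"] = self.frame["site_id"].astype(str)
        self.site_elevations = {
            str(s): float(e) for s, e in self.site_elevations.items()
        }
        for col in ("year", "day", "count"):
            values = self.frame[col].to_numpy()
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise InvalidParameterError(f"column {col!r} must be integer-valued")
            self.frame[col] = self.frame[col].astype(int)
        if (self.frame["count"] < 0).any():
            raise InvalidParameterError("counts must be >= 0")
        days = self.frame["day"]
        if ((days < 1) | (days > 366)).any():
            raise InvalidParameterError("days must lie in [1, 366]")
        unknown = set(self.frame["site_id"]) - set(self.site_elevations)
        if unknown:
            raise MissingSiteError(
                f"records reference sites without elevations: {sorted(unknown)}"
            )

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple],
        site_elevations: Mapping[str, float],
    ) -> "SurveyDataset":
        """Build from ``(site_id, year, day, count)`` tuples."""
        frame = pd.DataFrame(records, columns=["site_id", "year", "day", "count"])
        return cls(frame=frame, site_elevations=dict(site_elevations))

    @property
    def sites(self) -> list[str]:
        return sorted(self.site_elevations)

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def n_distinct_elevations(self) -> int:
        observed = set(self.frame["site_id"])
        return len({self.site_elevations[s] for s in observed})

    def scaler(self) -> ElevationScaler:
        return ElevationScaler.from_elevations(self.site_elevations.values())

    def check_supports(self, spec: ModelSpec) -> None:
        """Raise :class:`InsufficientDataError` if the design cannot
        identify the optional parameters of ``spec``."""
        n_elev = self.n_distinct_elevations()
        n_years = len(self.years)
        if spec.h2_active and n_elev < 3:
            raise InsufficientDataError(
                "quadratic elevation form needs >= 3 distinct elevations"
            )
        if (spec.h1_active or spec.duration_elevation) and n_elev < 2:
            raise InsufficientDataError(
                "elevation effects need >= 2 distinct site elevations"
            )
        if (spec.year_peak or spec.year_duration or spec.year_abundance) and n_years < 2:
            raise InsufficientDataError("yearly effects need >= 2 distinct years")


# ---------------------------------------------------------------------------
# Expected-count machinery.  `_mean_and_sd` is the single shared
# implementation used by the public scalar operations, the likelihood and
# the synthetic-data generator, so simulation and inference cannot drift.
# ---------------------------------------------------------------------------


def _mean_and_sd(day, z, n_peak, params: ParameterSet, q, r, u):
    """Vectorized expected count and effective flight-period SD.

    All of ``day``, ``z``, ``n_peak``, ``q``, ``r``, ``u`` broadcast.
    Returns ``(nbar, s_eff)``; the caller decides how to treat a
    nonpositive ``s_eff`` (error in the public API, penalty inside the
    optimizer).
    """
    day = np.asarray(day, dtype=float)
    z = np.asarray(z, dtype=float)
    dbar = params.peak_day * (1.0 + params.h1 * z + params.h2 * z * z)
    s_eff = params.duration_sd * (1.0 + params.g * z) * np.exp(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (day - dbar - q) / s_eff
        weight = np.exp(-0.5 * dev * dev)
    nbar = n_peak * np.exp(u) * weight
    return nbar, s_eff


def expected_peak_day(z, params: ParameterSet):
    """Expected peak day-of-year at normalized elevation ``z``."""
    z = np.asarray(z, dtype=float)
    result = params.peak_day * (1.0 + params.h1 * z + params.h2 * z * z)
    return result if result.ndim else float(result)


def phenology_weight(day, z, year: int, params: ParameterSet):
    """Gaussian phenology weight in (0, 1]; equals 1 at the peak day.

    Raises :class:`InvalidParameterError` when the effective flight-period
    SD at this elevation/year is nonpositive (possible when ``g*z <= -1``).
    """
    q, r = params.q(year), params.r(year)
    dbar = expected_peak_day(z, params)
    s_eff = params.duration_sd * (1.0 + params.g * np.asarray(z, dtype=float)) * math.exp(r)
    if np.any(s_eff <= 0):
        raise InvalidParameterError(
            f"effective duration SD is nonpositive at z={z!r} (g={params.g:g})"
        )
    dev = (np.asarray(day, dtype=float) - dbar - q) / s_eff
    result = np.exp(-0.5 * dev * dev)
    return result if np.ndim(result) else float(result)


def expected_count(
    site_id: str,
    elevation_m: float,
    year: int,
    day,
    params: ParameterSet,
    scaler: ElevationScaler,
):
    """Expected count for one site visit, ``n_i * exp(U_y) * T``."""
    site_id = str(site_id)
    if site_id not in params.site_peaks:
        raise MissingSiteError(f"no peak-abundance parameter for site {site_id!r}")
    z = scaler.transform(elevation_m)
    nbar, s_eff = _mean_and_sd(
        day, z, params.site_peaks[site_id], params,
        params.q(year), params.r(year), params.u(year),
    )
    if np.any(s_eff <= 0):
        raise InvalidParameterError(
            f"effective duration SD is nonpositive for site {site_id!r}"
        )
    return nbar if nbar.ndim else float(nbar)


def _nb_logpmf(n, mean, phi: float):
    """Negative-binomial log-pmf with mean ``mean`` and variance
    ``(1+phi)*mean`` (shape a = mean/phi, b = 1/phi); exact Poisson below
    the phi threshold."""
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if phi < POISSON_PHI_THRESHOLD:
        return n * np.log(mean) - mean - gammaln(n + 1.0)
    a = mean / phi
    return (
        gammaln(n + a)
        - gammaln(n + 1.0)
        - gammaln(a)
        - a * np.log1p(phi)
        - n * np.log1p(1.0 / phi)
    )


def nbd_log_probability(n, mean, phi: float):
    """Log-probability of count ``n`` under the NB observation model.

    ``mean`` must be positive (callers floor tiny means at
    :data:`MEAN_FLOOR`); ``phi >= 0`` with the Poisson limit taken exactly
    for very small ``phi``.
    """
    n_arr = np.asarray(n)
    if np.any(np.mod(n_arr, 1) != 0) or np.any(n_arr < 0):
        raise InvalidParameterError("counts must be nonnegative integers")
    if phi < 0:
        raise InvalidParameterError(f"phi must be >= 0, got {phi:g}")
    mean_arr = np.asarray(mean, dtype=float)
    if np.any(mean_arr <= 0):
        raise InvalidParameterError("mean must be > 0 (apply the floor upstream)")
    result = _nb_logpmf(n_arr, mean_arr, phi)
    return result if result.ndim else float(result)


def total_log_likelihood(
    data: SurveyDataset,
    params: ParameterSet,
    scaler: ElevationScaler,
) -> float:
    """Log-likelihood of all counts: sum of NB log-pmfs over every visit."""
    frame = data.frame
    site_ids = frame["site_id"].to_numpy()
    missing = set(site_ids) - set(params.site_peaks)
    if missing:
        raise MissingSiteError(f"no peak parameters for sites {sorted(missing)}")
    elev = np.array([data.site_elevations[s] for s in site_ids])
    z = scaler.transform(elev)
    n_peak = np.array([params.site_peaks[s] for s in site_ids])
    years = frame["year"].to_numpy()
    q = np.array([params.q(y) for y in years])
    r = np.array([params.r(y) for y in years])
    u = np.array([params.u(y) for y in years])
    nbar, s_eff = _mean_and_sd(frame["day"].to_numpy(), z, n_peak, params, q, r, u)
    if np.any(s_eff <= 0):
        raise InvalidParameterError(
            "effective duration SD nonpositive for at least one site/year"
        )
    nbar = np.maximum(nbar, MEAN_FLOOR)
    return float(
        np.sum(_nb_logpmf(frame["count"].to_numpy(), nbar, params.overdispersion))
    )
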