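"""Climate-driver regressions for yearly phenology and abundance effects.

Monthly weather-station records are summarised into twelve candidate
predictors per study year y: mean temperatures for January–June of year y
(T_Jan..T_Jun) and quarterly rainfall totals spanning July of year y-1
through June of year y (R1a and R1b: Jul–Sep of y-1 at the primary and
secondary stations; R2: Oct–Dec of y-1; R3: Jan–Mar of y; R4: Apr–Jun of
y).  Each species' yearly effect series (Q_y or rho_y) is regressed on
every predictor subset of size 0–3 with Gaussian errors under identity
and, optionally, inverse links; the same AIC retention rule used for the
count model picks the most parsimonious subset.  Predictors are z-scored
so coefficients are comparable effect sizes; note that under the inverse
link the sign of a coefficient is reversed relative to the direction of
its effect on the mean.

The community-level phenology sensitivity regresses the cross-species
mean Q_y on raw (not z-scored) mean March–June temperature, so its slope
is in days per degree Celsius.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import InsufficientDataError, InvalidParameterError, MissingClimateError
from .fit_select import DELTA_AIC_WINDOW

__all__ = [
    "ClimateTable",
    "DriverModelResult",
    "CommunitySlopeResult",
    "PREDICTOR_NAMES",
    "build_climate_table",
    "fit_driver_models",
    "community_phenology_slope",
    "VIF_WARN_THRESHOLD",
]

logger = logging.getLogger(__name__)

PREDICTOR_NAMES = (
    "R1a", "R1b", "R2", "R3", "R4",
    "T_Jan", "T_Feb", "T_Mar", "T_Apr", "T_May", "T_Jun",
)
# R1b exists only when a secondary station is supplied, so the realised
# pool is 11 or 12 predictors.

_TEMP_MONTHS = {"T_Jan": 1, "T_Feb": 2, "T_Mar": 3, "T_Apr": 4, "T_May": 5, "T_Jun": 6}

#: Variance-inflation factors above this trigger a recorded warning
#: (conservative collinearity screen); predictors are never auto-dropped.
VIF_WARN_THRESHOLD = 3.0

MAX_PREDICTORS = 3


@dataclass
class ClimateTable:
    """Per-study-year climate predictors, one row per year."""

    frame: pd.DataFrame  # indexed by year

    def __post_init__(self) -> None:
        self.frame = self.frame.sort_index()

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.frame.index]

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.frame.columns if c in PREDICTOR_NAMES]

    def mean_march_june_temperature(self) -> pd.Series:
        """Raw-degree mean of T_Mar..T_Jun per year (deg C)."""
        return self.frame[["T_Mar", "T_Apr", "T_May", "T_Jun"]].mean(axis=1)


def _quarter_sum(
    monthly: pd.DataFrame, station: str, year: int, months: Sequence[int], label: str
) -> float:
    rows = monthly[
        (monthly["station"] == station)
        & (monthly["year"] == year)
        & (monthly["month"].isin(months))
    ]
    if len(rows) != len(months):
        raise MissingClimateError(
            f"{label}: need months {list(months)} of {year} at station "
            f"{station!r}, found {len(rows)}"
        )
    return float(rows["precip_mm"].sum())


def build_climate_table(
    monthly: pd.DataFrame,
    study_years: Iterable[int],
    primary_station: str,
    secondary_station: str | None = None,
) -> ClimateTable:
    """Assemble the per-year predictor table from monthly station records.

    ``monthly`` needs columns ``station``, ``year``, ``month``,
    ``tmean_C``, ``precip_mm`` and must cover July of the year before the
    first study year through June of the last (previous-year rainfall
    quarters are lagged into study year y).  Missing months raise a
    :class:`MissingClimateError` naming the offending window.
    """
    required = {"station", "year", "month", "tmean_C", "precip_mm"}
    missing_cols = required - set(monthly.columns)
    if missing_cols:
        raise InvalidParameterError(f"monthly table missing columns {sorted(missing_cols)}")
    monthly = monthly.copy()
    monthly["station"] = monthly["station"].astype(str)

    rows = {}
    for year in sorted(int(y) for y in study_years):
        row: dict[str, float] = {}
        for label, month in _TEMP_MONTHS.items():
            sub = monthly[
                (monthly["station"] == primary_station)
                & (monthly["year"] == year)
                & (monthly["month"] == month)
            ]
            if sub.empty:
                raise MissingClimateError(
                    f"{label}: month {month} of {year} missing at station "
                    f"{primary_station!r}"
                )
            row[label] = float(sub["tmean_C"].iloc[0])
        row["R1a"] = _quarter_sum(monthly, primary_station, year - 1, (7, 8, 9), "R1a")
        if secondary_station is not None:
            row["R1b"] = _quarter_sum(
                monthly, secondary_station, year - 1, (7, 8, 9), "R1b"
            )
        row["R2"] = _quarter_sum(monthly, primary_station, year - 1, (10, 11, 12), "R2")
        row["R3"] = _quarter_sum(monthly, primary_station, year, (1, 2, 3), "R3")
        row["R4"] = _quarter_sum(monthly, primary_station, year, (4, 5, 6), "R4")
        rows[year] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "year"
    return ClimateTable(frame=frame)


@dataclass
class DriverModelResult:
    """Chosen climate-driver GLM for one species and response."""

    species: str
    response: str  # "Q" or "rho"
    link: str  # "identity" or "inverse"
    chosen_predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes the intercept under "const"
    aic: float
    is_null: bool
    vif: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    retained: list[tuple[str, tuple[str, ...], float]] = field(default_factory=list)


def _fit_glm(y: np.ndarray, X: pd.DataFrame, link: str):
    design = sm.add_constant(X, has_constant="add")
    if link == "identity":
        return sm.OLS(y, design).fit()
    if link == "inverse":
        model = sm.GLM(
            y, design, family=sm.families.Gaussian(sm.families.links.InversePower())
        )
        return model.fit()
    raise InvalidParameterError(f"unknown link {link!r}")


def fit_driver_models(
    response: Mapping[int, float],
    climate: ClimateTable,
    species: str = "",
    response_name: str = "Q",
    links: Sequence[str] = ("identity", "inverse"),
    max_predictors: int = MAX_PREDICTORS,
    vif_warn: float = VIF_WARN_THRESHOLD,
) -> DriverModelResult:
    """All-subset GLM selection of climate drivers for one yearly series.

    Fits the intercept-only model and every predictor subset of size one
    to ``max_predictors`` under each allowed link, z-scoring predictors
    over the usable years first.  The retention rule from the count-model
    stage is reused (AIC within 6 of the minimum and no smaller subset
    with lower AIC); the chosen model is the simplest retained one, ties
    broken by AIC.  Variance-inflation factors of the chosen subset above
    ``vif_warn`` are recorded as warnings, never auto-dropped.
    """
    years = sorted(int(y) for y in response)
    if len(years) < 8:
        raise InsufficientDataError(
            f"driver models need >= 8 usable years, got {len(years)}"
        )
    missing_years = [y for y in years if y not in climate.frame.index]
    if missing_years:
        raise MissingClimateError(f"no climate rows for years {missing_years}")

    X_raw = climate.frame.loc[years, [c for c in climate.frame.columns]]
    predictors = [c for c in PREDICTOR_NAMES if c in X_raw.columns]
    X_raw = X_raw[predictors]
    if X_raw.isna().any().any():
        raise MissingClimateError("climate table has missing cells for model years")
    sd = X_raw.std(ddof=1)
    if (sd == 0).any():
        constant = sd.index[sd == 0].tolist()
        raise InvalidParameterError(f"constant predictors {constant} cannot be z-scored")
    X = (X_raw - X_raw.mean()) / sd
    y = np.array([response[yr] for yr in years], dtype=float)

    fitted: list[tuple[str, tuple[str, ...], float, object]] = []
    for size in range(0, max_predictors + 1):
        for subset in itertools.combinations(predictors, size):
            for link in links:
                if size == 0 and link != links[0]:
                    continue  # the null model is link-invariant
                try:
                    res = _fit_glm(y, X[list(subset)], link)
                except Exception as exc:  # e.g. inverse link on a sign-changing mean
                    logger.debug("%s %s %s failed: %s", species, link, subset, exc)
                    continue
                fitted.append((link, subset, float(res.aic), res))
    if not fitted:
        raise InsufficientDataError("no driver model could be fitted")

    min_aic = min(aic for _, _, aic, _ in fitted)
    retained = [
        entry
        for entry in fitted
        if entry[2] <= min_aic + DELTA_AIC_WINDOW
        and not any(
            len(other[1]) < len(entry[1]) and other[2] < entry[2] for other in fitted
        )
    ]
    link, subset, aic, res = min(retained, key=lambda e: (len(e[1]), e[2]))

    coef = {name: float(v) for name, v in res.params.items()}
    warnings: list[str] = []
    vif: dict[str, float] = {}
    if len(subset) >= 2:
        design = sm.add_constant(X[list(subset)], has_constant="add").to_numpy()
        for i, name in enumerate(subset):
            vif[name] = float(variance_inflation_factor(design, i + 1))
            if vif[name] > vif_warn:
                msg = f"VIF of {name} = {vif[name]:.2f} exceeds {vif_warn:g}"
                warnings.append(msg)
                logger.warning("%s/%s: %s", species, response_name, msg)
    elif len(subset) == 1:
        vif[subset[0]] = 1.0

    return DriverModelResult(
        species=species,
        response=response_name,
        link=link,
        chosen_predictors=subset,
        coefficients=coef,
        aic=aic,
        is_null=(len(subset) == 0),
        vif=vif,
        warnings=warnings,
        retained=[(lk, sub, a) for lk, sub, a, _ in retained],
    )


@dataclass
class CommunitySlopeResult:
    """Community phenology sensitivity to spring temperature."""

    slope_days_per_degC: float
    standard_error: float
    delta_aic_vs_null: float
    n_years: int


def community_phenology_slope(
    Q_by_species: Mapping[str, Mapping[int, float]],
    climate: ClimateTable,
) -> CommunitySlopeResult:
    """Regress the cross-species mean yearly peak shift on spring warmth.

    The response is Q_y averaged over species per year; the predictor is
    the raw mean March–June temperature (deg C), so the slope reads
    directly as days of phenological shift per degree of warming.
    ``delta_aic_vs_null`` is AIC(slope model) - AIC(intercept model);
    negative values favour the temperature model.
    """
    if len(Q_by_species) < 2:
        raise InsufficientDataError("community slope needs >= 2 species")
    years = sorted({y for series in Q_by_species.values() for y in series})
    missing = [y for y in years if y not in climate.frame.index]
    if missing:
        raise MissingClimateError(f"no climate rows for years {missing}")
    mean_q = np.array(
        [
            np.mean([series[y] for series in Q_by_species.values() if y in series])
            for y in years
        ]
    )
    temp = climate.mean_march_june_temperature().loc[years].to_numpy()
    if np.std(temp) == 0:
        raise InvalidParameterError(
            "March–June temperature is constant; the slope is undefined"
        )
    design = sm.add_constant(pd.DataFrame({"T_MarJun": temp}))
    model = sm.OLS(mean_q, design).fit()
    null = sm.OLS(mean_q, np.ones((len(years), 1))).fit()
    return CommunitySlopeResult(
        slope_days_per_degC=float(model.params["T_MarJun"]),
        standard_error=float(model.bse["T_MarJun"]),
        delta_aic_vs_null=float(model.aic - null.aic),
        n_years=len(years),
    )
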