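"""Raw-measurement ingestion and derived wood anatomical/hydraulic variables.

Derived hydraulic variables follow the standard wood-anatomy definitions:
vessel composition index ``S = VA/VF``, vessel lumen fraction ``F = VF*VA``
(unit-harmonised to a dimensionless fraction by default), Carlquist's
vulnerability index ``VI = VD/VF`` and the Hagen-Poiseuille-proportional
relative hydraulic conductivity ``RC = r^4 * VF`` with ``r = VD/2``.

Also provides leaf-habit classification from annual canopy foliage series,
the UNEP aridity index, Hargreaves-Samani potential evapotranspiration and
an iterative variance-inflation-factor screen for climate variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "DerivedVariables",
    "LeafHabitResult",
    "VIFReport",
    "derive_vessel_variables",
    "fibre_total_diameter",
    "wood_density",
    "classify_leaf_habit",
    "aridity_index",
    "hargreaves_pet",
    "select_variables_vif",
    "species_means",
    "TRAIT_COLUMNS",
    "DERIVED_COLUMNS",
]

#: canonical individual-level trait column names (case-insensitive on input)
TRAIT_COLUMNS = ["VD", "VF", "VA", "FD", "FL", "FW", "WD", "H", "DBH"]
#: variables derived from the raw anatomical traits
DERIVED_COLUMNS = ["S", "F", "VI", "RC"]

#: UNEP aridity classes, ordered by increasing AI lower bound
UNEP_CLASSES = [
    (0.65, "humid"),
    (0.50, "dry subhumid"),
    (0.20, "semi-arid"),
    (0.05, "arid"),
    (0.00, "hyper-arid"),
]


@dataclass
class DerivedVariables:
    """Vessel-derived hydraulic variables for one individual or array thereof.

    ``S`` vessel composition index (VA/VF), ``F`` vessel lumen fraction,
    ``VI`` vulnerability index (VD/VF), ``RC`` relative hydraulic
    conductivity in um^4 mm^-2. ``va_reconstructed`` flags VA computed as
    the equivalent-circle area pi*(VD/2)^2 rather than measured.
    """

    S: np.ndarray | float
    F: np.ndarray | float
    VI: np.ndarray | float
    RC: np.ndarray | float
    VA: np.ndarray | float
    va_reconstructed: bool = False


@dataclass
class LeafHabitResult:
    habit: str
    foliated_days: float
    longest_leafless_spell: float
    extrapolated: bool = False


@dataclass
class VIFReport:
    """Outcome of the iterative VIF screen.

    ``retained`` preserves input order; ``removed`` lists dropped variables
    in removal order; ``vif`` maps retained variables to their final VIF;
    ``history`` records (variable, vif_at_removal) per iteration.
    """

    retained: list[str]
    removed: list[str]
    vif: dict[str, float]
    history: list[tuple[str, float]] = field(default_factory=list)


def _validate_nonnegative(**named):
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError(f"{name} must be nonnegative")


def derive_vessel_variables(VD, VF, VA=None, *, lumen_fraction_raw: bool = False) -> DerivedVariables:
    """Compute S, F, VI and RC from vessel diameter and frequency.

    Parameters
    ----------
    VD : scalar or array
        Mean equivalent-circle vessel diameter, um.
    VF : scalar or array
        Vessel frequency, count per mm^2.
    VA : scalar or array, optional
        Mean vessel lumen area, um^2. When absent it is reconstructed as
        the equivalent-circle area ``pi*(VD/2)**2`` and flagged, since
        averaging diameters then squaring differs from averaging areas.
    lumen_fraction_raw : bool
        If True, F is the raw product VF*VA in mixed units (mm^-2 * um^2),
        replicating the index as commonly tabulated; by default a 1e-6
        factor harmonises units so F is a true dimensionless lumen fraction.

    Where ``VF == 0`` the ratios S and VI are undefined and returned as NaN;
    RC and F are 0 there.
    """
    _validate_nonnegative(VD=VD, VF=VF)
    scalar = np.isscalar(VD) and np.isscalar(VF)
    VD = np.asarray(VD, dtype=float)
    VF = np.asarray(VF, dtype=float)
    reconstructed = VA is None
    if reconstructed:
        VA = np.pi * (VD / 2.0) ** 2
    else:
        _validate_nonnegative(VA=VA)
        VA = np.asarray(VA, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(VF > 0, VA / VF, np.nan)
        VI = np.where(VF > 0, VD / VF, np.nan)
    F = VF * VA * (1.0 if lumen_fraction_raw else 1e-6)
    RC = (VD / 2.0) ** 4 * VF
    if scalar:
        S, F, VI, RC, VA = (float(v) for v in (S, F, VI, RC, VA))
    return DerivedVariables(S=S, F=F, VI=VI, RC=RC, VA=VA, va_reconstructed=reconstructed)


def fibre_total_diameter(F_L, F_W):
    """Total fibre diameter ``F_D = F_L + 2*F_W`` (um)."""
    _validate_nonnegative(F_L=F_L, F_W=F_W)
    out = np.asarray(F_L, dtype=float) + 2.0 * np.asarray(F_W, dtype=float)
    return float(out) if out.ndim == 0 else out


def wood_density(dry_mass, green_volume):
    """Wood density from oven-dry mass (g) and water-displacement green volume (cm^3)."""
    volume = np.asarray(green_volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("green_volume must be positive")
    _validate_nonnegative(dry_mass=dry_mass)
    out = np.asarray(dry_mass, dtype=float) / volume
    return float(out) if out.ndim == 0 else out


def classify_leaf_habit(
    days,
    fractions,
    *,
    foliage_threshold: float = 0.5,
    evergreen_min_days: float = 360.0,
    deciduous_min_spell: float = 60.0,
    year_length: int = 365,
) -> LeafHabitResult:
    """Classify leaf habit from an annual canopy-foliage series.

    ``days`` are observation days-of-year (0-365), ``fractions`` the canopy
    foliage fraction at each observation. The series is linearly
    interpolated onto a daily grid, wrapping around the year. Foliated days
    are those holding >= ``foliage_threshold`` of the series maximum.
    Classes: evergreen when foliated_days >= ``evergreen_min_days``;
    deciduous when the longest consecutive leafless spell is
    >= ``deciduous_min_spell`` days; otherwise brevideciduous.
    """
    days = np.asarray(days, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if days.shape != fractions.shape or days.size < 1:
        raise ValueError("days and fractions must be equal-length, nonempty")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("foliage fractions must lie in [0, 1]")
    peak = float(np.max(fractions))
    if peak <= 0:
        raise ValueError("all-zero foliage series: maximum foliage must be positive")

    order = np.argsort(days)
    days, fractions = days[order], fractions[order]
    span = days[-1] - days[0]
    extrapolated = span < year_length - 31  # coarser than monthly coverage
    if extrapolated:
        warnings.warn(
            f"foliage series spans only {span:.0f} days; extrapolating cyclically",
            stacklevel=2,
        )
    # cyclic extension so the daily grid wraps between last and first obs
    grid = np.arange(year_length, dtype=float)
    ext_days = np.concatenate([[days[-1] - year_length], days, [days[0] + year_length]])
    ext_frac = np.concatenate([[fractions[-1]], fractions, [fractions[0]]])
    daily = np.interp(grid, ext_days, ext_frac)

    foliated = daily >= foliage_threshold * peak
    foliated_days = float(foliated.sum())
    # longest leafless run, treating the series as circular
    leafless = ~foliated
    if leafless.all():
        longest = float(year_length)
    elif not leafless.any():
        longest = 0.0
    else:
        doubled = np.concatenate([leafless, leafless])
        longest = run = 0
        for flag in doubled:
            run = run + 1 if flag else 0
            longest = max(longest, run)
        longest = float(min(longest, year_length))

    if foliated_days >= evergreen_min_days:
        habit = "evergreen"
    elif longest >= deciduous_min_spell:
        habit = "deciduous"
    else:
        habit = "brevideciduous"
    return LeafHabitResult(habit, foliated_days, longest, extrapolated)


def aridity_index(MAP, PET, *, humid_threshold: float = 0.65, fine_classes: bool = False):
    """UNEP aridity index ``AI = MAP/PET`` with class label.

    Returns ``(AI, label)``; label is "humid" iff AI >= 0.65 (coarse rule),
    or the full UNEP class when ``fine_classes`` is set.
    """
    PET = float(PET)
    if PET <= 0:
        raise ValueError("PET must be positive")
    MAP = float(MAP)
    if MAP < 0:
        raise ValueError("MAP must be nonnegative")
    ai = MAP / PET
    if fine_classes:
        label = next(name for bound, name in UNEP_CLASSES if ai >= bound)
    else:
        label = "humid" if ai >= humid_threshold else "non-humid"
    return ai, label


def hargreaves_pet(Tmean, Tmax, Tmin, Ra):
    """Hargreaves-Samani potential evapotranspiration, summed over periods.

    ``PET_period = 0.0023 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin)`` with Ra
    in mm-equivalent per period (typically monthly); the return value is the
    annual total in mm. Any negative per-period PET (Tmean < -17.8 C) is
    floored at zero.
    """
    Tmean = np.atleast_1d(np.asarray(Tmean, dtype=float))
    Tmax = np.atleast_1d(np.asarray(Tmax, dtype=float))
    Tmin = np.atleast_1d(np.asarray(Tmin, dtype=float))
    Ra = np.atleast_1d(np.asarray(Ra, dtype=float))
    if np.any(Tmax < Tmin):
        raise ValueError("Tmax must be >= Tmin in every period")
    per_period = 0.0023 * Ra * (Tmean + 17.8) * np.sqrt(Tmax - Tmin)
    return float(np.sum(np.clip(per_period, 0.0, None)))


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF per column of X (columns are variables), via statsmodels."""
    design = np.column_stack([np.ones(X.shape[0]), X])
    out = np.empty(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(X.shape[1]):
            out[i] = variance_inflation_factor(design, i + 1)
    return out


def select_variables_vif(env: pd.DataFrame, threshold: float = 10.0) -> VIFReport:
    """Iteratively drop the variable with the largest VIF until all <= threshold.

    ``VIF_i = 1/(1 - R^2_i)`` from regressing variable i on the remaining
    variables. Perfect collinearity yields infinite VIF. Tie-break: among
    equal-largest VIFs (including ties at infinity) the variable appearing
    later in input order is removed, so a duplicated column loses its copy.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables for a VIF screen")
    if env.shape[0] < 3:
        raise ValueError("need at least 3 plots for a VIF screen")
    cols = list(env.columns)
    history: list[tuple[str, float]] = []
    while len(cols) >= 2:
        vifs = _vif_values(env[cols].to_numpy(dtype=float))
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        vmax = vifs.max()
        if vmax <= threshold:
            break
        # later-in-order member among the maximal VIFs is removed
        drop_idx = int(np.flatnonzero(vifs == vmax)[-1])
        history.append((cols[drop_idx], float(vmax)))
        cols.pop(drop_idx)
    final = _vif_values(env[cols].to_numpy(dtype=float)) if len(cols) >= 2 else np.ones(len(cols))
    return VIFReport(
        retained=cols,
        removed=[name for name, _ in history],
        vif={c: float(v) for c, v in zip(cols, final)},
        history=history,
    )


def species_means(
    records: pd.DataFrame,
    *,
    log10: bool = False,
    species_col: str = "species",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Species-level arithmetic means of trait columns.

    With ``log10`` the transform is applied to individual values before
    averaging; nonpositive values then raise, naming the offending records.
    Missing values are ignored per-column (propagate as missing, never zero).
    """
    if species_col not in records.columns:
        raise ValueError(f"missing species column {species_col!r}")
    if columns is None:
        columns = [
            c for c in records.columns
            if c != species_col and pd.api.types.is_numeric_dtype(records[c])
        ]
    data = records[columns].astype(float)
    if log10:
        bad = (data <= 0).any(axis=1)
        if bad.any():
            idx = list(records.index[bad][:5])
            raise ValueError(
                f"log10 transform requires strictly positive values; offending records: {idx}"
            )
        data = np.log10(data)
    data = data.assign(**{species_col: records[species_col].to_numpy()})
    out = data.groupby(species_col, sort=True).mean()
    out.index.name = species_col
    return out
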