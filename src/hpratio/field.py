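"""From raw field measurements to the four ecological factors.

This module converts the kinds of raw data a pond campaign produces into
the quantities the log-linear framework consumes:

* plankton counts + cell geometry -> producer and herbivore carbon biomass
  (and from producer sizes, the edible fraction ``a_edi``);
* seston C and P concentrations -> molar C:P ratio ``a_nut``;
* PAR depth profiles -> light extinction coefficient ``lambda`` (Beer-
  Lambert, I(z) = I(0) exp(-lambda z));
* photosynthesis-irradiance points -> non-rectangular hyperbola curve
  (P_max, initial slope alpha, curvature xi);
* P-I curve + ambient PAR time series + lambda -> chlorophyll-a specific
  daily production rate ``mu``;
* fish catch per unit effort -> relative carnivore abundance
  ``theta = CPUE + 1``.

Conversion coefficients (biovolume-to-carbon power laws, length-weight
regressions, dry/wet-weight carbon fractions) live in editable tables with
literature-derived defaults; every entry can be overridden per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PlanktonCount",
    "DepthProfile",
    "ExtinctionFit",
    "PICurve",
    "TreatmentRecord",
    "CELL_CARBON_COEFFS",
    "LENGTH_WEIGHT_COEFFS",
    "SPECIAL_ROTIFER_CARBON",
    "CARBON_PER_DRY_WEIGHT",
    "CARBON_PER_WET_WEIGHT",
    "EDIBLE_SIZE_THRESHOLD_UM",
    "cell_carbon",
    "zooplankton_carbon",
    "edible_fraction",
    "seston_cp",
    "fit_extinction",
    "pi_response",
    "fit_pi_curve",
    "PICurveFitError",
    "daily_specific_production",
    "relative_fish_abundance",
]

# ---------------------------------------------------------------------------
# coefficient tables (editable defaults; provenance noted per row)
# ---------------------------------------------------------------------------

#: Biovolume (um^3) -> cell carbon (pg C): C = a * V**b.
#: Defaults follow the widely used protist/diatom power laws of
#: Menden-Deuer & Lessard (2000, Limnol. Oceanogr. 45:569).
CELL_CARBON_COEFFS: dict[str, tuple[float, float]] = {
    "protist": (0.216, 0.939),
    "diatom": (0.288, 0.811),
}

#: Crustacean body length (mm) -> dry weight (ug): DW = a * L**b.
#: Defaults are group-level regressions of Bottrell et al. (1976,
#: Norw. J. Zool. 24:419): ln W = ln a + b ln L.
LENGTH_WEIGHT_COEFFS: dict[str, tuple[float, float]] = {
    "cladoceran": (math.exp(1.7512), 2.653),
    "copepod": (math.exp(1.9526), 2.399),
}

#: Per-individual carbon (ug C ind^-1) for rotifer taxa whose biomass is
#: better captured by a fixed species weight than by biovolume.
SPECIAL_ROTIFER_CARBON: dict[str, float] = {
    "Asplanchna": 0.35,   # large predatory rotifer, literature-derived default
    "Keratella": 0.02,    # small loricate rotifer, literature-derived default
}

#: Carbon content of crustacean dry weight (g C per g DW).
CARBON_PER_DRY_WEIGHT = 0.48
#: Carbon content of rotifer wet weight (g C per g WW).
CARBON_PER_WET_WEIGHT = 0.024

#: Cells/colonies with major axis strictly below this are edible to most
#: herbivorous zooplankton.  Large cladocerans can handle up to ~70 um;
#: pass ``threshold_um=70`` to use that alternative convention.
EDIBLE_SIZE_THRESHOLD_UM = 30.0

#: Wet weight assumes unit density: 1 um^3 = 1e-6 ug.
_UG_PER_UM3 = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanktonCount:
    """One taxon's abundance record with the group-appropriate size data.

    Phytoplankton and rotifers carry ``biovolume`` (um^3 per cell or
    individual); phytoplankton additionally carry ``major_axis`` (um, of the
    cell or colony); crustaceans carry ``body_length`` (mm).
    """

    taxon: str
    group: str  # phytoplankton | rotifer | rotifer-special | cladoceran | copepod
    count_per_l: float
    biovolume: Optional[float] = None
    major_axis: Optional[float] = None
    body_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count_per_l < 0:
            raise ValueError(f"count_per_l must be >= 0, got {self.count_per_l}")
        for name in ("biovolume", "major_axis", "body_length"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class DepthProfile:
    """PAR (umol photon m^-2 s^-1) at increasing depths (m) below surface."""

    depths: np.ndarray
    par: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "par", np.asarray(self.par, dtype=float))
        if len(self.depths) != len(self.par):
            raise ValueError("depths and par must have equal length")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must increase from the surface")
        if np.any(self.par <= 0):
            raise ValueError("par values must be positive")


@dataclass(frozen=True)
class ExtinctionFit:
    """Beer-Lambert fit I(z) = I0 exp(-lambda z)."""

    lambda_: float  # extinction coefficient, m^-1
    i0: float       # fitted surface PAR
    r2: float

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lambda_}")


@dataclass(frozen=True)
class PICurve:
    """Non-rectangular hyperbola photosynthesis-irradiance curve.

    ``p_max`` (gC g chl-a^-1 h^-1) is the light-saturated rate,
    ``alpha_slope`` the initial slope per PAR unit and ``curvature``
    (xi in [0, 1)) interpolates between the rectangular hyperbola (xi -> 0)
    and the Blackman limit min(alpha I, P_max) (xi -> 1).
    """

    p_max: float
    alpha_slope: float
    curvature: float

    def __post_init__(self) -> None:
        if self.p_max <= 0:
            raise ValueError(f"p_max must be > 0, got {self.p_max}")
        if self.alpha_slope <= 0:
            raise ValueError(f"alpha_slope must be > 0, got {self.alpha_slope}")
        if not 0 <= self.curvature < 1:
            raise ValueError(f"curvature must be in [0, 1), got {self.curvature}")


@dataclass(frozen=True)
class TreatmentRecord:
    """One pond-section's campaign means, ready for the log-linear fit."""

    pond: str
    treatment: str
    h_biomass: float  # ug C L^-1
    p_biomass: float  # ug C L^-1
    a_nut: float      # seston molar C:P
    a_edi: float      # edible fraction of producer biomass
    mu: float         # gC g chl-a^-1 d^-1
    cpue: float       # g wet weight
    theta: float = None  # type: ignore[assignment]  # filled as cpue + 1

    def __post_init__(self) -> None:
        if self.h_biomass <= 0 or self.p_biomass <= 0:
            raise ValueError("biomasses must be positive")
        if not 0 <= self.a_edi <= 1:
            raise ValueError(f"a_edi must be in [0, 1], got {self.a_edi}")
        if self.a_nut <= 0 or self.mu <= 0:
            raise ValueError("a_nut and mu must be positive")
        if self.cpue < 0:
            raise ValueError(f"cpue must be >= 0, got {self.cpue}")
        if self.theta is None:
            object.__setattr__(self, "theta", relative_fish_abundance(self.cpue))
        elif abs(self.theta - (self.cpue + 1.0)) > 1e-9:
            raise ValueError(
                f"theta={self.theta} inconsistent with cpue+1={self.cpue + 1.0}"
            )


# ---------------------------------------------------------------------------
# biomass and stoichiometry
# ---------------------------------------------------------------------------


def cell_carbon(
    biovolume: float,
    group: str = "protist",
    coeffs: Optional[Mapping[str, tuple[float, float]]] = None,
) -> float:
    """Carbon content (pg C) of one cell from its biovolume (um^3).

    Uses the group-specific power law ``C = a * V**b`` from the coefficient
    table (see :data:`CELL_CARBON_COEFFS`).
    """
    table = CELL_CARBON_COEFFS if coeffs is None else coeffs
    if biovolume <= 0:
        raise ValueError(f"biovolume must be > 0, got {biovolume}")
    if group not in table:
        raise KeyError(
            f"unknown carbon-conversion group {group!r}; configured: "
            f"{sorted(table)}"
        )
    a, b = table[group]
    return a * biovolume**b


def zooplankton_carbon(
    record: PlanktonCount,
    length_weight: Optional[Mapping[str, tuple[float, float]]] = None,
    special_carbon: Optional[Mapping[str, float]] = None,
    c_per_dw: float = CARBON_PER_DRY_WEIGHT,
    c_per_ww: float = CARBON_PER_WET_WEIGHT,
) -> float:
    """Carbon biomass (ug C L^-1) contributed by one zooplankton record.

    Crustaceans (``cladoceran``/``copepod``): length (mm) -> dry weight (ug)
    by the group power-law regression, then ``c_per_dw`` g C per g DW.
    Rotifers: biovolume (um^3) -> wet weight at unit density, then
    ``c_per_ww`` g C per g WW.  ``rotifer-special`` taxa use fixed
    per-individual carbon weights (:data:`SPECIAL_ROTIFER_CARBON`).
    """
    lw = LENGTH_WEIGHT_COEFFS if length_weight is None else length_weight
    special = SPECIAL_ROTIFER_CARBON if special_carbon is None else special_carbon
    if record.count_per_l == 0:
        return 0.0
    if record.group in ("cladoceran", "copepod"):
        if record.body_length is None or record.body_length <= 0:
            raise ValueError(
                f"crustacean record {record.taxon!r} needs a positive body_length"
            )
        a, b = lw[record.group]
        dw_ug = a * record.body_length**b
        return record.count_per_l * dw_ug * c_per_dw
    if record.group == "rotifer":
        if record.biovolume is None or record.biovolume <= 0:
            raise ValueError(
                f"rotifer record {record.taxon!r} needs a positive biovolume"
            )
        ww_ug = record.biovolume * _UG_PER_UM3
        return record.count_per_l * ww_ug * c_per_ww
    if record.group == "rotifer-special":
        if record.taxon not in special:
            raise KeyError(
                f"no per-taxon carbon weight for {record.taxon!r}; configured: "
                f"{sorted(special)}"
            )
        return record.count_per_l * special[record.taxon]
    raise ValueError(
        f"group {record.group!r} is not a zooplankton group "
        "(expected cladoceran, copepod, rotifer or rotifer-special)"
    )


def edible_fraction(
    items: Iterable[tuple[float, float]],
    threshold_um: float = EDIBLE_SIZE_THRESHOLD_UM,
) -> float:
    """Biomass fraction of producers with major axis strictly below threshold.

    ``items`` are (major_axis um, carbon biomass) pairs; an item exactly at
    the threshold counts as inedible.
    """
    total = 0.0
    edible = 0.0
    for size, biomass in items:
        if biomass < 0:
            raise ValueError("biomasses must be nonnegative")
        total += biomass
        if size < threshold_um:
            edible += biomass
    if total <= 0:
        raise ValueError("total biomass is zero: edible fraction undefined")
    return edible / total


#: Atomic weights used for the molar conversion.
_ATOMIC_WEIGHT_C = 12.011
_ATOMIC_WEIGHT_P = 30.974


def seston_cp(carbon: float, phosphorus: float, molar: bool = True) -> float:
    """Seston C:P ratio from concentrations in the same mass units.

    Molar by default (the convention of ecological stoichiometry);
    ``molar=False`` returns the plain mass ratio.
    """
    if carbon <= 0 or phosphorus <= 0:
        raise ValueError("carbon and phosphorus must be positive")
    if molar:
        return (carbon / _ATOMIC_WEIGHT_C) / (phosphorus / _ATOMIC_WEIGHT_P)
    return carbon / phosphorus


# ---------------------------------------------------------------------------
# light and photosynthesis
# ---------------------------------------------------------------------------


def fit_extinction(profile: DepthProfile) -> ExtinctionFit:
    """Least-squares Beer-Lambert fit of a PAR depth profile.

    ln I is regressed on depth; the negated slope is the extinction
    coefficient lambda (clamped at zero for profiles that brighten with
    depth within noise), the exponentiated intercept is the surface PAR.
    """
    if len(profile.depths) < 3:
        raise ValueError(f"need >= 3 depths, got {len(profile.depths)}")
    ln_i = np.log(profile.par)
    res = stats.linregress(profile.depths, ln_i)
    lam = max(-float(res.slope), 0.0)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return ExtinctionFit(lambda_=lam, i0=float(np.exp(res.intercept)), r2=r2)


def pi_response(curve: PICurve, irradiance) -> np.ndarray | float:
    """Photosynthetic rate at irradiance I under the non-rectangular hyperbola.

    The rate is the smaller root of
    ``xi P^2 - (alpha I + P_max) P + alpha I P_max = 0``; for xi below 1e-9
    the rectangular-hyperbola limit ``alpha I P_max / (alpha I + P_max)`` is
    used for numerical continuity.
    """
    I = np.asarray(irradiance, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be >= 0")
    a, pm, xi = curve.alpha_slope, curve.p_max, curve.curvature
    s = a * I + pm
    if xi < 1e-9:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0, a * I * pm / np.where(s > 0, s, 1.0), 0.0)
    else:
        disc = np.clip(s**2 - 4.0 * xi * a * I * pm, 0.0, None)
        out = (s - np.sqrt(disc)) / (2.0 * xi)
    return float(out) if np.isscalar(irradiance) else out


class PICurveFitError(RuntimeError):
    """Non-convergent P-I fit; carries the initial guess used."""

    def __init__(self, message: str, init: tuple[float, float, float]):
        super().__init__(f"{message} (initialization p_max={init[0]:.4g}, "
                         f"alpha={init[1]:.4g}, xi={init[2]:.4g})")
        self.init = init


def fit_pi_curve(points: Sequence[tuple[float, float]]) -> PICurve:
    """Nonlinear least-squares fit of the non-rectangular hyperbola.

    ``points`` are (PAR, rate) pairs spanning limiting and saturating light.
    Initialization: alpha from the slope through the two lowest-PAR points,
    P_max from the maximum observed rate, xi = 0.5; all three parameters are
    bounded (p_max, alpha > 0; xi in [0, 1)).
    """
    pts = sorted((float(i), float(r)) for i, r in points)
    if len(pts) < 4:
        raise ValueError(f"need >= 4 P-I points, got {len(pts)}")
    I = np.array([p[0] for p in pts])
    R = np.array([p[1] for p in pts])
    if np.all(R <= 0):
        raise PICurveFitError(
            "all photosynthetic rates are <= 0; curve undefined",
            (float(np.max(R)), 0.0, 0.5),
        )
    lowI = [p for p in pts if p[0] > 0][:2]
    if len(lowI) >= 2 and lowI[1][0] > lowI[0][0]:
        alpha0 = max((lowI[1][1] - lowI[0][1]) / (lowI[1][0] - lowI[0][0]), 1e-8)
    elif lowI:
        alpha0 = max(lowI[0][1] / lowI[0][0], 1e-8)
    else:
        alpha0 = 1e-3
    pmax0 = float(np.max(R))
    init = (pmax0, alpha0, 0.5)

    def residuals(p):
        pm, a, xi = p
        c = PICurve(p_max=pm, alpha_slope=a, curvature=xi)
        return pi_response(c, I) - R

    try:
        sol = optimize.least_squares(
            residuals,
            x0=np.array(init),
            bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, 1.0 - 1e-9]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except Exception as exc:  # numerical failure inside the solver
        raise PICurveFitError(f"P-I fit failed: {exc}", init) from None
    if not sol.success:
        raise PICurveFitError(f"P-I fit did not converge: {sol.message}", init)
    pm, a, xi = sol.x
    return PICurve(p_max=float(pm), alpha_slope=float(a), curvature=float(xi))


def daily_specific_production(
    curve: PICurve,
    par_times_h: np.ndarray,
    par_values: np.ndarray,
    lambda_: float,
    depth: float,
    lookback_days: int = 3,
    dz: float = 0.1,
    max_gap_h: float = 1.0,
) -> float:
    """Chlorophyll-specific daily production rate mu (gC g chl-a^-1 d^-1).

    ``par_times_h``/``par_values`` give surface PAR over (at least) the
    ``lookback_days`` window preceding the sampling date, with times in
    hours from the window start.  At each time step the water column is
    resolved on a ``dz`` grid (default 10 cm, matching typical profile
    measurements); the hourly rate ``pi_response(curve, I0 e^(-lambda z))``
    is depth-averaged by the trapezoid rule, integrated over each 24-h day,
    and the ``lookback_days`` daily totals are averaged.

    Gaps in the PAR series larger than ``max_gap_h`` hours raise an error.
    """
    t = np.asarray(par_times_h, dtype=float)
    I0 = np.asarray(par_values, dtype=float)
    if len(t) != len(I0) or len(t) < 2:
        raise ValueError("PAR series needs matched times and values (n >= 2)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("PAR times must be strictly increasing")
    if np.any(I0 < 0):
        raise ValueError("PAR values must be >= 0")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    if depth <= 0 or dz <= 0:
        raise ValueError("depth and dz must be positive")
    window = 24.0 * lookback_days
    if t[-1] - t[0] < window - 1e-9:
        raise ValueError(
            f"PAR series spans {t[-1] - t[0]:.2f} h, " f"need {window:.0f} h"
        )
    gaps = np.diff(t)
    if np.max(gaps) > max_gap_h:
        raise ValueError(
            f"PAR series has a gap of {np.max(gaps):.2f} h "
            f"(> tolerance {max_gap_h} h)"
        )

    z = np.arange(0.0, depth + 0.5 * dz, dz)
    z = z[z <= depth + 1e-12]
    if z[-1] < depth - 1e-12:
        z = np.append(z, depth)
    atten = np.exp(-lambda_ * z)  # (nz,)

    # depth-averaged rate at every time step, vectorized over (time, depth)
    Iz = I0[:, None] * atten[None, :]
    rates = pi_response(curve, Iz)
    col_rate = np.trapezoid(rates, z, axis=1) / depth  # gC gchl^-1 h^-1

    daily = []
    t0 = t[0]
    for d in range(lookback_days):
        lo, hi = t0 + 24.0 * d, t0 + 24.0 * (d + 1)
        mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        daily.append(float(np.trapezoid(col_rate[mask], t[mask])))
    return float(np.mean(daily))


def relative_fish_abundance(cpue: float) -> float:
    """Relative carnivore abundance theta = CPUE + 1 (log theta = 0 at zero catch)."""
    if cpue < 0:
        raise ValueError(f"cpue must be >= 0, got {cpue}")
    return cpue + 1.0


# ---------------------------------------------------------------------------
# campaign-level derivation
# ---------------------------------------------------------------------------

_PHYTO_GROUPS = ("protist", "diatom")


def _unit_key(df: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return df.groupby(["pond", "treatment"], sort=True)


def derive_treatments(
    profiles: pd.DataFrame,
    pi_points: pd.DataFrame,
    par_series: pd.DataFrame,
    counts: pd.DataFrame,
    seston: pd.DataFrame,
    cpue: pd.DataFrame,
    depth: float = 1.5,
    edible_threshold_um: float = EDIBLE_SIZE_THRESHOLD_UM,
    lookback_days: int = 3,
) -> list[TreatmentRecord]:
    """Run the whole derivation pipeline on one campaign's raw tables.

    Expected columns (one row per observation):

    * ``profiles``: pond, treatment, date, depth_m, par
    * ``pi_points``: pond, treatment, par, rate
    * ``par_series``: pond, treatment, date, time_h, par (time in hours from
      the start of the ``lookback_days`` window before each sampling date)
    * ``counts``: pond, treatment, date, taxon, group, count_per_l,
      biovolume, major_axis, body_length
    * ``seston``: pond, treatment, date, c_ug_l, p_ug_l
    * ``cpue``: pond, treatment, date, cpue

    Per (pond, treatment) section: the extinction coefficient is fitted per
    date and the P-I curve once; the daily specific production rate is
    computed per date from the PAR series and averaged; biomasses, edible
    fraction, seston C:P and CPUE are averaged over dates.  Returns one
    :class:`TreatmentRecord` per section.
    """
    records = []
    pi_by_unit = {k: g for k, g in _unit_key(pi_points)}
    for (pond, treatment), prof_unit in _unit_key(profiles):
        key = (pond, treatment)
        curve = fit_pi_curve(
            list(zip(pi_by_unit[key]["par"], pi_by_unit[key]["rate"]))
        )
        par_unit = par_series[
            (par_series["pond"] == pond) & (par_series["treatment"] == treatment)
        ]
        mus = []
        for date, prof in prof_unit.groupby("date"):
            fit = fit_extinction(
                DepthProfile(prof["depth_m"].to_numpy(), prof["par"].to_numpy())
            )
            day = par_unit[par_unit["date"] == date]
            mus.append(
                daily_specific_production(
                    curve,
                    day["time_h"].to_numpy(),
                    day["par"].to_numpy(),
                    fit.lambda_,
                    depth,
                    lookback_days=lookback_days,
                )
            )
        mu = float(np.mean(mus))

        cnt_unit = counts[(counts["pond"] == pond) & (counts["treatment"] == treatment)]
        p_per_date, h_per_date, edi_per_date = [], [], []
        for date, cnt in cnt_unit.groupby("date"):
            phyto_items = []
            h_total = 0.0
            for row in cnt.itertuples(index=False):
                if row.group in _PHYTO_GROUPS:
                    pg = cell_carbon(row.biovolume, row.group)
                    biomass_ug_l = row.count_per_l * pg * 1e-6  # pg -> ug
                    phyto_items.append((row.major_axis, biomass_ug_l))
                else:
                    h_total += zooplankton_carbon(
                        PlanktonCount(
                            taxon=row.taxon,
                            group=row.group,
                            count_per_l=row.count_per_l,
                            biovolume=_maybe(row.biovolume),
                            body_length=_maybe(row.body_length),
                        )
                    )
            p_per_date.append(sum(b for _, b in phyto_items))
            h_per_date.append(h_total)
            edi_per_date.append(edible_fraction(phyto_items, edible_threshold_um))
        ses_unit = seston[(seston["pond"] == pond) & (seston["treatment"] == treatment)]
        cp_per_date = [
            seston_cp(row.c_ug_l, row.p_ug_l) for row in ses_unit.itertuples()
        ]
        cpue_unit = cpue[(cpue["pond"] == pond) & (cpue["treatment"] == treatment)]
        records.append(
            TreatmentRecord(
                pond=str(pond),
                treatment=str(treatment),
                h_biomass=float(np.mean(h_per_date)),
                p_biomass=float(np.mean(p_per_date)),
                a_nut=float(np.mean(cp_per_date)),
                a_edi=float(np.mean(edi_per_date)),
                mu=mu,
                cpue=float(np.mean(cpue_unit["cpue"])),
            )
        )
    return records


def _maybe(v) -> Optional[float]:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
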