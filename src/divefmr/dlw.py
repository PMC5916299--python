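"""Doubly-labeled-water (DLW) energetics.

The DLW method doses an animal with water enriched in the stable isotopes
deuterium (²H) and ¹⁸O. ¹⁸O leaves the body as both water and respiratory CO2
while ²H leaves only as water, so the difference between the two washout
(turnover) rates, scaled by the body-water pool, estimates CO2 production and
hence field metabolic rate (FMR). This module implements:

* isotope dilution spaces (plateau and mass-scaling methods),
* fractional turnover rates from the exponential decline of excess enrichment,
* CO2 production by the single-pool (Nagy 1980) and two-pool
  (Speakman, Nair & Goran 1993) equations,
* conversion of CO2 production to watts,
* water influx/efflux for a linearly changing pool (Nagy & Costa 1980),
* the time-budget correction from whole-interval FMR to at-sea FMR, and
* Monte-Carlo propagation of analytical (assay) uncertainty.

Enrichments are handled internally as excess mole fractions; user-facing
values are ppm (1 ppm = 1e-6 mole fraction). All pools are mol of body water,
all rates day⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .constants import resolve_constants

__all__ = [
    "IsotopeSample",
    "DoseRecord",
    "IsotopeStudy",
    "DilutionSpaces",
    "TurnoverRates",
    "OnshoreRateSpec",
    "EnergeticsResult",
    "InvalidStudyError",
    "dilution_space_plateau",
    "dilution_space_scaling",
    "tbw_fraction",
    "turnover_rate",
    "rco2_single_pool",
    "rco2_two_pool",
    "mol_day_to_ml_g_hr",
    "fmr_from_co2",
    "water_flux",
    "at_sea_fmr",
    "rco2_uncertainty",
    "process_study",
]


class InvalidStudyError(ValueError):
    """Raised when an isotope study cannot yield a physical estimate."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeSample:
    """A single serum sample: absolute enrichments in ppm (mole fraction x 1e6)."""

    time_days: float
    o18_ppm: float
    h2_ppm: float
    phase: Literal["background", "equilibration", "final"]


@dataclass(frozen=True)
class DoseRecord:
    """Weighed injectate: mass in g, label content as mole fractions in (0, 1]."""

    dose_mass_g: float
    o18_fraction: float
    h2_fraction: float

    def __post_init__(self) -> None:
        if self.dose_mass_g <= 0:
            raise ValueError("dose_mass_g must be positive")
        for name in ("o18_fraction", "h2_fraction"):
            f = getattr(self, name)
            if not (0 < f <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {f}")


@dataclass
class IsotopeStudy:
    """One animal's complete DLW record."""

    animal_id: str
    dose: DoseRecord
    samples: Sequence[IsotopeSample]
    mass_initial_kg: float
    mass_final_kg: float
    interval_days: float
    time_at_sea_days: float = np.nan
    time_ashore_days: float = np.nan

    def __post_init__(self) -> None:
        if self.mass_initial_kg <= 0 or self.mass_final_kg <= 0:
            raise ValueError("body masses must be positive")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")

    def sample(self, phase: str) -> IsotopeSample:
        for s in self.samples:
            if s.phase == phase:
                return s
        raise InvalidStudyError(f"{self.animal_id}: no {phase!r} sample")


@dataclass(frozen=True)
class DilutionSpaces:
    """Body-water pool sizes (mol) from each isotope, plus their ratio."""

    n_o: float
    n_d: float
    method: Literal["plateau", "scaling"]

    @property
    def ratio_dil(self) -> float:
        return self.n_d / self.n_o

    def __post_init__(self) -> None:
        if self.n_o <= 0 or self.n_d <= 0:
            raise ValueError("dilution spaces must be positive")
        if not (1.0 <= self.ratio_dil <= 1.1):
            warnings.warn(
                f"dilution-space ratio {self.ratio_dil:.4f} outside the typical "
                "[1.0, 1.1] envelope for a valid study",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TurnoverRates:
    """Fractional turnover rates (day⁻¹) of ¹⁸O and ²H."""

    k_o: float
    k_d: float

    def __post_init__(self) -> None:
        if not (self.k_o > self.k_d > 0):
            warnings.warn(
                f"expected k_o > k_d > 0 for a metabolizing animal, got "
                f"k_o={self.k_o:.4g}, k_d={self.k_d:.4g}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class OnshoreRateSpec:
    """How to price time spent ashore when deriving at-sea FMR.

    ``rate_wkg`` is an explicit onshore metabolic rate. Alternatively
    ``basal_multiple`` scales an allometric basal prediction (Kleiber:
    3.4 * m^0.75 W for mass m in kg, expressed per kg). Exactly one of the
    two must be given — there is no silent default, because the onshore rate
    is an assumption, not a measurement.
    """

    rate_wkg: float | None = None
    basal_multiple: float | None = None

    def resolve(self, mass_kg: float) -> float:
        if (self.rate_wkg is None) == (self.basal_multiple is None):
            raise ValueError("specify exactly one of rate_wkg or basal_multiple")
        if self.rate_wkg is not None:
            return self.rate_wkg
        basal_w = 3.4 * mass_kg**0.75
        return self.basal_multiple * basal_w / mass_kg


@dataclass
class EnergeticsResult:
    """Per-animal DLW outputs on the conventional reporting scales."""

    animal_id: str
    n_o_mol: float
    n_d_mol: float
    k_o: float
    k_d: float
    rco2_nagy_ml_g_hr: float
    rco2_speakman_ml_g_hr: float
    fmr_w_nagy: float
    fmr_w_speakman: float
    fmr_wkg_nagy: float
    fmr_wkg_speakman: float
    tbw_percent: float
    influx_ml_kg_day: float
    efflux_ml_kg_day: float
    at_sea_fmr_wkg: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dilution spaces and pools
# ---------------------------------------------------------------------------

def _excess_ppm(sample: IsotopeSample, background: IsotopeSample, isotope: str) -> float:
    attr = {"o18": "o18_ppm", "h2": "h2_ppm"}[isotope]
    return getattr(sample, attr) - getattr(background, attr)


def dilution_space_plateau(
    dose: DoseRecord,
    isotope: Literal["o18", "h2"],
    equil: IsotopeSample,
    background: IsotopeSample,
    constants: Mapping[str, float] | None = None,
    animal_id: str = "?",
) -> float:
    """Body-water pool (mol) from the plateau (initial) method.

    N = (mol of excess isotope injected) / (excess mole-fraction enrichment at
    equilibration above background). The dose's excess label content is its
    mole fraction minus the background mole fraction.
    """
    c = resolve_constants(constants)
    ppm = c["ppm_to_mole_fraction"]
    excess_ppm = _excess_ppm(equil, background, isotope)
    if excess_ppm <= 0:
        raise InvalidStudyError(
            f"{animal_id}: non-positive {isotope} excess enrichment at equilibration "
            f"({excess_ppm:.3g} ppm)"
        )
    dose_fraction = dose.o18_fraction if isotope == "o18" else dose.h2_fraction
    background_fraction = (
        background.o18_ppm if isotope == "o18" else background.h2_ppm
    ) * ppm
    dose_mol_water = dose.dose_mass_g / c["water_molar_mass"]
    excess_mol = dose_mol_water * (dose_fraction - background_fraction)
    return excess_mol / (excess_ppm * ppm)


def dilution_space_scaling(
    n_initial_mol: float, mass_initial_kg: float, mass_final_kg: float
) -> float:
    """Final pool by the scaling method: constant body-water fraction.

    N_final = N_initial * mass_final / mass_initial.
    """
    if min(n_initial_mol, mass_initial_kg, mass_final_kg) <= 0:
        raise ValueError("pool and masses must be positive")
    return n_initial_mol * mass_final_kg / mass_initial_kg


def tbw_fraction(
    n_o_mol: float, mass_kg: float, constants: Mapping[str, float] | None = None
) -> float:
    """Total body water as percent of body mass, from the ¹⁸O space."""
    if n_o_mol <= 0 or mass_kg <= 0:
        raise ValueError("pool and mass must be positive")
    c = resolve_constants(constants)
    return 100.0 * (n_o_mol * c["water_molar_mass"]) / (mass_kg * 1000.0)


# ---------------------------------------------------------------------------
# turnover and CO2 production
# ---------------------------------------------------------------------------

def turnover_rate(
    initial: IsotopeSample,
    final: IsotopeSample,
    background: IsotopeSample,
    isotope: Literal["o18", "h2"],
    animal_id: str = "?",
) -> float:
    """Fractional turnover rate k = ln(excess_initial / excess_final) / Δt (day⁻¹)."""
    e0 = _excess_ppm(initial, background, isotope)
    e1 = _excess_ppm(final, background, isotope)
    dt = final.time_days - initial.time_days
    if dt <= 0:
        raise InvalidStudyError(f"{animal_id}: non-positive elapsed time for {isotope}")
    if e0 <= 0:
        raise InvalidStudyError(f"{animal_id}: non-positive initial {isotope} excess")
    if e1 <= 0:
        raise InvalidStudyError(f"{animal_id}: non-positive final {isotope} excess")
    if e1 >= e0:
        warnings.warn(
            f"{animal_id}: {isotope} excess did not decline ({e0:.3g} -> {e1:.3g} ppm); "
            "isotope is not turning over",
            stacklevel=2,
        )
    return float(np.log(e0 / e1) / dt)


def rco2_single_pool(
    n_mol: float,
    k: TurnoverRates,
    constants: Mapping[str, float] | None = None,
) -> float:
    """CO2 production (mol/day) by the single-pool equation (Nagy 1980).

    rCO2 = (N / 2.078) (k_o − k_d) − 0.0062 k_d N
    """
    c = resolve_constants(constants)
    rco2 = (n_mol / c["co2_denominator"]) * (k.k_o - k.k_d) - (
        c["fractionation_coeff"] * k.k_d * n_mol
    )
    if rco2 < 0:
        warnings.warn(
            f"negative CO2 production ({rco2:.4g} mol/day); turnover rates imply "
            "no net CO2 flux",
            stacklevel=2,
        )
    return rco2


def rco2_two_pool(
    spaces: DilutionSpaces,
    k: TurnoverRates,
    ratio_mode: Literal["fixed", "observed"] = "fixed",
    constants: Mapping[str, float] | None = None,
) -> float:
    """CO2 production (mol/day) by the two-pool equation (Speakman, Nair & Goran 1993).

    rCO2 = (N_o / 2.078) (k_o − R k_d) − 0.0062 R k_d N_o, with R the
    dilution-space ratio N_d/N_o, either the fixed population value (1.0427)
    or the observed per-animal ratio. R = 1 collapses onto the single-pool
    equation exactly.
    """
    c = resolve_constants(constants)
    if ratio_mode == "fixed":
        r = c["dilution_space_ratio"]
    elif ratio_mode == "observed":
        r = spaces.ratio_dil
    else:
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    n = spaces.n_o
    rco2 = (n / c["co2_denominator"]) * (k.k_o - r * k.k_d) - (
        c["fractionation_coeff"] * r * k.k_d * n
    )
    if rco2 < 0:
        warnings.warn(
            f"negative CO2 production ({rco2:.4g} mol/day)", stacklevel=2
        )
    return rco2


def mol_day_to_ml_g_hr(
    rco2_mol_day: float, mean_mass_kg: float, constants: Mapping[str, float] | None = None
) -> float:
    """Convert CO2 production from mol/day to the mass-specific ml g⁻¹ hr⁻¹ scale."""
    c = resolve_constants(constants)
    ml_day = rco2_mol_day * c["molar_volume_stp"] * 1000.0
    return ml_day / (mean_mass_kg * 1000.0) / 24.0


def fmr_from_co2(
    rco2_ml_g_hr: float,
    mass_initial_kg: float,
    mass_final_kg: float,
    constants: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Field metabolic rate (W, W/kg) from mass-specific CO2 production.

    Uses the arithmetic mean of initial and final mass and the configured
    energy equivalent (default 23.6 kJ per liter CO2).
    """
    if mass_initial_kg <= 0 or mass_final_kg <= 0:
        raise ValueError("masses must be positive")
    c = resolve_constants(constants)
    mean_mass = 0.5 * (mass_initial_kg + mass_final_kg)
    # ml/g/hr * kg = L/hr of CO2; * kJ/L -> kJ/hr; /3.6 -> W
    watts = rco2_ml_g_hr * mean_mass * c["energy_per_l_co2"] / 3.6
    return watts, watts / mean_mass


# ---------------------------------------------------------------------------
# water flux
# ---------------------------------------------------------------------------

def water_flux(
    n_d_initial_mol: float,
    n_d_final_mol: float,
    k_d: float,
    interval_days: float,
    mean_mass_kg: float,
    constants: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Water influx and efflux (ml kg⁻¹ day⁻¹) for a linearly changing pool.

    Efflux follows Nagy & Costa (1980) eq. 5, using the log-mean pool
    N̄ = (N₂ − N₁)/ln(N₂/N₁) (steady-pool limit: efflux = k_d N). Influx is
    efflux plus the pool-change rate (eq. 6 structure), so
    influx − efflux = (N₂ − N₁)/Δt identically.
    """
    if n_d_initial_mol <= 0 or n_d_final_mol <= 0:
        raise ValueError("pools must be positive")
    c = resolve_constants(constants)
    n1, n2 = n_d_initial_mol, n_d_final_mol
    if np.isclose(n1, n2):
        n_bar = 0.5 * (n1 + n2)
    else:
        n_bar = (n2 - n1) / np.log(n2 / n1)
    efflux_mol_day = k_d * n_bar
    influx_mol_day = efflux_mol_day + (n2 - n1) / interval_days
    to_ml_kg_day = c["water_molar_mass"] / mean_mass_kg  # mol/day -> ml/kg/day (1 g ~ 1 ml)
    return influx_mol_day * to_ml_kg_day, efflux_mol_day * to_ml_kg_day


# ---------------------------------------------------------------------------
# at-sea correction
# ---------------------------------------------------------------------------

def at_sea_fmr(
    fmr_total_wkg: float,
    interval_days: float,
    time_at_sea_days: float,
    onshore: OnshoreRateSpec,
    mass_kg: float = np.nan,
) -> tuple[float, list[str]]:
    """Time-budget partition of whole-interval FMR into an at-sea rate.

    at_sea = (fmr_total * interval − onshore_rate * (interval − t_sea)) / t_sea

    Returns (value, flags). A non-positive result is returned flagged
    'invalid-partition' rather than raised, so cohort runs can proceed.
    """
    if not (0 < time_at_sea_days <= interval_days):
        raise ValueError("require 0 < time_at_sea_days <= interval_days")
    if time_at_sea_days == interval_days:
        return fmr_total_wkg, []
    onshore_rate = onshore.resolve(mass_kg)
    value = (
        fmr_total_wkg * interval_days - onshore_rate * (interval_days - time_at_sea_days)
    ) / time_at_sea_days
    flags = []
    if value <= 0:
        flags.append("invalid-partition")
    return value, flags


# ---------------------------------------------------------------------------
# full-study processing and uncertainty
# ---------------------------------------------------------------------------

def _rco2_chain_ml_g_hr(
    study: IsotopeStudy,
    o18_bg: float,
    h2_bg: float,
    o18_eq: float,
    h2_eq: float,
    o18_fin: float,
    h2_fin: float,
    t_eq: float,
    t_fin: float,
    equation: Literal["speakman", "nagy"],
    ratio_mode: Literal["fixed", "observed"],
    c: Mapping[str, float],
):
    """Vectorized core: enrichments (scalars or arrays, ppm absolute) -> rCO2.

    Returns (rco2_ml_g_hr, n_o, n_d, k_o, k_d) with the same broadcast shape
    as the enrichment inputs. Non-finite where a draw is unphysical.
    """
    ppm = c["ppm_to_mole_fraction"]
    dose = study.dose
    dose_mol = dose.dose_mass_g / c["water_molar_mass"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex_o_eq = np.asarray(o18_eq - o18_bg, dtype=float)
        ex_h_eq = np.asarray(h2_eq - h2_bg, dtype=float)
        ex_o_fin = np.asarray(o18_fin - o18_bg, dtype=float)
        ex_h_fin = np.asarray(h2_fin - h2_bg, dtype=float)
        bad = (ex_o_eq <= 0) | (ex_h_eq <= 0) | (ex_o_fin <= 0) | (ex_h_fin <= 0)
        n_o = dose_mol * (dose.o18_fraction - o18_bg * ppm) / (ex_o_eq * ppm)
        n_d = dose_mol * (dose.h2_fraction - h2_bg * ppm) / (ex_h_eq * ppm)
        dt = t_fin - t_eq
        k_o = np.log(ex_o_eq / ex_o_fin) / dt
        k_d = np.log(ex_h_eq / ex_h_fin) / dt
        # mean ¹⁸O pool across the interval (plateau initial, scaling final)
        n_o_mean = 0.5 * n_o * (1.0 + study.mass_final_kg / study.mass_initial_kg)
        if equation == "speakman":
            r = c["dilution_space_ratio"] if ratio_mode == "fixed" else n_d / n_o
        else:
            r = 1.0
        rco2_mol_day = (n_o_mean / c["co2_denominator"]) * (k_o - r * k_d) - (
            c["fractionation_coeff"] * r * k_d * n_o_mean
        )
        mean_mass = 0.5 * (study.mass_initial_kg + study.mass_final_kg)
        rco2 = rco2_mol_day * c["molar_volume_stp"] * 1000.0 / (mean_mass * 1000.0) / 24.0
        rco2 = np.where(bad, np.nan, rco2)
    return rco2, n_o, n_d, k_o, k_d


def rco2_uncertainty(
    study: IsotopeStudy,
    analytical_sd_ppm: Mapping[str, float],
    n_draws: int = 10_000,
    seed: int = 20180402,
    equation: Literal["speakman", "nagy"] = "speakman",
    ratio_mode: Literal["fixed", "observed"] = "fixed",
    constants: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Monte-Carlo 95% interval on CO2 production (ml g⁻¹ hr⁻¹).

    Each of the six measured enrichments (two isotopes × background /
    equilibration / final) is resampled from a Gaussian centred on the
    triplicate mean with the stated per-isotope analytical SD, the full
    estimation chain is recomputed per draw, and the central 95% interval of
    the draws is returned. Deterministic for a given seed.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    c = resolve_constants(constants)
    rng = np.random.default_rng(seed)
    bg = study.sample("background")
    eq = study.sample("equilibration")
    fin = study.sample("final")
    sd_o = float(analytical_sd_ppm.get("o18", 0.0))
    sd_h = float(analytical_sd_ppm.get("h2", 0.0))

    def draw(center: float, sd: float) -> np.ndarray:
        return center + sd * rng.standard_normal(n_draws)

    rco2, *_ = _rco2_chain_ml_g_hr(
        study,
        draw(bg.o18_ppm, sd_o), draw(bg.h2_ppm, sd_h),
        draw(eq.o18_ppm, sd_o), draw(eq.h2_ppm, sd_h),
        draw(fin.o18_ppm, sd_o), draw(fin.h2_ppm, sd_h),
        eq.time_days, fin.time_days, equation, ratio_mode, c,
    )
    rco2 = rco2[np.isfinite(rco2)]
    lo, hi = np.percentile(rco2, [2.5, 97.5])
    return float(lo), float(hi)


def process_study(
    study: IsotopeStudy,
    onshore: OnshoreRateSpec | None = None,
    analytical_sd_ppm: Mapping[str, float] | None = None,
    n_draws: int = 10_000,
    seed: int = 20180402,
    ratio_mode: Literal["fixed", "observed"] = "fixed",
    constants: Mapping[str, float] | None = None,
) -> EnergeticsResult:
    """Run the complete DLW chain for one study.

    Dilution spaces use the plateau method at equilibration and the scaling
    method for the final pool; turnover rates come from the decline of excess
    enrichment between the equilibration and final samples; CO2 production
    uses the mean ¹⁸O pool; FMR conversion uses the mean body mass; water flux
    uses the ²H pools with the linearly-changing-pool efflux equation.
    """
    c = resolve_constants(constants)
    bg = study.sample("background")
    eq = study.sample("equilibration")
    fin = study.sample("final")

    n_o = dilution_space_plateau(study.dose, "o18", eq, bg, c, study.animal_id)
    n_d = dilution_space_plateau(study.dose, "h2", eq, bg, c, study.animal_id)
    n_o_fin = dilution_space_scaling(n_o, study.mass_initial_kg, study.mass_final_kg)
    n_d_fin = dilution_space_scaling(n_d, study.mass_initial_kg, study.mass_final_kg)
    spaces = DilutionSpaces(n_o=n_o, n_d=n_d, method="plateau")

    k_o = turnover_rate(eq, fin, bg, "o18", study.animal_id)
    k_d = turnover_rate(eq, fin, bg, "h2", study.animal_id)
    k = TurnoverRates(k_o=k_o, k_d=k_d)

    mean_mass = 0.5 * (study.mass_initial_kg + study.mass_final_kg)
    n_o_mean = 0.5 * (n_o + n_o_fin)
    spaces_mean = DilutionSpaces(n_o=n_o_mean, n_d=n_d * n_o_mean / n_o, method="plateau")

    rco2_nagy = mol_day_to_ml_g_hr(rco2_single_pool(n_o_mean, k, c), mean_mass, c)
    rco2_spk = mol_day_to_ml_g_hr(
        rco2_two_pool(spaces_mean, k, ratio_mode=ratio_mode, constants=c), mean_mass, c
    )
    w_nagy, wkg_nagy = fmr_from_co2(rco2_nagy, study.mass_initial_kg, study.mass_final_kg, c)
    w_spk, wkg_spk = fmr_from_co2(rco2_spk, study.mass_initial_kg, study.mass_final_kg, c)

    influx, efflux = water_flux(n_d, n_d_fin, k_d, study.interval_days, mean_mass, c)
    tbw = tbw_fraction(n_o, study.mass_initial_kg, c)

    result = EnergeticsResult(
        animal_id=study.animal_id,
        n_o_mol=n_o,
        n_d_mol=n_d,
        k_o=k_o,
        k_d=k_d,
        rco2_nagy_ml_g_hr=rco2_nagy,
        rco2_speakman_ml_g_hr=rco2_spk,
        fmr_w_nagy=w_nagy,
        fmr_w_speakman=w_spk,
        fmr_wkg_nagy=wkg_nagy,
        fmr_wkg_speakman=wkg_spk,
        tbw_percent=tbw,
        influx_ml_kg_day=influx,
        efflux_ml_kg_day=efflux,
    )

    if onshore is not None and np.isfinite(study.time_at_sea_days):
        value, flags = at_sea_fmr(
            wkg_spk, study.interval_days, study.time_at_sea_days, onshore, mean_mass
        )
        result.at_sea_fmr_wkg = value
        result.flags.extend(flags)

    if analytical_sd_ppm is not None:
        result.ci_low, result.ci_high = rco2_uncertainty(
            study, analytical_sd_ppm, n_draws=n_draws, seed=seed,
            ratio_mode=ratio_mode, constants=c,
        )
    return result
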