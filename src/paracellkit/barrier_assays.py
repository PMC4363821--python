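"""Transepithelial barrier computations.

This module turns raw Transwell measurements into the three quantities that
characterise the paracellular pathway of an epithelial monolayer:

* **TER** — transepithelial electrical resistance, blank-corrected and
  area-normalised (Ohm*cm^2).
* **eta = P_Na/P_Cl** — charge selectivity, obtained by inverting the
  Goldman-Hodgkin-Katz (GHK) dilution-potential relation for a NaCl
  dilution experiment (isosmotic replacement of NaCl by sucrose on the
  basolateral side).
* **P_Na, P_Cl** — absolute ionic permeabilities (cm/s), obtained from TER
  and eta with the Kimizuka-Koketsu conductance relation.

The dilution-potential model considers only Na+ and Cl-: K+, Ca2+ and Mg2+
are present at identical concentrations in both baths, so their GHK terms
cancel and they carry no information about selectivity.  Under the sign
convention used here the potential is apical minus basolateral with the
full-strength bath (solution A) apical; a cation-selective monolayer then
shows a positive dilution potential.

A single-timepoint tracer-flux assay (apparent permeability
P = (dQ/dt)/(A*C0) with linear accumulation) and a small per-condition
summary pipeline complete the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .constants import FARADAY, MM_TO_MOL_PER_CM3, R_GAS, T_BODY_K
from .errors import (
    DegenerateDesignError,
    InvalidMeasurementError,
    OutOfRangeError,
    ParacellError,
)

__all__ = [
    "IonicSolution",
    "EphysMeasurement",
    "BarrierResult",
    "TracerAssay",
    "TracerResult",
    "StandardCurve",
    "ConditionSummary",
    "compute_ter",
    "ghk_dilution_potential",
    "invert_dilution_potential",
    "nernst_limits_mV",
    "kimizuka_koketsu",
    "fit_standard_curve",
    "tracer_permeability",
    "ephys_pipeline",
    "bath_concentration",
    "DEFAULT_FILTER_AREA_CM2",
]

#: 12-mm Transwell insert growth area, cm^2
DEFAULT_FILTER_AREA_CM2 = 1.12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonicSolution:
    """Named ion concentrations of one bath recipe (all mM)."""

    na_mM: float
    k_mM: float
    cl_mM: float
    ca_mM: float
    mg_mM: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("na_mM", "k_mM", "cl_mM", "ca_mM", "mg_mM"):
            if getattr(self, name) < 0:
                raise OutOfRangeError(f"{name} must be non-negative, got {getattr(self, name)}")

    @classmethod
    def from_salts(
        cls,
        nacl_mM: float,
        kcl_mM: float = 5.0,
        cacl2_mM: float = 1.0,
        mgcl2_mM: float = 1.0,
        label: str = "",
        cl_accounting: str = "full",
    ) -> "IonicSolution":
        """Build a recipe from salt amounts.

        ``cl_accounting='full'`` counts every chloride-bearing salt
        (Cl = NaCl + KCl + 2*CaCl2 + 2*MgCl2); ``'nacl_only'`` counts only
        the NaCl contribution.
        """
        if cl_accounting == "full":
            cl = nacl_mM + kcl_mM + 2.0 * cacl2_mM + 2.0 * mgcl2_mM
        elif cl_accounting == "nacl_only":
            cl = nacl_mM
        else:
            raise OutOfRangeError(f"unknown cl_accounting {cl_accounting!r}")
        return cls(na_mM=nacl_mM, k_mM=kcl_mM, cl_mM=cl, ca_mM=cacl2_mM, mg_mM=mgcl2_mM, label=label)

    @classmethod
    def solution_a(cls, cl_accounting: str = "full") -> "IonicSolution":
        """Full-strength bath: 140 mM NaCl, 5 KCl, 1 CaCl2, 1 MgCl2."""
        return cls.from_salts(140.0, label="A", cl_accounting=cl_accounting)

    @classmethod
    def solution_b(cls, cl_accounting: str = "full") -> "IonicSolution":
        """Half-NaCl bath: 70 mM NaCl (sucrose-substituted), 5 KCl, 1 CaCl2, 1 MgCl2."""
        return cls.from_salts(70.0, label="B", cl_accounting=cl_accounting)


@dataclass(frozen=True)
class EphysMeasurement:
    """One filter on one day: raw resistances plus the dilution potential."""

    raw_resistance_ohm: float
    blank_resistance_ohm: float
    filter_area_cm2: float
    dilution_potential_mV: float
    apical: IonicSolution
    basolateral: IonicSolution
    condition: str = ""
    day: int = 0
    replicate_id: str = ""
    temperature_K: float = T_BODY_K

    def ter_ohm_cm2(self) -> float:
        return compute_ter(self.raw_resistance_ohm, self.blank_resistance_ohm, self.filter_area_cm2)


@dataclass(frozen=True)
class BarrierResult:
    """Derived barrier parameters for one filter."""

    ter_ohm_cm2: float
    eta: float
    p_na: float
    p_cl: float
    condition: str = ""
    day: int = 0
    replicate_id: str = ""


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of fluorescence on concentration, with the inverse mapping."""

    slope: float
    intercept: float
    r_squared: float

    def fluorescence(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration

    def concentration(self, fluorescence: float) -> float:
        return (fluorescence - self.intercept) / self.slope


@dataclass(frozen=True)
class TracerAssay:
    """Single-timepoint flux assay: basolateral tracer, apical collection."""

    standard_curve: Sequence[tuple[float, float]]
    sample_fluorescence: float
    apical_volume_cm3: float
    duration_s: float
    area_cm2: float
    c0: float  # basolateral tracer concentration, mol/cm^3
    tracer: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise OutOfRangeError("duration_s must be positive")
        if self.c0 <= 0:
            raise OutOfRangeError("c0 must be positive")


@dataclass(frozen=True)
class TracerResult:
    p_cm_s: float
    below_curve: bool = False


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    quantity: str  # TER | eta | p_na | p_cl | flux_P
    n: int
    mean: float
    sem: float
    day: int = 0
    degenerate_n: bool = False


# ---------------------------------------------------------------------------
# core computations
# ---------------------------------------------------------------------------

def compute_ter(
    raw_resistance_ohm: float,
    blank_resistance_ohm: float,
    filter_area_cm2: float,
) -> float:
    """Blank-corrected, area-normalised transepithelial resistance (Ohm*cm^2).

    Raises :class:`InvalidMeasurementError` when the monolayer reads below
    the blank filter -- such a record is physically impossible and is
    rejected rather than clamped to zero.
    """
    if raw_resistance_ohm <= 0 or blank_resistance_ohm <= 0 or filter_area_cm2 <= 0:
        raise OutOfRangeError("resistances and area must be positive")
    if raw_resistance_ohm < blank_resistance_ohm:
        raise InvalidMeasurementError(
            f"raw resistance {raw_resistance_ohm} Ohm below blank {blank_resistance_ohm} Ohm: "
            "invalid monolayer record"
        )
    return (raw_resistance_ohm - blank_resistance_ohm) * filter_area_cm2


def _check_solutions(apical: IonicSolution, basolateral: IonicSolution) -> None:
    if min(apical.na_mM, basolateral.na_mM, apical.cl_mM, basolateral.cl_mM) <= 0:
        raise OutOfRangeError("Na and Cl must be present (>0 mM) on both sides")


def ghk_dilution_potential(
    eta: float,
    apical: IonicSolution,
    basolateral: IonicSolution,
    temperature_K: float = T_BODY_K,
) -> float:
    """GHK dilution potential (mV, apical minus basolateral) for a given eta.

    V = (RT/F) * ln[(eta*Na_ap + Cl_bl) / (eta*Na_bl + Cl_ap)]

    Only Na+ and Cl- enter; all other ions are assumed symmetric across the
    baths.  Strictly increasing in eta whenever Na is diluted basolaterally,
    bounded by the Cl- and Na+ Nernst potentials.
    """
    if eta <= 0 or not math.isfinite(eta):
        raise OutOfRangeError(f"eta must be positive and finite, got {eta}")
    _check_solutions(apical, basolateral)
    rtf_mV = 1000.0 * R_GAS * temperature_K / FARADAY
    num = eta * apical.na_mM + basolateral.cl_mM
    den = eta * basolateral.na_mM + apical.cl_mM
    return rtf_mV * math.log(num / den)


def nernst_limits_mV(
    apical: IonicSolution,
    basolateral: IonicSolution,
    temperature_K: float = T_BODY_K,
) -> tuple[float, float]:
    """(Cl- limit, Na+ limit) of the dilution potential, mV.

    These are the eta -> 0 and eta -> inf limits of the GHK expression; any
    measurable dilution potential must lie strictly between them.
    """
    _check_solutions(apical, basolateral)
    rtf_mV = 1000.0 * R_GAS * temperature_K / FARADAY
    v_cl = rtf_mV * math.log(basolateral.cl_mM / apical.cl_mM)
    v_na = rtf_mV * math.log(apical.na_mM / basolateral.na_mM)
    return v_cl, v_na


def invert_dilution_potential(
    potential_mV: float,
    apical: IonicSolution,
    basolateral: IonicSolution,
    temperature_K: float = T_BODY_K,
) -> float:
    """Closed-form inverse of :func:`ghk_dilution_potential`.

    With x = exp(V*F/RT):  eta = (Cl_ap*x - Cl_bl) / (Na_ap - x*Na_bl).
    Raises :class:`OutOfRangeError` when the potential is at or outside the
    Nernst limits for the given solutions.
    """
    v_cl, v_na = nernst_limits_mV(apical, basolateral, temperature_K)
    lo, hi = min(v_cl, v_na), max(v_cl, v_na)
    if not lo < potential_mV < hi:
        raise OutOfRangeError(
            f"potential {potential_mV:.3f} mV outside the admissible open interval "
            f"(Cl- limit {v_cl:.3f} mV, Na+ limit {v_na:.3f} mV)"
        )
    x = math.exp(potential_mV * FARADAY / (1000.0 * R_GAS * temperature_K))
    return (apical.cl_mM * x - basolateral.cl_mM) / (apical.na_mM - x * basolateral.na_mM)


def kimizuka_koketsu(
    ter_ohm_cm2: float,
    eta: float,
    c_mol_per_cm3: float,
    temperature_K: float = T_BODY_K,
) -> tuple[float, float]:
    """Absolute permeabilities (P_Na, P_Cl) in cm/s from TER and eta.

    For a symmetric NaCl bath of concentration C the GHK slope conductance is
    G = (F^2/RT) * C * (P_Na + P_Cl); identifying G with 1/TER gives the
    total permeability, which eta splits into the two ions:

        P_Na + P_Cl = RT / (F^2 * C * TER)
        P_Na = total * eta/(1+eta),   P_Cl = total / (1+eta)
    """
    if min(ter_ohm_cm2, eta, c_mol_per_cm3, temperature_K) <= 0:
        raise OutOfRangeError("TER, eta, C and T must all be positive")
    total = R_GAS * temperature_K / (FARADAY**2 * c_mol_per_cm3 * ter_ohm_cm2)
    p_na = total * eta / (1.0 + eta)
    return p_na, total - p_na


# ---------------------------------------------------------------------------
# tracer flux
# ---------------------------------------------------------------------------

def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of fluorescence on known concentration."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateDesignError("need >= 2 (concentration, fluorescence) pairs")
    conc, fluor = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise DegenerateDesignError("all standard concentrations identical: slope undefined")
    fit = _sps.linregress(conc, fluor)
    r2 = float(fit.rvalue**2) if np.unique(fluor).size > 1 else 1.0
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=r2)


def tracer_permeability(assay: TracerAssay) -> TracerResult:
    """Apparent permeability P = (dQ/dt)/(A*C0), cm/s.

    Q is the amount of tracer collected apically at the single timepoint,
    obtained from the sample fluorescence through the standard curve;
    accumulation is assumed linear over the collection window.  A sample
    reading below the curve intercept yields P = 0 with a warning flag
    rather than a negative permeability.
    """
    curve = fit_standard_curve(assay.standard_curve)
    conc = curve.concentration(assay.sample_fluorescence)
    if conc < 0:
        warnings.warn(
            f"sample fluorescence {assay.sample_fluorescence} below the standard-curve "
            "intercept; permeability clamped to 0",
            stacklevel=2,
        )
        return TracerResult(0.0, below_curve=True)
    q_mol = assay.apical_volume_cm3 * conc
    dq_dt = q_mol / assay.duration_s
    return TracerResult(dq_dt / (assay.area_cm2 * assay.c0), below_curve=False)


# ---------------------------------------------------------------------------
# per-condition pipeline
# ---------------------------------------------------------------------------

def bath_concentration(
    record: EphysMeasurement,
    c_mode: str = "apical",
    c_override: float | None = None,
) -> float:
    """NaCl concentration (mol/cm^3) entering the Kimizuka-Koketsu relation.

    ``'apical'`` (default) uses the apical Na concentration; ``'logmean'``
    uses the logarithmic mean of the two bath Na concentrations;
    ``'override'`` uses an explicit value in mol/cm^3.
    """
    if c_mode == "override":
        if c_override is None or c_override <= 0:
            raise OutOfRangeError("c_override must be a positive mol/cm^3 value")
        return c_override
    if c_mode == "apical":
        return record.apical.na_mM * MM_TO_MOL_PER_CM3
    if c_mode == "logmean":
        a, b = record.apical.na_mM, record.basolateral.na_mM
        lm = a if a == b else (a - b) / math.log(a / b)
        return lm * MM_TO_MOL_PER_CM3
    raise OutOfRangeError(f"unknown c_mode {c_mode!r}")


def _mean_sem(values: Sequence[float]) -> tuple[float, float, bool]:
    # local import avoided: identical convention as stats.mean_sem, kept tiny here
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateDesignError("no values to summarise")
    if arr.size == 1:
        return float(arr[0]), 0.0, True
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size)), False


def ephys_pipeline(
    records: Iterable[EphysMeasurement],
    c_mode: str = "apical",
    c_override: float | None = None,
    averaging: str = "per_record",
) -> tuple[list[BarrierResult], list[ConditionSummary]]:
    """Per-filter barrier parameters plus per-(condition, day) summaries.

    ``averaging='per_record'`` (default) computes TER, eta, P_Na, P_Cl per
    filter and then averages; ``'pooled'`` first averages TER and dilution
    potential within each (condition, day) group and derives eta and the
    permeabilities from the group means (n is reported, SEMs are those of
    the underlying TER/potential propagation and are reported as 0).
    """
    records = list(records)
    if not records:
        raise DegenerateDesignError("no ephys records")
    if averaging not in ("per_record", "pooled"):
        raise OutOfRangeError(f"unknown averaging mode {averaging!r}")

    results: list[BarrierResult] = []
    for rec in records:
        ter = rec.ter_ohm_cm2()
        eta = invert_dilution_potential(
            rec.dilution_potential_mV, rec.apical, rec.basolateral, rec.temperature_K
        )
        c = bath_concentration(rec, c_mode, c_override)
        p_na, p_cl = kimizuka_koketsu(ter, eta, c, rec.temperature_K)
        results.append(
            BarrierResult(ter, eta, p_na, p_cl, rec.condition, rec.day, rec.replicate_id)
        )

    groups: dict[tuple[str, int], list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault((rec.condition, rec.day), []).append(i)

    summaries: list[ConditionSummary] = []
    for (condition, day), idx in groups.items():
        areas = {records[i].filter_area_cm2 for i in idx}
        if len(areas) > 1:
            warnings.warn(
                f"mixed filter areas {sorted(areas)} within condition {condition!r} day {day}",
                stacklevel=2,
            )
        if averaging == "per_record":
            per_q = {
                "TER": [results[i].ter_ohm_cm2 for i in idx],
                "eta": [results[i].eta for i in idx],
                "p_na": [results[i].p_na for i in idx],
                "p_cl": [results[i].p_cl for i in idx],
            }
            for quantity, vals in per_q.items():
                mean, sem, degen = _mean_sem(vals)
                summaries.append(
                    ConditionSummary(condition, quantity, len(vals), mean, sem, day, degen)
                )
        else:  # pooled
            mean_ter, _, _ = _mean_sem([results[i].ter_ohm_cm2 for i in idx])
            mean_v, _, _ = _mean_sem([records[i].dilution_potential_mV for i in idx])
            ref = records[idx[0]]
            eta = invert_dilution_potential(mean_v, ref.apical, ref.basolateral, ref.temperature_K)
            c = bath_concentration(ref, c_mode, c_override)
            p_na, p_cl = kimizuka_koketsu(mean_ter, eta, c, ref.temperature_K)
            n = len(idx)
            for quantity, value in (("TER", mean_ter), ("eta", eta), ("p_na", p_na), ("p_cl", p_cl)):
                summaries.append(ConditionSummary(condition, quantity, n, value, 0.0, day, n == 1))
    return results, summaries
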