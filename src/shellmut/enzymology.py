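"""Quantitative enzymology: activity units, Michaelis-Menten kinetics,
fold changes, activity profiles, and stability/degradation bookkeeping.

Activity follows the ABTS laccase assay convention: absorbance at 420 nm,
molar extinction coefficient 38,000 M^-1 cm^-1, one unit (U) = 1 umol of
product per minute.  Kinetic parameters are obtained by nonlinear least
squares on the Michaelis-Menten rate law

    v = Vmax [S] / (Km + [S]),

with kcat = Vmax / (amount of enzyme) and catalytic efficiency kcat/Km;
standard errors come from the fit covariance, the efficiency SE by the
delta method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

ABTS_EXTINCTION = 38_000.0  # M^-1 cm^-1 at 420 nm


@dataclass(frozen=True)
class ActivityMeasurement:
    """One spectrophotometric activity reading.

    delta_absorbance is the A420 change over ``time`` minutes in a reaction
    of ``reaction_volume`` litres read through ``path_length`` cm;
    ``enzyme_mass`` is the grams of enzyme in the reaction before dilution.
    """

    delta_absorbance: float
    time: float  # min
    enzyme_mass: float  # g
    reaction_volume: float = 1.0e-3  # L
    path_length: float = 1.0  # cm
    extinction: float = ABTS_EXTINCTION  # M^-1 cm^-1
    dilution_factor: float = 1.0


def specific_activity(m: ActivityMeasurement) -> float:
    """Specific activity in U per g (U = umol product per minute)."""
    if m.time <= 0:
        raise ValueError("time must be positive")
    if m.enzyme_mass <= 0:
        raise ValueError("enzyme_mass must be positive")
    for name in ("reaction_volume", "path_length", "extinction", "dilution_factor"):
        if getattr(m, name) <= 0:
            raise ValueError(f"{name} must be positive")
    # Beer-Lambert: dA/dt / (eps * l) is a molar concentration rate;
    # times volume (mol/min), times 1e6 (umol/min), times dilution.
    umol_per_min = (
        (m.delta_absorbance / m.time)
        / (m.extinction * m.path_length)
        * m.reaction_volume
        * 1e6
        * m.dilution_factor
    )
    return umol_per_min / m.enzyme_mass


@dataclass
class KineticDataset:
    """Rate-vs-substrate data for one enzyme/substrate pair.

    substrate in mM, rates in umol product per minute per reaction,
    enzyme_concentration in uM, reaction_volume in litres.  Replicate rates
    at repeated substrate levels are allowed.
    """

    substrate: np.ndarray  # mM
    rates: np.ndarray  # umol/min per reaction
    enzyme_concentration: float  # uM
    reaction_volume: float = 1.0e-3  # L
    enzyme_id: str = ""

    def __post_init__(self) -> None:
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.substrate.shape != self.rates.shape:
            raise ValueError("substrate and rates must have the same shape")
        if np.unique(self.substrate).size < 4:
            raise ValueError("need at least 4 distinct substrate levels")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.enzyme_concentration <= 0 or self.reaction_volume <= 0:
            raise ValueError("enzyme concentration and volume must be positive")

    @property
    def enzyme_umol(self) -> float:
        """Amount of enzyme in the reaction, umol (uM x L)."""
        return self.enzyme_concentration * self.reaction_volume


class KineticFitError(RuntimeError):
    pass


@dataclass
class MichaelisMentenResults:
    """Fitted Michaelis-Menten parameters with uncertainties."""

    Km: float  # mM
    Km_se: float
    kcat: float  # min^-1
    kcat_se: float
    efficiency: float  # kcat/Km, mM^-1 min^-1
    efficiency_se: float
    Vmax: float  # umol/min per reaction
    cov: np.ndarray  # 2x2 covariance of (Km, Vmax)
    data: KineticDataset
    efficiency_replicate_mean: float | None = None

    def summary(self) -> str:
        lines = [
            f"Michaelis-Menten fit{': ' + self.data.enzyme_id if self.data.enzyme_id else ''}",
            f"  n obs             {self.data.rates.size}",
            f"  Km     (mM)       {self.Km:.3f} +/- {self.Km_se:.3f}",
            f"  kcat   (min^-1)   {self.kcat:.3f} +/- {self.kcat_se:.3f}",
            f"  kcat/Km (mM^-1 min^-1) {self.efficiency:.3f} +/- {self.efficiency_se:.3f}",
        ]
        if self.efficiency_replicate_mean is not None:
            lines.append(
                f"  kcat/Km, replicate-ratio mean {self.efficiency_replicate_mean:.3f}"
            )
        return "\n".join(lines)


class MichaelisMenten:
    """Michaelis-Menten rate model for one kinetic dataset.

    ``fit()`` runs positivity-bounded nonlinear least squares initialised at
    Km0 = median substrate, Vmax0 = max rate, and returns a
    :class:`MichaelisMentenResults`.
    """

    def __init__(self, data: KineticDataset):
        self.data = data

    @staticmethod
    def rate(s, Km, Vmax):
        return Vmax * s / (Km + s)

    def _replicate_splits(self) -> list[np.ndarray] | None:
        """Index sets splitting the data into balanced replicate series.

        The k-th replicate series takes the k-th occurrence of every
        substrate level; returns None when levels are unreplicated or
        unbalanced.
        """
        d = self.data
        levels, inverse, counts = np.unique(
            d.substrate, return_inverse=True, return_counts=True
        )
        r = counts[0]
        if r < 2 or not np.all(counts == r):
            return None
        occurrence = np.zeros(d.substrate.size, dtype=int)
        seen = {}
        for i, lev in enumerate(inverse):
            occurrence[i] = seen.get(lev, 0)
            seen[lev] = occurrence[i] + 1
        return [np.flatnonzero(occurrence == k) for k in range(r)]

    def fit(self, replicate_efficiency: bool = False) -> MichaelisMentenResults:
        """Fit the rate law; optionally also report the mean of per-replicate
        kcat/Km ratios (published tables sometimes average replicate ratios
        instead of dividing the pooled estimates)."""
        result = self._fit_once(self.data)
        if replicate_efficiency:
            splits = self._replicate_splits()
            if splits is not None:
                ratios = []
                for idx in splits:
                    sub = KineticDataset(
                        substrate=self.data.substrate[idx],
                        rates=self.data.rates[idx],
                        enzyme_concentration=self.data.enzyme_concentration,
                        reaction_volume=self.data.reaction_volume,
                        enzyme_id=self.data.enzyme_id,
                    )
                    ratios.append(self._fit_once(sub).efficiency)
                result.efficiency_replicate_mean = float(np.mean(ratios))
        return result

    def _fit_once(self, d: KineticDataset) -> MichaelisMentenResults:
        p0 = (float(np.median(d.substrate)), float(d.rates.max()))
        try:
            popt, pcov = curve_fit(
                self.rate,
                d.substrate,
                d.rates,
                p0=p0,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10_000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except RuntimeError as exc:
            raise KineticFitError(
                f"Michaelis-Menten fit did not converge (p0={p0}): {exc}"
            ) from exc
        Km, Vmax = popt
        if Km <= 0 or Vmax <= 0:
            raise KineticFitError(f"non-positive parameter estimate: Km={Km}, Vmax={Vmax}")
        Km_se, Vmax_se = np.sqrt(np.diag(pcov))

        kcat = Vmax / d.enzyme_umol
        kcat_se = Vmax_se / d.enzyme_umol
        eff = kcat / Km
        # delta method on f(Km, Vmax) = Vmax / (E * Km)
        grad = np.array([-eff / Km, eff / Vmax])
        eff_var = float(grad @ pcov @ grad)
        eff_se = float(np.sqrt(max(eff_var, 0.0)))

        return MichaelisMentenResults(
            Km=float(Km),
            Km_se=float(Km_se),
            kcat=float(kcat),
            kcat_se=float(kcat_se),
            efficiency=float(eff),
            efficiency_se=eff_se,
            Vmax=float(Vmax),
            cov=pcov,
            data=d,
        )


def fit_michaelis_menten(
    data: KineticDataset, replicate_efficiency: bool = False
) -> MichaelisMentenResults:
    """Convenience wrapper: fit the Michaelis-Menten model to one dataset."""
    return MichaelisMenten(data).fit(replicate_efficiency=replicate_efficiency)


def fold_change(value_mut: float, value_wt: float) -> float:
    """Ratio mutant / wild type (report to 2 decimals in summary tables)."""
    if value_wt <= 0:
        raise ValueError("wild-type value must be positive")
    return value_mut / value_wt


@dataclass
class ActivityProfile:
    """Relative-activity profile over a condition axis (temperature or pH).

    Values are normalised so the maximum is 100; ``optimum`` is the condition
    at the maximum (ties resolve to the lowest condition and are flagged).
    """

    conditions: np.ndarray
    relative: np.ndarray  # percent, max = 100
    optimum: float
    tied_optimum: bool = False


def relative_profile(conditions, raw_activities) -> ActivityProfile:
    """Normalise raw activities to percent of the maximum."""
    cond = np.asarray(conditions, dtype=float)
    raw = np.asarray(raw_activities, dtype=float)
    if cond.shape != raw.shape:
        raise ValueError("conditions and activities must have the same shape")
    if cond.size < 2:
        raise ValueError("need at least 2 conditions")
    if np.any(raw < 0):
        raise ValueError("activities must be non-negative")
    peak = raw.max()
    if peak <= 0:
        raise ValueError("all activities are zero; cannot normalise")
    rel = raw / peak * 100.0
    at_max = np.isclose(raw, peak)
    tied = at_max.sum() > 1
    if tied:
        logger.warning("tied maximum activity; optimum set to the lowest condition")
    optimum = float(cond[at_max].min())
    return ActivityProfile(conditions=cond, relative=rel, optimum=optimum, tied_optimum=tied)


def residual_activity(values, reference: float) -> np.ndarray:
    """Percent activity remaining relative to the t = 0 reference."""
    if reference is None or reference <= 0:
        raise ValueError("t=0 reference activity must be positive")
    return np.asarray(values, dtype=float) / reference * 100.0


@dataclass(frozen=True)
class StabilityRecord:
    """Melting temperature and computed structure energy for one enzyme."""

    enzyme: str
    Tm: float  # degrees C
    dG_stability: float  # J
    ddG_vs_wt: float | None = None  # J, as printed in the source table


def stability_deltas(
    records: list[StabilityRecord], wt_id: str, tol: float = 0.005
) -> pd.DataFrame:
    """Tabulate delta-Tm and delta-delta-G of each enzyme against the wild type.

    The stored ddG column is passed through verbatim; a recomputed
    ``ddG_recomputed`` = dG_mut - dG_wt column is added with a consistency
    flag, since published energy tables are not always self-consistent.
    """
    ids = [r.enzyme for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate enzyme ids")
    by_id = {r.enzyme: r for r in records}
    if wt_id not in by_id:
        raise KeyError(f"wild-type id {wt_id!r} not present")
    wt = by_id[wt_id]

    rows = []
    for r in records:
        ddg_re = r.dG_stability - wt.dG_stability
        consistent = (
            None
            if r.ddG_vs_wt is None
            else bool(abs(r.ddG_vs_wt - ddg_re) <= tol)
        )
        rows.append(
            {
                "enzyme": r.enzyme,
                "Tm_C": r.Tm,
                "dTm_C": r.Tm - wt.Tm,
                "dG_J": r.dG_stability,
                "ddG_stored_J": r.ddG_vs_wt,
                "ddG_recomputed_J": ddg_re,
                "ddG_consistent": consistent,
            }
        )
    return pd.DataFrame(rows)


def degradation_percent(peak_area_treated: float, peak_area_control: float) -> float:
    """Substrate degradation percent from HPLC peak areas, clamped to [0, 100]."""
    if peak_area_control <= 0:
        raise ValueError("control peak area must be positive")
    if peak_area_treated < 0:
        raise ValueError("treated peak area must be non-negative")
    pct = (1.0 - peak_area_treated / peak_area_control) * 100.0
    if peak_area_treated > peak_area_control:
        warnings.warn(
            "treated peak area exceeds control; degradation clamped to 0%",
            stacklevel=2,
        )
    return float(np.clip(pct, 0.0, 100.0))
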