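"""Dissolution–supersaturation–precipitation analytics.

Covers the mole/mass/concentration bookkeeping of a powder dissolution
study of a cocrystal (dose composition, unit conversions, equivalents),
supersaturation ratios against the crystalline API's equilibrium
solubility, the coformer:API congruency ratio that diagnoses whether the
cocrystal dissolves stoichiometrically, percent dissolved from the
coformer ledger, and a Welch t comparison of solubility summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


def ng_ml_to_uM(c: float, mw: float) -> float:
    """Convert ng/mL to μM.  ng/mL ÷ g/mol = μM exactly (unit algebra)."""
    if mw <= 0:
        raise ValueError("molar mass must be positive")
    return c / mw


def uM_to_ng_ml(c: float, mw: float) -> float:
    """Convert μM to ng/mL (inverse of :func:`ng_ml_to_uM`)."""
    if mw <= 0:
        raise ValueError("molar mass must be positive")
    return c * mw


def mass_to_mmol(mass_mg: float, mw: float) -> float:
    """mg ÷ (g/mol) = mmol."""
    if mw <= 0:
        raise ValueError("molar mass must be positive")
    return mass_mg / mw


def mmol_to_mass(mmol: float, mw: float) -> float:
    """mmol × (g/mol) = mg."""
    if mw <= 0:
        raise ValueError("molar mass must be positive")
    return mmol * mw


def equivalents(n_a: float, n_b: float) -> float:
    """Molar equivalents of component a relative to component b."""
    if n_b <= 0:
        raise ValueError("reference mole amount must be positive")
    return n_a / n_b


@dataclass(frozen=True)
class CocrystalDose:
    """A weighed cocrystal powder dose.

    ``stoichiometry`` is the coformer:API molar ratio of the crystal
    (1.0 for a 1:1 cocrystal).
    """

    total_mass: float  # mg
    mw_api: float  # g/mol
    mw_coformer: float  # g/mol
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if self.total_mass <= 0:
            raise ValueError("dose mass must be positive")
        if self.mw_api <= 0 or self.mw_coformer <= 0:
            raise ValueError("molar masses must be positive")
        if self.stoichiometry < 0:
            raise ValueError("stoichiometry must be >= 0")


class DoseComposition(NamedTuple):
    mmol_cocrystal: float
    mg_api: float
    mg_coformer: float


def dose_composition(d: CocrystalDose) -> DoseComposition:
    """Split a cocrystal dose into moles of formula units and component
    masses.

    One formula unit contains one API molecule and ``stoichiometry``
    coformer molecules, so its molar mass is
    ``mw_api + stoichiometry * mw_coformer``; the component masses sum to
    the dose mass exactly.
    """
    mw_unit = d.mw_api + d.stoichiometry * d.mw_coformer
    mmol = d.total_mass / mw_unit
    mg_api = mmol * d.mw_api
    mg_cof = mmol * d.stoichiometry * d.mw_coformer
    return DoseComposition(mmol, mg_api, mg_cof)


@dataclass(frozen=True)
class DissolutionProfile:
    """Time series of API and coformer molar concentrations in a medium."""

    times: np.ndarray  # minutes
    conc_api: np.ndarray  # μM
    conc_coformer: np.ndarray  # μM
    medium: str = ""
    volume: float | None = None  # mL
    dose: CocrystalDose | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        ca = np.asarray(self.conc_api, dtype=float)
        cc = np.asarray(self.conc_coformer, dtype=float)
        if not (len(t) == len(ca) == len(cc)):
            raise ValueError("time and concentration series must be equal length")
        if len(t) == 0:
            raise ValueError("profile must contain at least one timepoint")
        if np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if not (np.all(np.isfinite(ca)) and np.all(np.isfinite(cc))):
            raise ValueError("concentrations must be finite")
        if np.any(ca < 0) or np.any(cc < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc_api", ca)
        object.__setattr__(self, "conc_coformer", cc)

    @classmethod
    def from_csv(
        cls,
        path,
        medium: str = "",
        volume: float | None = None,
        dose: CocrystalDose | None = None,
    ) -> "DissolutionProfile":
        """Read a ``time_min,conc_api_uM,conc_coformer_uM`` CSV.

        Rows are sorted by time before validation, so files written in
        any order canonicalise identically.
        """
        df = pd.read_csv(path)
        required = {"time_min", "conc_api_uM", "conc_coformer_uM"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
        df = df.sort_values("time_min")
        return cls(
            times=df["time_min"].to_numpy(),
            conc_api=df["conc_api_uM"].to_numpy(),
            conc_coformer=df["conc_coformer_uM"].to_numpy(),
            medium=medium,
            volume=volume,
            dose=dose,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_min": self.times,
                "conc_api_uM": self.conc_api,
                "conc_coformer_uM": self.conc_coformer,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SolubilitySummary:
    """Equilibrium solubility as mean ± SD over n replicates (μM)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")
        if self.n < 2:
            raise ValueError("at least two replicates required")


def supersaturation_ratio(c, s: SolubilitySummary | float):
    """Supersaturation ratio c / S of a concentration (or series) against
    the crystalline API's equilibrium solubility in the same medium."""
    s_mean = s.mean if isinstance(s, SolubilitySummary) else float(s)
    if s_mean <= 0:
        raise ValueError("solubility must be positive")
    return np.asarray(c, dtype=float) / s_mean if np.ndim(c) else float(c) / s_mean


class SupersaturationProfile(NamedTuple):
    times: np.ndarray
    ratio: np.ndarray
    max_ratio: float
    time_of_max: float


def supersaturation_profile(
    p: DissolutionProfile, s: SolubilitySummary | float
) -> SupersaturationProfile:
    """Per-timepoint API supersaturation series plus its maximum and the
    time at which the maximum occurs (first occurrence on ties)."""
    ratio = supersaturation_ratio(p.conc_api, s)
    i = int(np.argmax(ratio))
    return SupersaturationProfile(p.times, ratio, float(ratio[i]), float(p.times[i]))


class CongruencySeries(NamedTuple):
    times: np.ndarray
    ratio: np.ndarray  # NaN where undefined
    defined: np.ndarray  # boolean mask


def congruency_ratio(p: DissolutionProfile) -> CongruencySeries:
    """Coformer:API molar concentration ratio per timepoint.

    Congruent dissolution of a cocrystal yields a ratio equal to its
    stoichiometry (1.0 for 1:1) at every point.  Points where the API
    concentration is zero are flagged undefined (NaN), not dropped.
    """
    defined = p.conc_api > 0
    ratio = np.full_like(p.conc_api, np.nan)
    ratio[defined] = p.conc_coformer[defined] / p.conc_api[defined]
    return CongruencySeries(p.times, ratio, defined)


def percent_dissolved(p: DissolutionProfile, basis: str = "coformer") -> np.ndarray:
    """Percent of the cocrystal dose dissolved, per timepoint.

    Computed from the coformer by default (the coformer does not
    precipitate, so its solution concentration tracks cumulative
    cocrystal dissolution); ``basis="api"`` is a cross-check that only
    agrees under congruent conditions.  Values above 100% are reported
    with a warning, never silently clamped.
    """
    if p.volume is None or p.dose is None:
        raise ValueError("profile needs a dose and a volume for percent dissolved")
    comp = dose_composition(p.dose)
    if basis == "coformer":
        if comp.mg_coformer <= 0:
            raise ValueError("dose contains no coformer")
        # μM · mL = nmol; nmol × (g/mol) = ng; ng / 1e6 = mg
        mg_in_solution = p.conc_coformer * p.volume * p.dose.mw_coformer / 1e6
        pct = 100.0 * mg_in_solution / comp.mg_coformer
    elif basis == "api":
        mg_in_solution = p.conc_api * p.volume * p.dose.mw_api / 1e6
        pct = 100.0 * mg_in_solution / comp.mg_api
    else:
        raise ValueError(f"unknown basis {basis!r}")
    if np.any(pct > 100.0 + 1e-9):
        warnings.warn(
            f"percent dissolved exceeds 100% (max {pct.max():.1f}%): check "
            "dose, volume or calibration",
            stacklevel=2,
        )
    return pct


class WelchResult(NamedTuple):
    t: float
    df: float
    p_value: float


def compare_solubilities(a: SolubilitySummary, b: SolubilitySummary) -> WelchResult:
    """Two-sided Welch (unequal-variance) t test from summary statistics.

    Chosen over pooled Student's t because triplicate solubility
    measurements carry no evidence of equal variances.
    """
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        # degenerate: identical constants; no evidence of a difference
        return WelchResult(0.0, float(a.n + b.n - 2), 1.0)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return WelchResult(float(t), float(df), float(p))


def analytics_table(
    p: DissolutionProfile, s: SolubilitySummary | float
) -> pd.DataFrame:
    """Combined per-timepoint analytics: supersaturation, congruency and
    percent dissolved (when dose/volume are known)."""
    ss = supersaturation_profile(p, s)
    cong = congruency_ratio(p)
    df = pd.DataFrame(
        {
            "time_min": p.times,
            "conc_api_uM": p.conc_api,
            "conc_coformer_uM": p.conc_coformer,
            "supersaturation": ss.ratio,
            "congruency_coformer_to_api": cong.ratio,
        }
    )
    if p.volume is not None and p.dose is not None:
        df["percent_dissolved"] = percent_dissolved(p)
    return df
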