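"""Fixture molecules and a seeded dissolution simulator.

The fixture library ships the API (cilnidipine), the discovered coformer
(p-toluenesulfonamide), the screening controls and amino-acid leads, plus
generic filler coformers, so every pipeline stage can run without
external data.

The dissolution–supersaturation–precipitation (DSP) simulator is a
deliberately minimal kinetic model: cube-root (surface-area-limited)
dissolution of the cocrystal powder releasing API and coformer in their
stoichiometric ratio, with a first-order precipitation sink on the API
that switches on permanently once the API concentration first exceeds a
critical supersaturation concentration.  The coformer never precipitates.
It exists to generate profiles with known ground truth for the analytics
module, not to fit any measured dissolution curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from cocryscreen.complementarity import CutoffSet, DEFAULT_CUTOFFS
from cocryscreen.descriptors import DescriptorVector
from cocryscreen.dissolution import CocrystalDose, DissolutionProfile
from cocryscreen.molecules import Molecule, read_smiles_file

# Reference molar masses (g/mol) used in dose arithmetic.
MW_CILNIDIPINE = 492.5
MW_TSA = 171.2


def fixture_library() -> dict[str, Molecule]:
    """Load the shipped fixture library as {name: Molecule}."""
    path = resources.files("cocryscreen.data") / "coformers.smi"
    with resources.as_file(path) as p:
        mols = read_smiles_file(p)
    return {m.name: m for m in mols}


@dataclass(frozen=True)
class DspParams:
    """Parameters of the DSP simulator.

    Attributes
    ----------
    s_api:
        Crystalline API equilibrium solubility in the medium, μM.
    c_crit:
        Critical supersaturation concentration (μM): once the API
        concentration first exceeds it, bulk precipitation starts and
        stays on.
    k_d:
        Dissolution rate constant of the cube-root law
        dM/dt = -k_d M^(2/3), in mg^(1/3)/min.
    k_p:
        First-order precipitation rate constant, 1/min, acting on the
        excess (C_api - s_api)+.
    dose, volume:
        Cocrystal dose and medium volume (mL).
    dt, t_end:
        Integration step and horizon, minutes.
    sample_dt:
        Spacing of the reported profile timepoints (defaults to dt).
    noise_sd:
        SD of additive Gaussian noise (μM) applied to the sampled
        concentrations (truncated at 0); emulates assay scatter.
    seed:
        Seed for the noise generator.
    """

    s_api: float
    c_crit: float
    k_d: float
    k_p: float
    dose: CocrystalDose
    volume: float
    dt: float = 0.01
    t_end: float = 480.0
    sample_dt: float | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_api <= 0:
            raise ValueError("s_api must be positive")
        if self.c_crit < self.s_api:
            raise ValueError("c_crit must be >= s_api")
        if self.k_d < 0 or self.k_p < 0:
            raise ValueError("rate constants must be >= 0")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.k_p * self.dt > 0.5:
            raise ValueError(
                "k_p * dt too large for a stable explicit step; reduce dt"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class DspResult(NamedTuple):
    profile: DissolutionProfile
    ledger: pd.DataFrame


def simulate_dsp(p: DspParams, medium: str = "synthetic") -> DspResult:
    """Integrate the DSP model and return the sampled profile plus a
    per-step ground-truth ledger.

    The ledger tracks undissolved cocrystal, dissolved and precipitated
    API, and dissolved coformer in μmol of formula units, so mass
    conservation (undissolved + in solution + precipitated = dose) can be
    audited at every step.  The ledger is always noise-free; noise only
    affects the sampled profile.
    """
    d = p.dose
    stoich = d.stoichiometry
    mw_unit = d.mw_api + stoich * d.mw_coformer
    v_l = p.volume / 1000.0
    n_steps = int(round(p.t_end / p.dt))

    mass = d.total_mass  # mg undissolved cocrystal
    n0 = d.total_mass / mw_unit * 1000.0  # μmol formula units in the dose
    n_api = 0.0  # μmol API in solution
    n_ppt = 0.0  # μmol API precipitated
    n_cof = 0.0  # μmol coformer in solution
    precip_on = False

    cols = {
        name: np.empty(n_steps + 1)
        for name in (
            "time_min",
            "undissolved_mg",
            "api_solution_umol",
            "api_precipitated_umol",
            "coformer_solution_umol",
            "conc_api_uM",
            "conc_coformer_uM",
        )
    }
    active = np.empty(n_steps + 1, dtype=bool)

    def record(i: int, t: float) -> None:
        cols["time_min"][i] = t
        cols["undissolved_mg"][i] = mass
        cols["api_solution_umol"][i] = n_api
        cols["api_precipitated_umol"][i] = n_ppt
        cols["coformer_solution_umol"][i] = n_cof
        cols["conc_api_uM"][i] = n_api / v_l
        cols["conc_coformer_uM"][i] = n_cof / v_l
        active[i] = precip_on

    record(0, 0.0)
    for i in range(1, n_steps + 1):
        diss_mg = min(mass, p.k_d * mass ** (2.0 / 3.0) * p.dt)
        mass -= diss_mg
        dn = diss_mg / mw_unit * 1000.0
        n_api += dn
        n_cof += stoich * dn
        if not precip_on and n_api / v_l > p.c_crit:
            precip_on = True
        if precip_on:
            dppt = min(n_api, p.k_p * max(n_api / v_l - p.s_api, 0.0) * v_l * p.dt)
            n_api -= dppt
            n_ppt += dppt
        record(i, i * p.dt)

    ledger = pd.DataFrame(cols)
    ledger["precipitation_active"] = active
    ledger["undissolved_umol"] = ledger["undissolved_mg"] / mw_unit * 1000.0
    ledger.attrs["dose_umol"] = n0
    ledger.attrs["percent_dissolved_final"] = 100.0 * (n0 - ledger["undissolved_umol"].iloc[-1]) / n0
    ledger.attrs["max_supersaturation"] = float(
        ledger["conc_api_uM"].max() / p.s_api
    )
    ledger.attrs["time_of_max_supersaturation"] = float(
        ledger.loc[ledger["conc_api_uM"].idxmax(), "time_min"]
    )

    sample_dt = p.sample_dt if p.sample_dt is not None else p.dt
    stride = max(1, int(round(sample_dt / p.dt)))
    idx = np.arange(stride, n_steps + 1, stride)
    times = cols["time_min"][idx]
    conc_api = cols["conc_api_uM"][idx].copy()
    conc_cof = cols["conc_coformer_uM"][idx].copy()
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        conc_api = np.clip(conc_api + rng.normal(0, p.noise_sd, len(idx)), 0, None)
        conc_cof = np.clip(conc_cof + rng.normal(0, p.noise_sd, len(idx)), 0, None)
    profile = DissolutionProfile(
        times=times,
        conc_api=conc_api,
        conc_coformer=conc_cof,
        medium=medium,
        volume=p.volume,
        dose=d,
    )
    return DspResult(profile, ledger)


#: Descriptor vector of a mid-size, flexible, moderately polar reference
#: API used by the synthetic screening-set generator.
REFERENCE_API_VECTOR = DescriptorVector(
    S=6.5, M_over_L=0.62, S_over_L=0.42, dipole=6.0, FNO=0.25
)


class ScreeningSet(NamedTuple):
    api: DescriptorVector
    coformers: dict[str, list[DescriptorVector]]
    labels: dict[str, str]  # name -> "similar" | "dissimilar"


def make_screening_set(
    seed: int,
    n_similar: int,
    n_dissimilar: int,
    api: DescriptorVector = REFERENCE_API_VECTOR,
    cut: CutoffSet = DEFAULT_CUTOFFS,
) -> ScreeningSet:
    """Generate a labelled synthetic descriptor library around an API.

    "similar" coformers sit within 0.2·δ_D of the API in every
    descriptor (complementarity score <= 1 by construction, and PASS
    under the default rule); "dissimilar" ones are displaced by at least
    2·δ_D in the S axis or the dipole (score >= 2, guaranteed FAIL).
    The construction therefore guarantees that every similar coformer
    outranks every dissimilar one.
    """
    if n_similar < 0 or n_dissimilar < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    d_ml, d_s, d_sl, d_dip, d_fno = cut.as_array()
    coformers: dict[str, list[DescriptorVector]] = {}
    labels: dict[str, str] = {}

    for i in range(n_similar):
        u = rng.uniform(-0.2, 0.2, size=5)
        vec = DescriptorVector(
            S=api.S + u[1] * d_s,
            M_over_L=api.M_over_L + u[0] * d_ml,
            S_over_L=api.S_over_L + u[2] * d_sl,
            dipole=max(0.0, api.dipole + u[3] * d_dip),
            FNO=float(np.clip(api.FNO + u[4] * d_fno, 0, 1)),
        )
        name = f"similar_{i:03d}"
        coformers[name] = [vec]
        labels[name] = "similar"

    for i in range(n_dissimilar):
        big = rng.uniform(2.0, 3.0)
        which = rng.integers(0, 2)  # displace S or dipole, both stay valid
        s = api.S + (big * d_s if which == 0 else rng.uniform(-0.5, 0.5) * d_s)
        dip = api.dipole + (
            big * d_dip if which == 1 else rng.uniform(-0.5, 0.5) * d_dip
        )
        ml = api.M_over_L + rng.uniform(-0.5, 0.5) * d_ml
        sl = min(api.S_over_L + rng.uniform(-0.4, 0.4) * d_sl, ml)
        vec = DescriptorVector(
            S=s,
            M_over_L=ml,
            S_over_L=sl,
            dipole=max(0.0, dip),
            FNO=float(np.clip(api.FNO + rng.uniform(-0.5, 0.5) * d_fno, 0, 1)),
        )
        name = f"dissimilar_{i:03d}"
        coformers[name] = [vec]
        labels[name] = "dissimilar"

    return ScreeningSet(api=api, coformers=coformers, labels=labels)


def _reference_dose() -> CocrystalDose:
    # 10.8 mg of 1:1 cocrystal in 80 mL, the dose/volume geometry of a
    # small-beaker powder dissolution study.
    return CocrystalDose(
        total_mass=10.8,
        mw_api=MW_CILNIDIPINE,
        mw_coformer=MW_TSA,
        stoichiometry=1.0,
    )


def fig5_style_profiles(seed: int = 0) -> dict[str, DissolutionProfile]:
    """Two regime profiles emulating the narrated dissolution behaviours.

    ``"blank"``: precipitation engages almost immediately (low critical
    concentration, fast sink) so the bulk API is pinned near the
    crystalline solubility while the coformer keeps accumulating — the
    coformer:API ratio exceeds 100 within minutes, an early-incongruent
    regime.  ``"fassif"``: a much higher critical concentration lets the
    cocrystal dissolve congruently (ratio = 1) for roughly three hours
    before bulk precipitation caps the API near four times its
    solubility.  Both are noise-free so analytic checks against the
    ledger are exact; both record the seed used.
    """
    dose = _reference_dose()
    blank = simulate_dsp(
        DspParams(
            s_api=0.046,
            c_crit=0.05,
            k_d=0.015,
            k_p=150.0,
            dose=dose,
            volume=80.0,
            dt=0.001,
            t_end=480.0,
            sample_dt=2.5,
            noise_sd=0.0,
            seed=seed,
        ),
        medium="blank-regime",
    ).profile
    fassif = simulate_dsp(
        DspParams(
            s_api=25.0,
            c_crit=100.0,
            k_d=0.0076,
            k_p=0.05,
            dose=dose,
            volume=80.0,
            dt=0.1,
            t_end=480.0,
            sample_dt=5.0,
            noise_sd=0.0,
            seed=seed,
        ),
        medium="fassif-regime",
    ).profile
    return {"blank": blank, "fassif": fassif}
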