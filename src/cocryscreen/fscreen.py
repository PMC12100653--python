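"""COSMOquick-style screening-function ranking.

The screening function combines the excess (mixing) enthalpy of the
supercooled 1:1 API–coformer liquid with a flexibility penalty on
rotatable bonds:

    F_screen = ΔH_mix + a · (max(1, n_drug) + max(1, n_coformer))

ΔH_mix approximates the free energy of cocrystal formation (the entropy
of mixing and the fusion term are neglected in this approach); ``a`` is a
fit parameter to be calibrated on experimental outcomes.  Lower F_screen
means a more promising coformer.  ΔH_mix values are consumed as input
(they come from σ-profile thermodynamics engines); this module only
combines and ranks them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MixRecord:
    """One coformer's mixing enthalpy (kcal/mol, supercooled 1:1 mix)
    and rotatable-bond count."""

    name: str
    dH_mix: float
    n_coformer: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.dH_mix):
            raise ValueError(f"dH_mix must be finite for {self.name!r}")
        if self.n_coformer < 0:
            raise ValueError(f"rotatable-bond count must be >= 0 for {self.name!r}")


@dataclass(frozen=True)
class FscreenParams:
    """Flexibility-penalty weight ``a`` (kcal/mol per rotatable-bond
    unit) and the API's rotatable-bond count."""

    n_drug: int
    a: float | None = None

    def __post_init__(self) -> None:
        if self.n_drug < 0:
            raise ValueError("n_drug must be >= 0")
        if self.a is None:
            warnings.warn(
                "no flexibility-penalty weight 'a' given; using a = 0 "
                "(F_screen reduces to dH_mix). 'a' is a fit parameter to "
                "be determined on a set of experimental results.",
                stacklevel=2,
            )
            object.__setattr__(self, "a", 0.0)

    @property
    def weight(self) -> float:
        return float(self.a)


def f_screen(rec: MixRecord, p: FscreenParams) -> float:
    """Evaluate the screening function for one coformer (kcal/mol).

    Both rotatable-bond counts are floored at 1, so perfectly rigid
    molecules still pay one penalty unit each.
    """
    return rec.dH_mix + p.weight * (max(1, p.n_drug) + max(1, rec.n_coformer))


def rank_fscreen(records: Sequence[MixRecord], p: FscreenParams) -> pd.DataFrame:
    """Rank coformers by ascending F_screen.

    Ties are broken lexicographically by name; ranks are 1..N.

    Raises
    ------
    ValueError
        On an empty record list or duplicate coformer names.
    """
    if not records:
        raise ValueError("no mix records to rank")
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate coformer names: {dupes}")
    df = pd.DataFrame(
        {
            "name": names,
            "dH_mix_kcal_mol": [r.dH_mix for r in records],
            "n_rotatable": [r.n_coformer for r in records],
            "f_screen": [f_screen(r, p) for r in records],
        }
    )
    df = df.sort_values(["f_screen", "name"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def read_mix_csv(path) -> list[MixRecord]:
    """Read a ``name,dH_mix_kcal_mol,n_rotatable`` CSV of mixing
    enthalpies."""
    df = pd.read_csv(path)
    required = {"name", "dH_mix_kcal_mol", "n_rotatable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mix CSV missing columns: {sorted(missing)}")
    return [
        MixRecord(
            name=str(row["name"]),
            dH_mix=float(row["dH_mix_kcal_mol"]),
            n_coformer=int(row["n_rotatable"]),
        )
        for _, row in df.iterrows()
    ]
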