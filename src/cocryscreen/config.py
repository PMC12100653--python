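"""Run configuration shared across the screening pipeline.

All switches that change numerical output are collected here so a run can
be reproduced from its manifest: the embedding seed, the box orientation
rule, the partial-charge model, the vdW radii table, the FNO atom universe
and the hit-rate averaging mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import yaml

#: Bondi (1964) van der Waals radii in Å for the elements that occur in
#: typical API/coformer chemistry.  Overridable per run.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}


@dataclass
class RunConfig:
    """Pipeline configuration with reproducibility-relevant switches.

    Parameters
    ----------
    seed:
        Random seed used for conformer embedding and any synthetic data.
    box_orientation:
        ``"principal"`` orients the vdW bounding box along the principal
        axes of the atomic coordinates (deterministic, default);
        ``"minvol"`` searches rotations for the minimal-volume box.
    charge_model:
        Partial-charge model for the dipole descriptor.  Only the
        empirical Gasteiger model is implemented; the field is recorded in
        output manifests because complementarity scores are only
        comparable within one charge model.
    fno_universe:
        Atom universe for the N+O fraction: ``"heavy"`` (default, makes
        FNO independent of hydrogen handling) or ``"all"``.
    hit_rate_mode:
        ``"pairs"``: hit rate is the percentage of (API conformer,
        coformer conformer) pairs passing all cutoffs.  ``"any"``: an API
        conformation counts as a hit when any coformer conformation
        passes; the rate is averaged over API conformations.
    neutralize_zwitterions:
        Process zwitterionizable molecules (amino acids) as the neutral
        tautomer; the dipole of a net-charged species is origin-dependent.
    vdw_radii:
        Per-element vdW radii in Å; defaults to Bondi values.
    """

    seed: int = 2025
    box_orientation: Literal["principal", "minvol"] = "principal"
    charge_model: Literal["gasteiger"] = "gasteiger"
    fno_universe: Literal["heavy", "all"] = "heavy"
    hit_rate_mode: Literal["pairs", "any"] = "pairs"
    neutralize_zwitterions: bool = True
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if self.box_orientation not in ("principal", "minvol"):
            raise ValueError(f"unknown box_orientation {self.box_orientation!r}")
        if self.charge_model != "gasteiger":
            raise ValueError(f"unknown charge_model {self.charge_model!r}")
        if self.fno_universe not in ("heavy", "all"):
            raise ValueError(f"unknown fno_universe {self.fno_universe!r}")
        if self.hit_rate_mode not in ("pairs", "any"):
            raise ValueError(f"unknown hit_rate_mode {self.hit_rate_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        radii = dict(BONDI_RADII)
        radii.update(data.pop("vdw_radii", {}))
        return cls(vdw_radii=radii, **data)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = RunConfig()
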