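"""Molecular-complementarity scoring and coformer ranking.

For an API/coformer pair the complementarity score is the sum over the
five descriptors D of |X_D,API - X_D,cof| / δ_D, where the cutoffs δ_D
come from a statistical survey of known cocrystals (90% of surveyed
cocrystals differ by less than δ_D in each descriptor):

    C_score = |ΔM/L|/0.31 + |ΔS|/3.23 + |ΔS/L|/0.28
              + |Δdipole|/5.94 + |ΔFNO|/0.29

Lower scores mean more similar molecules and a better cocrystallization
prospect.  Scores are averaged over all (API conformer, coformer
conformer) pairs.  The alternative "default settings" rule predicts
cocrystal formation iff every |Δ_D| is within its cutoff; the hit rate is
the percentage of conformer pairs passing that test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cocryscreen.config import RunConfig, DEFAULT_CONFIG
from cocryscreen.descriptors import DescriptorVector, ensemble_descriptors
from cocryscreen.molecules import ConformerEnsemble


@dataclass(frozen=True)
class CutoffSet:
    """Descriptor cutoffs δ_D (Å for S, Debye for the dipole)."""

    delta_M_over_L: float = 0.31
    delta_S: float = 3.23
    delta_S_over_L: float = 0.28
    delta_dipole: float = 5.94
    delta_FNO: float = 0.29

    def __post_init__(self) -> None:
        if not np.all(self.as_array() > 0):
            raise ValueError("all cutoffs must be strictly positive")

    def as_array(self) -> np.ndarray:
        """Same canonical order as DescriptorVector.as_array()."""
        return np.array(
            [
                self.delta_M_over_L,
                self.delta_S,
                self.delta_S_over_L,
                self.delta_dipole,
                self.delta_FNO,
            ]
        )


DEFAULT_CUTOFFS = CutoffSet()


def c_score(
    a: DescriptorVector, b: DescriptorVector, cut: CutoffSet = DEFAULT_CUTOFFS
) -> float:
    """Cutoff-normalised complementarity score of one descriptor pair.

    Non-negative and symmetric; zero iff the vectors coincide.
    """
    return float(np.sum(np.abs(a.as_array() - b.as_array()) / cut.as_array()))


# Relative slack on the inclusive cutoff boundary so a difference equal
# to δ_D up to float rounding still counts as a pass.
_BOUNDARY_RTOL = 1e-9


def pass_default(
    a: DescriptorVector, b: DescriptorVector, cut: CutoffSet = DEFAULT_CUTOFFS
) -> bool:
    """Default-settings PASS/FAIL rule: PASS iff |Δ_D| <= δ_D for all
    five descriptors (the boundary counts as a pass)."""
    norm = np.abs(a.as_array() - b.as_array()) / cut.as_array()
    return bool(np.all(norm <= 1.0 + _BOUNDARY_RTOL))


def _pair_matrix(
    api: Sequence[DescriptorVector],
    cof: Sequence[DescriptorVector],
    cut: CutoffSet,
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, passes) over the Cartesian product of conformer pairs."""
    if len(api) == 0 or len(cof) == 0:
        raise ValueError("descriptor lists must be nonempty")
    A = np.stack([v.as_array() for v in api])[:, None, :]
    B = np.stack([v.as_array() for v in cof])[None, :, :]
    norm = np.abs(A - B) / cut.as_array()
    scores = norm.sum(axis=2)
    passes = np.all(norm <= 1.0 + _BOUNDARY_RTOL, axis=2)
    return scores, passes


def mean_c_score(
    api: Sequence[DescriptorVector],
    cof: Sequence[DescriptorVector],
    cut: CutoffSet = DEFAULT_CUTOFFS,
) -> float:
    """Arithmetic mean of c_score over all (API conformer, coformer
    conformer) pairs."""
    scores, _ = _pair_matrix(api, cof, cut)
    return float(scores.mean())


def hit_rate(
    api: Sequence[DescriptorVector],
    cof: Sequence[DescriptorVector],
    cut: CutoffSet = DEFAULT_CUTOFFS,
    mode: str = "pairs",
) -> float:
    """Percentage hit rate of the default-settings test.

    ``mode="pairs"``: 100 × (passing conformer pairs) / (total pairs).
    ``mode="any"``: an API conformation is a hit when any coformer
    conformation passes with it; the rate is averaged over API
    conformations.
    """
    _, passes = _pair_matrix(api, cof, cut)
    if mode == "pairs":
        return float(100.0 * passes.mean())
    if mode == "any":
        return float(100.0 * passes.any(axis=1).mean())
    raise ValueError(f"unknown hit-rate mode {mode!r}")


@dataclass(frozen=True)
class CoformerResult:
    """Screening outcome for one coformer against the API ensemble."""

    name: str
    mean_c_score: float
    pair_scores: np.ndarray = field(repr=False)
    hit_rate: float
    pass_default: bool
    rank: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.mean_c_score, self.pair_scores.mean()):
            raise ValueError("mean_c_score must equal the mean of pair_scores")
        if not (0.0 <= self.hit_rate <= 100.0):
            raise ValueError("hit rate must lie in [0, 100]")
        if self.pass_default != (self.hit_rate > 0):
            raise ValueError("pass_default must equal (hit_rate > 0)")


@dataclass(frozen=True)
class RankingTable:
    """Coformers ordered by ascending mean complementarity score."""

    results: tuple[CoformerResult, ...]
    metadata: dict = field(default_factory=dict)
    failures: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        scores = [r.mean_c_score for r in self.results]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError("results must be sorted ascending by mean_c_score")
        if [r.rank for r in self.results] != list(range(1, len(self.results) + 1)):
            raise ValueError("ranks must be 1..N without gaps")

    def __len__(self) -> int:
        return len(self.results)

    def rank_of(self, name: str) -> int:
        for r in self.results:
            if r.name == name:
                return r.rank
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [r.rank for r in self.results],
                "name": [r.name for r in self.results],
                "mean_c_score": [r.mean_c_score for r in self.results],
                "hit_rate": [r.hit_rate for r in self.results],
                "pass_default": [r.pass_default for r in self.results],
            }
        )


def rank_descriptor_sets(
    api: Sequence[DescriptorVector],
    coformers: dict[str, Sequence[DescriptorVector]],
    cut: CutoffSet = DEFAULT_CUTOFFS,
    hit_rate_mode: str = "pairs",
    metadata: dict | None = None,
    failures: Sequence[tuple[str, str]] = (),
) -> RankingTable:
    """Rank coformers given precomputed descriptor vectors.

    Sorting is ascending in mean score (lower = more promising); ties are
    broken lexicographically by coformer name.
    """
    rows = []
    for name, vecs in coformers.items():
        scores, passes = _pair_matrix(api, list(vecs), cut)
        hr = hit_rate(api, list(vecs), cut, mode=hit_rate_mode)
        rows.append((float(scores.mean()), name, scores, hr))
    rows.sort(key=lambda r: (r[0], r[1]))
    results = tuple(
        CoformerResult(
            name=name,
            mean_c_score=score,
            pair_scores=scores,
            hit_rate=hr,
            pass_default=hr > 0,
            rank=i + 1,
        )
        for i, (score, name, scores, hr) in enumerate(rows)
    )
    meta = dict(metadata or {})
    meta.setdefault("cutoffs", cut.as_array().tolist())
    meta.setdefault("hit_rate_mode", hit_rate_mode)
    meta.setdefault("tie_break", "lexicographic by name")
    return RankingTable(results=results, metadata=meta, failures=tuple(failures))


def screen_mc(
    api: ConformerEnsemble,
    coformers: Sequence[ConformerEnsemble],
    cut: CutoffSet = DEFAULT_CUTOFFS,
    config: RunConfig | None = None,
) -> RankingTable:
    """Full complementarity screen of an API ensemble against a coformer
    library.

    A coformer whose descriptors cannot be computed is reported in
    ``RankingTable.failures`` and excluded from the ranking rather than
    aborting the screen.
    """
    cfg = config or DEFAULT_CONFIG
    api_vecs = ensemble_descriptors(api, cfg)
    library: dict[str, Sequence[DescriptorVector]] = {}
    failures: list[tuple[str, str]] = []
    for ens in coformers:
        name = ens.molecule.name or ens.molecule.smiles
        if name in library:
            raise ValueError(f"duplicate coformer name {name!r}")
        try:
            library[name] = ensemble_descriptors(ens, cfg)
        except Exception as exc:  # report-and-continue policy
            failures.append((name, str(exc)))
    metadata = {
        "seed": api.seed,
        "charge_model": cfg.charge_model,
        "box_orientation": cfg.box_orientation,
        "api": api.molecule.name or api.molecule.smiles,
        "n_api_conformers": len(api),
        "n_coformers": len(library),
    }
    return rank_descriptor_sets(
        api_vecs,
        library,
        cut,
        hit_rate_mode=cfg.hit_rate_mode,
        metadata=metadata,
        failures=failures,
    )
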