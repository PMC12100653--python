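"""The five shape/polarity complementarity descriptors.

Per conformer: the short (S), medium (M) and long (L) axes of a box
enclosing the molecular van der Waals volume — reported as S, M/L and S/L
— plus the dipole moment from empirical partial charges, and the
(conformation-independent) fraction of nitrogen and oxygen atoms (FNO).

Molecules that tend to cocrystallize tend to be similar in these five
numbers; the screening module turns descriptor differences into a score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cocryscreen.config import RunConfig, DEFAULT_CONFIG
from cocryscreen.molecules import Molecule, Conformer, ConformerEnsemble

#: 1 e·Å expressed in Debye.
EA_TO_DEBYE = 4.8032


@dataclass(frozen=True)
class BoxAxes:
    """Sorted axes (Å) of the vdW-enclosing box: S <= M <= L."""

    S: float
    M: float
    L: float

    def __post_init__(self) -> None:
        if not (0 < self.S <= self.M <= self.L):
            raise ValueError(f"box axes must satisfy 0 < S <= M <= L, got {self}")

    @property
    def volume(self) -> float:
        return self.S * self.M * self.L


@dataclass(frozen=True)
class DescriptorVector:
    """The five descriptors of one conformer.

    S is in Å, the dipole in Debye; M/L, S/L and FNO are dimensionless.
    """

    S: float
    M_over_L: float
    S_over_L: float
    dipole: float
    FNO: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError(f"descriptor vector must be finite: {self}")
        if self.S <= 0:
            raise ValueError("S axis must be positive")
        if not (0 < self.S_over_L <= self.M_over_L <= 1):
            raise ValueError("axis ratios must satisfy 0 < S/L <= M/L <= 1")
        if self.dipole < 0:
            raise ValueError("dipole magnitude cannot be negative")
        if not (0 <= self.FNO <= 1):
            raise ValueError("FNO must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        """Canonical order: (M/L, S, S/L, dipole, FNO)."""
        return np.array(
            [self.M_over_L, self.S, self.S_over_L, self.dipole, self.FNO]
        )


def _atom_radii(elements, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        try:
            out[i] = radii[el]
        except KeyError:
            raise KeyError(f"no van der Waals radius configured for element {el!r}")
    return out


def _extents(coords: np.ndarray, radii: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Box extents along the three (orthonormal) frame axes, vdW-enclosing."""
    proj = coords @ frame  # (n_atoms, 3)
    return (proj + radii[:, None]).max(axis=0) - (proj - radii[:, None]).min(axis=0)


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    _, vecs = np.linalg.eigh(cov)
    return vecs


def box_axes(
    c: Conformer,
    radii: dict[str, float] | None = None,
    orientation: str = "principal",
) -> BoxAxes:
    """Axes of a box enclosing the conformer's van der Waals volume.

    With ``orientation="principal"`` (default) the box is aligned with the
    principal axes of the unit-mass atomic coordinate covariance; along
    each axis the extent is ``max(projection + r) - min(projection - r)``
    over all atoms.  ``orientation="minvol"`` instead searches rotations
    for the minimal-volume enclosing box (slower, non-standard).

    Raises
    ------
    KeyError
        If an element has no configured vdW radius.
    """
    if radii is None:
        radii = DEFAULT_CONFIG.vdw_radii
    coords = c.coordinates - c.coordinates.mean(axis=0)
    r = _atom_radii(c.elements, radii)
    if orientation == "principal":
        ext = _extents(coords, r, _principal_frame(coords))
    elif orientation == "minvol":
        ext = _minvol_extents(coords, r)
    else:
        raise ValueError(f"unknown box orientation {orientation!r}")
    s, m, length = np.sort(ext)
    return BoxAxes(S=float(s), M=float(m), L=float(length))


def _minvol_extents(coords: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Minimal-volume box via local optimisation over rotations.

    Deterministic multi-start (principal frame plus a fixed set of
    rotations); adequate for small molecules, not a guaranteed global
    optimum.
    """

    def volume(angles: np.ndarray) -> float:
        frame = Rotation.from_euler("zyx", angles).as_matrix()
        return float(np.prod(_extents(coords, r, frame)))

    starts = [np.zeros(3)]
    p = _principal_frame(coords)
    if np.linalg.det(p) < 0:
        p = p @ np.diag([1.0, 1.0, -1.0])
    starts.append(Rotation.from_matrix(p.T).as_euler("zyx"))
    grid = np.deg2rad([0.0, 30.0, 60.0])
    starts.extend(np.array([a, b, 0.0]) for a in grid for b in grid)
    best = None
    for x0 in starts:
        res = minimize(volume, x0, method="Nelder-Mead", options={"xatol": 1e-4})
        if best is None or res.fun < best.fun:
            best = res
    frame = Rotation.from_euler("zyx", best.x).as_matrix()
    return _extents(coords, r, frame)


def gasteiger_charges(mol_h: Chem.Mol) -> np.ndarray:
    """Gasteiger–Marsili empirical partial charges (e) for an
    explicit-hydrogen molecule; charges depend only on the bond graph."""
    mol = Chem.Mol(mol_h)
    AllChem.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise ValueError("Gasteiger charges did not converge to finite values")
    return q


def _charges_for(c: Conformer) -> np.ndarray:
    # AddHs enumerates heavy atoms first then hydrogens, in the same order
    # used at embedding time, so topological charges line up with coords.
    molh = Chem.AddHs(Chem.Mol(c.parent.rdmol))
    if molh.GetNumAtoms() != len(c.elements):
        raise ValueError("conformer atom count does not match its parent molecule")
    return gasteiger_charges(molh)


def dipole_moment(c: Conformer, charges: np.ndarray | None = None) -> float:
    """Dipole moment magnitude in Debye from point partial charges.

    ``|Σ q_i (r_i - r_com)| × 4.8032`` with the origin at the centre of
    mass.  For a net-neutral charge set the origin is immaterial; for a
    net-charged one the value is origin-dependent and a warning is issued.
    """
    if charges is None:
        charges = _charges_for(c)
    charges = np.asarray(charges, dtype=float)
    if charges.shape[0] != c.coordinates.shape[0]:
        raise ValueError("one charge per atom required")
    if abs(charges.sum()) > 1e-6:
        warnings.warn(
            f"net molecular charge {charges.sum():+.3f} e: dipole is "
            "origin-dependent; computed about the centre of mass",
            stacklevel=2,
        )
    pt = Chem.GetPeriodicTable()
    masses = np.array([pt.GetAtomicWeight(el) for el in c.elements])
    com = (masses[:, None] * c.coordinates).sum(axis=0) / masses.sum()
    mu = (charges[:, None] * (c.coordinates - com)).sum(axis=0)
    return float(np.linalg.norm(mu) * EA_TO_DEBYE)


def fno_fraction(m: Molecule, universe: str = "heavy") -> float:
    """Fraction of nitrogen plus oxygen atoms.

    By default counted over heavy (non-hydrogen) atoms, which makes the
    value independent of implicit/explicit hydrogen handling; set
    ``universe="all"`` to include hydrogens in the denominator.
    """
    heavy = m.rdmol.GetNumHeavyAtoms()
    n_no = sum(1 for a in m.rdmol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    if universe == "heavy":
        denom = heavy
    elif universe == "all":
        denom = heavy + sum(a.GetTotalNumHs() for a in m.rdmol.GetAtoms())
    else:
        raise ValueError(f"unknown FNO universe {universe!r}")
    return n_no / denom if denom else 0.0


def descriptor_vector(
    c: Conformer,
    charges: np.ndarray | None = None,
    config: RunConfig | None = None,
) -> DescriptorVector:
    """Assemble the five descriptors for one conformer."""
    cfg = config or DEFAULT_CONFIG
    axes = box_axes(c, cfg.vdw_radii, cfg.box_orientation)
    return DescriptorVector(
        S=axes.S,
        M_over_L=axes.M / axes.L,
        S_over_L=axes.S / axes.L,
        dipole=dipole_moment(c, charges),
        FNO=fno_fraction(c.parent, cfg.fno_universe),
    )


def ensemble_descriptors(
    ensemble: ConformerEnsemble, config: RunConfig | None = None
) -> list[DescriptorVector]:
    """Descriptor vectors for every conformer of an ensemble.

    Partial charges are computed once (they depend only on the bond
    graph) and reused across conformers.
    """
    cfg = config or DEFAULT_CONFIG
    charges = gasteiger_charges(ensemble.rdmol_h)
    return [descriptor_vector(c, charges, cfg) for c in ensemble.conformers]
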