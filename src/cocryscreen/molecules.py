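"""Molecule parsing, conformer embedding and basic molecular arithmetic.

Structures come in as SMILES strings or single V2000 SDF records.  3D
conformer ensembles are generated with seeded distance-geometry embedding
(ETKDGv3) followed by MMFF94 minimisation, which makes ensembles bitwise
repeatable for a fixed (molecule, count, seed) triple — a property the
downstream descriptor screening relies on for reproducible rankings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")


class StructureParseError(ValueError):
    """Raised when a SMILES string or SDF record cannot be parsed."""


class EmbeddingError(RuntimeError):
    """Raised when 3D embedding fails for a molecule after retries."""


@dataclass(frozen=True)
class Molecule:
    """A parsed molecular structure.

    Attributes
    ----------
    name:
        Text label (e.g. ``"p-toluenesulfonamide"``).
    smiles:
        Canonical SMILES as produced by RDKit.
    rdmol:
        The underlying RDKit molecule (heavy-atom graph; hydrogens are
        made explicit at embedding time).
    """

    name: str
    smiles: str
    rdmol: Chem.Mol = field(compare=False, repr=False)

    @property
    def atoms(self) -> list[tuple[str, int]]:
        """(element symbol, formal charge) per atom of the heavy-atom graph."""
        return [(a.GetSymbol(), a.GetFormalCharge()) for a in self.rdmol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float]]:
        """((begin index, end index), bond order) per bond."""
        return [
            ((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), b.GetBondTypeAsDouble())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def net_charge(self) -> int:
        return sum(a.GetFormalCharge() for a in self.rdmol.GetAtoms())


@dataclass(frozen=True)
class Conformer:
    """One 3D coordinate set (Å) for a molecule with explicit hydrogens."""

    coordinates: np.ndarray
    parent: Molecule
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if coords.shape[0] != len(self.elements):
            raise ValueError("one coordinate triple per atom required")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)


@dataclass(frozen=True)
class ConformerEnsemble:
    """A molecule with one or more embedded 3D conformers.

    ``rdmol_h`` carries the explicit-hydrogen RDKit molecule with all
    conformers attached, so downstream charge models can be evaluated on
    the very geometry the descriptors use.
    """

    molecule: Molecule
    conformers: tuple[Conformer, ...]
    seed: int
    rdmol_h: Chem.Mol = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.conformers) < 1:
            raise ValueError("ensemble must contain at least one conformer")

    def __len__(self) -> int:
        return len(self.conformers)


_SDF_MARKER = re.compile(r"^\s*M\s+END", re.MULTILINE)


def parse_structure(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string or a single V2000 SDF record.

    Parameters
    ----------
    text:
        SMILES, or the content of one SDF/MOL record (detected by the
        ``M  END`` line).
    name:
        Label attached to the molecule; for SDF records the title line is
        used when no name is given.

    Raises
    ------
    StructureParseError
        If the text is not valid SMILES / not a valid SDF record.  No
        partial molecule is returned.
    """
    if not text.strip():
        raise StructureParseError("empty structure record")
    # molblocks carry a (possibly blank) title line: trim the right only
    text = text.rstrip() if _SDF_MARKER.search(text) else text.strip()
    if _SDF_MARKER.search(text):
        mol = Chem.MolFromMolBlock(text, sanitize=True)
        if mol is None:
            raise StructureParseError(
                f"invalid SDF record{f' for {name!r}' if name else ''}: "
                f"{text.splitlines()[0][:60]!r}"
            )
        if not name:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    else:
        mol = Chem.MolFromSmiles(text)
        if mol is None:
            raise StructureParseError(
                f"invalid SMILES{f' for {name!r}' if name else ''}: {text!r}"
            )
    return Molecule(name=name, smiles=Chem.MolToSmiles(mol), rdmol=mol)


def read_smiles_file(path) -> list[Molecule]:
    """Read a ``name<TAB>smiles`` (or ``smiles<TAB>name``) list file.

    Lines starting with ``#`` and blank lines are skipped.  Column order
    is resolved per line by which field parses as SMILES.
    """
    molecules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            if len(parts) == 1:
                name, smi = "", parts[0]
            else:
                a, b = parts[0].strip(), parts[1].strip()
                if Chem.MolFromSmiles(b) is not None:
                    name, smi = a, b
                else:
                    name, smi = b, a
            try:
                molecules.append(parse_structure(smi, name=name))
            except StructureParseError as exc:
                raise StructureParseError(f"{path}:{lineno}: {exc}") from exc
    return molecules


def molar_mass(m: Molecule) -> float:
    """Molar mass in g/mol (standard atomic weights, hydrogens included)."""
    return Descriptors.MolWt(m.rdmol)


def count_rotatable_bonds(m: Molecule) -> int:
    """Number of rotatable bonds under the strict definition.

    A rotatable bond is a single, non-ring bond between two non-terminal
    heavy atoms, with amide C–N (and similarly locked linkages) excluded.
    """
    return rdMolDescriptors.CalcNumRotatableBonds(
        m.rdmol, rdMolDescriptors.NumRotatableBondsOptions.Strict
    )


def default_conformer_count(m: Molecule, role: str) -> int:
    """Conformer count policy: 10 for the API; 1 for rigid and 3 for
    flexible coformers (flexible = at least one rotatable bond)."""
    if role == "api":
        return 10
    if role == "coformer":
        return 1 if count_rotatable_bonds(m) == 0 else 3
    raise ValueError(f"role must be 'api' or 'coformer', got {role!r}")


def embed_conformers(m: Molecule, n: int, seed: int = 2025) -> ConformerEnsemble:
    """Generate ``n`` low-energy 3D conformers with explicit hydrogens.

    Distance-geometry embedding (ETKDGv3) with a fixed random seed,
    followed by MMFF94 minimisation (UFF fallback for atoms outside the
    MMFF parameterisation).  Deterministic: the same (molecule, n, seed)
    yields bitwise-identical coordinates.

    Raises
    ------
    EmbeddingError
        If fewer than ``n`` conformers could be embedded after retrying
        with random-coordinate initialisation.
    """
    if n < 1:
        raise ValueError("conformer count must be >= 1")
    molh = Chem.AddHs(Chem.Mol(m.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    cids = list(AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params))
    if len(cids) < n:
        params.useRandomCoords = True
        params.maxIterations = 2000
        molh.RemoveAllConformers()
        cids = list(AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params))
    if len(cids) < n:
        raise EmbeddingError(
            f"could not embed {n} conformer(s) of {m.name or m.smiles!r} "
            f"(got {len(cids)})"
        )
    if AllChem.MMFFHasAllMoleculeParams(molh):
        AllChem.MMFFOptimizeMoleculeConfs(molh)
    else:
        AllChem.UFFOptimizeMoleculeConfs(molh)
    elements = tuple(a.GetSymbol() for a in molh.GetAtoms())
    conformers = tuple(
        Conformer(
            coordinates=molh.GetConformer(cid).GetPositions(),
            parent=m,
            elements=elements,
        )
        for cid in cids
    )
    return ConformerEnsemble(
        molecule=m, conformers=conformers, seed=int(seed), rdmol_h=molh
    )


def ensemble_to_sdf(ensemble: ConformerEnsemble, path) -> None:
    """Write a conformer ensemble as a multi-record V2000 SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        mol = Chem.Mol(ensemble.rdmol_h)
        mol.SetProp("_Name", ensemble.molecule.name)
        mol.SetIntProp("embedding_seed", ensemble.seed)
        for conf in mol.GetConformers():
            writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()
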