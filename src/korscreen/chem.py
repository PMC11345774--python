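"""Molecule handling: I/O, conformers, feature perception, descriptors, basicity filters.

The definition of "nonbasic" used throughout the pipeline lives here: a
compound passes only if it carries no formal charge anywhere and no amine
expected to be protonated at physiological pH (aliphatic primary/secondary/
tertiary amines, amidines, guanidines). Amide, anilinic and aromatic-ring
nitrogens do not count as basic.

Pharmacophore feature perception follows a declared, tool-independent
convention (see docs/methods.md):

* HBA — carbonyl oxygen, hydroxyl/aliphatic-ether oxygen (ester sp3 oxygen
  and aromatic ring oxygen excluded), nitrile nitrogen, aromatic nitrogen
  without hydrogen; never on charged atoms.
* HBD — neutral N or O bearing at least one hydrogen.
* HY — one feature per all-carbon(/S/halogen) ring at the ring centroid,
  plus one per bonded cluster (size >= 2) of acyclic apolar atoms; atoms
  adjacent to a charged atom are not apolar.
* AR — aromatic ring centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("HBA", "HBD", "HY", "AR")

# --- SMARTS conventions -----------------------------------------------------

_HBA_PATTERNS = {
    "carbonyl_O": Chem.MolFromSmarts("[OX1;+0]=[#6]"),
    "hydroxyl_O": Chem.MolFromSmarts("[OX2H1;+0;!$([OX2][#6X3]=[OX1])]"),
    # aliphatic ether O that is not the sp3 oxygen of an ester and not aromatic
    "ether_O": Chem.MolFromSmarts("[OX2H0;+0;!a;!$([OX2][#6X3]=[OX1])]"),
    "nitrile_N": Chem.MolFromSmarts("[NX1;+0]#[CX2]"),
    "aromatic_N": Chem.MolFromSmarts("[nX2;H0;+0]"),
}

_HBD_PATTERNS = {
    "N_H": Chem.MolFromSmarts("[#7;H1,H2,H3;+0]"),
    "O_H": Chem.MolFromSmarts("[OX2H1;+0]"),
}

# basic nitrogens: aliphatic amines (not amide/thioamide/sulfonamide/anilinic/
# imine/nitrile), plus amidine and guanidine groups
_BASIC_AMINE = Chem.MolFromSmarts(
    "[NX3;+0;H2,H1,H0;"
    "!$([NX3][#6X3]=[OX1]);"  # amide
    "!$([NX3][#6X3]=[SX1]);"  # thioamide
    "!$([NX3][#6X3]=[NX2]);"  # amidine sp3 N (counted via _AMIDINE)
    "!$([NX3][SX4](=[OX1])=[OX1]);"  # sulfonamide
    "!$([NX3]a);"  # anilinic
    "!$([NX3][NX2]=*);"  # hydrazone
    "$([NX3]([#6X4,#1])([#6X4,#1])[#6X4,#1])"  # only sp3-C/H neighbors
    "]"
)
_AMIDINE = Chem.MolFromSmarts("[NX2;+0]=[CX3][NX3;+0]")
_GUANIDINE = Chem.MolFromSmarts("[NX2;+0]=[CX3]([NX3;+0])[NX3;+0]")

_APOLAR_ELEMENTS = {6, 16, 9, 17, 35, 53}  # C, S, F, Cl, Br, I


class BasicityVerdict(str, Enum):
    """Outcome of the nonbasic (charge/basicity) filter."""

    PASS = "pass"
    FAIL_CHARGED = "fail_charged"
    FAIL_BASIC = "fail_basic"


@dataclass
class PerceivedFeature:
    """A pharmacophore feature perceived on one conformer."""

    kind: str
    center: np.ndarray
    source_atoms: tuple[int, ...]
    weight: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class MoleculeRecord:
    """A library compound: structure, conformers, descriptors, filter flags.

    The RDKit molecule is stored without explicit hydrogens; conformers hold
    heavy-atom coordinates in Angstrom.
    """

    id: str
    mol: Chem.Mol
    descriptors: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def inchikey(self) -> str:
        return Chem.MolToInchiKey(self.mol)

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def conformer_coords(self, index: int = 0) -> np.ndarray:
        if index >= self.mol.GetNumConformers():
            raise IndexError(
                f"molecule {self.id!r} has {self.mol.GetNumConformers()} "
                f"conformer(s); index {index} out of range"
            )
        return np.array(self.mol.GetConformer(index).GetPositions(), dtype=float)


def from_smiles(mol_id: str, smiles: str) -> MoleculeRecord:
    """Build a record from SMILES; raises ValueError on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {mol_id!r}: {smiles!r}")
    rec = MoleculeRecord(id=mol_id, mol=mol)
    rec.descriptors = compute_descriptors(rec)
    verdict = nonbasic_filter(rec)
    rec.flags = {
        "is_charged": verdict is BasicityVerdict.FAIL_CHARGED,
        "has_basic_amine": verdict is BasicityVerdict.FAIL_BASIC,
    }
    return rec


def read_library(path: str | Path, fmt: str | None = None) -> list[MoleculeRecord]:
    """Read a compound library from a SMILES (.smi, one `SMILES<TAB>ID` per
    line) or SDF file. Invalid entries are logged and skipped; an empty
    result raises ValueError."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"library file not found: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".mol", ".sd"} else "smiles"
    records: list[MoleculeRecord] = []
    n_skipped = 0
    if fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
            try:
                records.append(from_smiles(mol_id, smiles))
            except ValueError:
                n_skipped += 1
                logger.warning("skipping unparseable SMILES line %d of %s", i + 1, path)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                logger.warning("skipping unparseable SDF block %d of %s", i + 1, path)
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}_{i}"
            rec = MoleculeRecord(id=mol_id, mol=mol)
            rec.descriptors = compute_descriptors(rec)
            verdict = nonbasic_filter(rec)
            rec.flags = {
                "is_charged": verdict is BasicityVerdict.FAIL_CHARGED,
                "has_basic_amine": verdict is BasicityVerdict.FAIL_BASIC,
            }
            records.append(rec)
    else:
        raise ValueError(f"unknown library format {fmt!r}")
    if not records:
        raise ValueError(f"no valid molecules in {path}")
    if n_skipped:
        logger.info("%s: read %d molecules, skipped %d", path, len(records), n_skipped)
    return records


def write_smiles(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def write_sdf(records: Iterable[MoleculeRecord], path: str | Path, conformer_index: int = 0) -> None:
    """Write records (first/selected conformer) as SDF V2000."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for rec in records:
        mol = Chem.Mol(rec.mol)
        mol.SetProp("_Name", rec.id)
        if mol.GetNumConformers() > conformer_index:
            writer.write(mol, confId=mol.GetConformers()[conformer_index].GetId())
        else:
            writer.write(mol)
    writer.close()


def embed_conformers(rec: MoleculeRecord, n_conformers: int = 1, seed: int = 0xC0FFEE % (2**31)) -> MoleculeRecord:
    """Generate 3D conformers (ETKDG) in place; heavy-atom coordinates only.

    The embedding seed is fixed per call so identical input yields identical
    geometry.
    """
    molh = Chem.AddHs(rec.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31)
    params.useRandomCoords = False
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_conformers, params=params)
    if len(ids) == 0:
        # fall back to random coords for pathological inputs
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_conformers, params=params)
    if len(ids) == 0:
        raise RuntimeError(f"conformer embedding failed for {rec.id}")
    for cid in ids:
        AllChem.MMFFOptimizeMolecule(molh, confId=cid, maxIters=200)
    rec.mol = Chem.RemoveHs(molh)
    return rec


# --- perception -------------------------------------------------------------

def _hba_atoms(mol: Chem.Mol) -> set[int]:
    atoms: set[int] = set()
    for patt in _HBA_PATTERNS.values():
        for match in mol.GetSubstructMatches(patt):
            atoms.add(match[0])
    return atoms


def _hbd_atoms(mol: Chem.Mol) -> set[int]:
    atoms: set[int] = set()
    for patt in _HBD_PATTERNS.values():
        for match in mol.GetSubstructMatches(patt):
            atoms.add(match[0])
    return atoms


def _apolar_atoms(mol: Chem.Mol) -> set[int]:
    apolar: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in _APOLAR_ELEMENTS:
            continue
        if atom.GetFormalCharge() != 0:
            continue
        if any(nb.GetFormalCharge() != 0 for nb in atom.GetNeighbors()):
            continue
        apolar.add(atom.GetIdx())
    return apolar


def _hy_clusters(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Hydrophobic clusters: one per fully apolar ring, plus connected
    clusters (size >= 2) of acyclic apolar atoms."""
    apolar = _apolar_atoms(mol)
    clusters: list[tuple[int, ...]] = []
    ring_atoms: set[int] = set()
    for ring in mol.GetRingInfo().AtomRings():
        ring_atoms.update(ring)
        if all(a in apolar for a in ring):
            clusters.append(tuple(sorted(ring)))
    acyclic = apolar - ring_atoms
    seen: set[int] = set()
    for start in sorted(acyclic):
        if start in seen:
            continue
        component = {start}
        stack = [start]
        while stack:
            a = stack.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                j = nb.GetIdx()
                if j in acyclic and j not in component:
                    component.add(j)
                    stack.append(j)
        seen |= component
        if len(component) >= 2:
            clusters.append(tuple(sorted(component)))
    return clusters


def _aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    return [
        tuple(sorted(ring))
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring)
    ]


def perceive_features(rec: MoleculeRecord, conformer_index: int = 0) -> list[PerceivedFeature]:
    """Perceive HBA/HBD/HY/AR features on one conformer.

    Feature centers are atom positions (HBA/HBD) or centroids of the
    contributing atoms (HY/AR).
    """
    coords = rec.conformer_coords(conformer_index)
    feats: list[PerceivedFeature] = []
    for idx in sorted(_hba_atoms(rec.mol)):
        feats.append(PerceivedFeature("HBA", coords[idx], (idx,), 1))
    for idx in sorted(_hbd_atoms(rec.mol)):
        feats.append(PerceivedFeature("HBD", coords[idx], (idx,), 1))
    for cluster in _hy_clusters(rec.mol):
        feats.append(
            PerceivedFeature("HY", coords[list(cluster)].mean(axis=0), cluster, len(cluster))
        )
    for ring in _aromatic_rings(rec.mol):
        feats.append(
            PerceivedFeature("AR", coords[list(ring)].mean(axis=0), ring, len(ring))
        )
    return feats


# --- filters and descriptors -----------------------------------------------

def nonbasic_filter(rec: MoleculeRecord) -> BasicityVerdict:
    """Charge/basicity verdict; a pure function of the connection table."""
    mol = rec.mol
    if Chem.GetFormalCharge(mol) != 0 or any(
        a.GetFormalCharge() != 0 for a in mol.GetAtoms()
    ):
        return BasicityVerdict.FAIL_CHARGED
    if (
        mol.HasSubstructMatch(_BASIC_AMINE)
        or mol.HasSubstructMatch(_AMIDINE)
        or mol.HasSubstructMatch(_GUANIDINE)
    ):
        return BasicityVerdict.FAIL_BASIC
    return BasicityVerdict.PASS


def compute_descriptors(rec: MoleculeRecord) -> dict:
    """Physicochemical descriptors used by the decoy generator and triage.

    HBD/HBA counts use the same perception rules as the 3D features so that
    property windows and query features agree on what counts as an acceptor.
    Computed on the canonically renumbered connection table so the values
    are bit-identical regardless of atom input order.
    """
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(rec.mol))
    if mol is None:  # pathological round-trip failure; fall back
        mol = rec.mol
    return {
        "MW": float(Descriptors.MolWt(mol)),
        "rotatable_bonds": int(Descriptors.NumRotatableBonds(mol)),
        "hbd": len(_hbd_atoms(mol)),
        "hba": len(_hba_atoms(mol)),
        "logP_estimate": float(Crippen.MolLogP(mol)),
        "net_formal_charge": int(Chem.GetFormalCharge(mol)),
    }


def descriptor_table(records: Sequence[MoleculeRecord]):
    """Descriptor TSV-ready table (pandas DataFrame, one row per molecule)."""
    import pandas as pd

    rows = []
    for rec in records:
        d = rec.descriptors or compute_descriptors(rec)
        rows.append({"id": rec.id, **d, **rec.flags})
    return pd.DataFrame(rows)
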