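"""Reading molecule files and indexing circular atom environments.

Molecules are read from SMILES, SDF or MOL2 files into an ordered
:class:`MoleculeSet`; records that fail to parse are logged and dropped,
and their original positions are kept so that activity vectors supplied
in file order can be realigned.

Substructures are circular (Morgan/ECFP-style) atom environments: for
every heavy atom of a molecule and every bond radius requested, the
environment within that many bonds of the root atom is assigned the
integer identifier produced by the standard connectivity-invariant
hashing.  Identifiers are stable across runs and machines.  Hash
collisions (distinct environments mapping to the same identifier) are
accepted and treated as the same substructure.

The :class:`SubstructureIndex` built from a training set records, for
every identifier, which molecules contain it (presence-based: a molecule
counts once however many occurrences it has), its bond radius and a
SMILES rendering.  It is the shared basis for keyed fingerprints and for
both alert-derivation algorithms.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

# RDKit is chatty about individual parse failures; we log them ourselves.
RDLogger.DisableLog("rdApp.error")

ACTIVE_LABELS = {"1", "active", "true", "yes", "toxic", "pos", "positive"}
INACTIVE_LABELS = {"0", "inactive", "false", "no", "nontoxic", "non-toxic",
                   "neg", "negative"}


@dataclass
class MoleculeRecord:
    """One successfully parsed molecule.

    ``index`` is the 0-based position among *kept* molecules (contiguous
    after parse failures are removed); ``source`` points back at the
    originating line or block for provenance.
    """

    index: int
    mol: Chem.Mol
    name: str = ""
    source: str = ""


@dataclass
class AtomEnvironment:
    """A circular substructure rooted at one heavy atom.

    For a fixed (molecule, root atom) the radii of emitted environments
    are distinct; an environment exists only while the radius does not
    exceed the reachable graph distance from the root.
    """

    molecule_index: int
    root_atom: int
    radius: int
    identifier: int


@dataclass
class MoleculeSet:
    """Ordered parsed molecules with an optional parallel activity vector."""

    records: list[MoleculeRecord]
    activities: np.ndarray | None = None
    activity_kind: str | None = None  # "binary" | "continuous"
    failed: list[tuple[int, str]] = field(default_factory=list)
    n_input: int | None = None  # record count before failure removal

    def __post_init__(self) -> None:
        if self.n_input is None:
            self.n_input = len(self.records) + len(self.failed)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    @property
    def mols(self) -> list[Chem.Mol]:
        return [r.mol for r in self.records]

    def write_smiles(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                name = rec.name or f"mol{rec.index}"
                fh.write(f"{Chem.MolToSmiles(rec.mol)}\t{name}\n")

    def write_sdf(self, path: str | os.PathLike,
                  activity_tag: str | None = None) -> None:
        writer = Chem.SDWriter(str(path))
        try:
            for i, rec in enumerate(self.records):
                mol = Chem.Mol(rec.mol)
                mol.SetProp("_Name", rec.name or f"mol{rec.index}")
                if activity_tag is not None and self.activities is not None:
                    mol.SetProp(activity_tag, str(self.activities[i]))
                writer.write(mol)
        finally:
            writer.close()


@dataclass
class SubstructureIndex:
    """Training-set mapping substructure identifier -> containing molecules.

    ``n`` is the number of training molecules; ``entries[id]`` is the
    sorted tuple of training molecule indices containing the identifier
    at least once.  ``example_of[id]`` records one (molecule index, root
    atom) occurrence for SMILES rendering and depiction.
    """

    n: int
    entries: dict[int, tuple[int, ...]]
    radius_of: dict[int, int]
    smiles_of: dict[int, str]
    radii_allowed: frozenset[int]
    example_of: dict[int, tuple[int, int]] = field(default_factory=dict)

    def n_s(self, identifier: int) -> int:
        """Number of training compounds containing the substructure."""
        return len(self.entries[identifier])

    def __contains__(self, identifier: int) -> bool:
        return identifier in self.entries

    def __len__(self) -> int:
        return len(self.entries)


# one Morgan generator per max radius, shared across calls
_GENERATORS: dict[int, object] = {}


def _generator(max_radius: int):
    gen = _GENERATORS.get(max_radius)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=max_radius)
        _GENERATORS[max_radius] = gen
    return gen


def enumerate_atom_environments(
    record: MoleculeRecord | Chem.Mol,
    radii: Iterable[int],
    molecule_index: int | None = None,
) -> list[AtomEnvironment]:
    """Enumerate the circular environments of one molecule.

    Emits one :class:`AtomEnvironment` per (heavy atom, radius) pair for
    which the environment exists, ordered by atom index then ascending
    radius.  Environments are enumerated per root atom so that symmetric
    occurrences (identical environments rooted at different atoms) are
    all reported.
    """
    radii = sorted(set(int(r) for r in radii))
    if not radii:
        raise ValueError("radii must be a non-empty set of integers >= 0")
    if radii[0] < 0:
        raise ValueError("bond radii must be >= 0")
    if isinstance(record, MoleculeRecord):
        mol = record.mol
        mol_index = record.index if molecule_index is None else molecule_index
    else:
        mol = record
        mol_index = 0 if molecule_index is None else molecule_index

    gen = _generator(max(radii))
    wanted = set(radii)
    out: list[AtomEnvironment] = []
    for atom_idx in range(mol.GetNumAtoms()):
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        gen.GetSparseCountFingerprint(mol, fromAtoms=[atom_idx],
                                      additionalOutput=ao)
        by_radius: dict[int, int] = {}
        for identifier, occurrences in ao.GetBitInfoMap().items():
            for root, radius in occurrences:
                if root == atom_idx and radius in wanted:
                    by_radius[radius] = identifier
        for radius in sorted(by_radius):
            out.append(AtomEnvironment(mol_index, atom_idx, radius,
                                       by_radius[radius]))
    return out


def environment_smiles(mol: Chem.Mol, root_atom: int, radius: int) -> str:
    """Canonical SMILES of the environment subgraph around ``root_atom``."""
    if radius == 0:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[root_atom])
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, root_atom)
    atoms: set[int] = {root_atom}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms),
                                    bondsToUse=list(bonds), canonical=True)


def extract_substructure_information(
    molset: MoleculeSet | Sequence[Chem.Mol],
    radii: Iterable[int],
) -> SubstructureIndex:
    """Build the substructure dictionary of a molecule set.

    Entries cover exactly the identifiers emitted by
    :func:`enumerate_atom_environments` over all molecules, restricted to
    ``radii``; ``entries[id]`` lists every molecule containing ``id`` at
    least once (presence-based counting).
    """
    records = molset.records if isinstance(molset, MoleculeSet) else [
        MoleculeRecord(i, m) for i, m in enumerate(molset)]
    if not records:
        raise ValueError("cannot index an empty molecule set")
    radii_set = frozenset(int(r) for r in radii)

    containing: dict[int, set[int]] = {}
    radius_of: dict[int, int] = {}
    example_of: dict[int, tuple[int, int]] = {}
    for i, rec in enumerate(records):
        for env in enumerate_atom_environments(rec.mol, radii_set,
                                               molecule_index=i):
            containing.setdefault(env.identifier, set()).add(i)
            if env.identifier not in radius_of:
                radius_of[env.identifier] = env.radius
                example_of[env.identifier] = (i, env.root_atom)

    smiles_of = {}
    for identifier, (mol_i, root) in example_of.items():
        smiles_of[identifier] = environment_smiles(
            records[mol_i].mol, root, radius_of[identifier])

    return SubstructureIndex(
        n=len(records),
        entries={k: tuple(sorted(v)) for k, v in containing.items()},
        radius_of=radius_of,
        smiles_of=smiles_of,
        radii_allowed=radii_set,
        example_of=example_of,
    )


def _read_smiles_file(path: str, delimiter: str | None = None
                      ) -> tuple[list[tuple[Chem.Mol, str, str]],
                                 list[tuple[int, str]]]:
    parsed, failed = [], []
    position = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(delimiter)
            smiles, name = tokens[0], (tokens[1] if len(tokens) > 1 else "")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None or mol.GetNumAtoms() == 0:
                failed.append((position, f"unparseable SMILES: {smiles!r}"))
            else:
                parsed.append((mol, name, line))
            position += 1
    return parsed, failed


def _read_sdf_file(path: str) -> tuple[list[tuple[Chem.Mol, str, str]],
                                       list[tuple[int, str]]]:
    parsed, failed = [], []
    supplier = Chem.SDMolSupplier(path, sanitize=True, removeHs=True)
    for position, mol in enumerate(supplier):
        if mol is None or mol.GetNumAtoms() == 0:
            failed.append((position, "unparseable SDF record"))
        else:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            parsed.append((mol, name, f"record {position}"))
    return parsed, failed


def _read_mol2_file(path: str) -> tuple[list[tuple[Chem.Mol, str, str]],
                                        list[tuple[int, str]]]:
    # RDKit has no multi-record mol2 supplier; split on the MOLECULE tag.
    with open(path) as fh:
        text = fh.read()
    blocks = ["@<TRIPOS>MOLECULE" + b
              for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
    parsed, failed = [], []
    for position, block in enumerate(blocks):
        mol = Chem.MolFromMol2Block(block, sanitize=True)
        if mol is None or mol.GetNumAtoms() == 0:
            failed.append((position, "unparseable MOL2 block"))
        else:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            parsed.append((mol, name, f"block {position}"))
    return parsed, failed


_EXTENSION_FORMATS = {".smi": "smiles", ".smiles": "smiles", ".txt": "smiles",
                      ".sdf": "sdf", ".mol2": "mol2"}


def read_molecules(path: str | os.PathLike, format: str | None = None,
                   delimiter: str | None = None) -> MoleculeSet:
    """Read a molecule file into a :class:`MoleculeSet`.

    Parameters
    ----------
    path:
        File in SMILES (one record per line, whitespace- or
        tab-delimited, first token SMILES, optional second token name,
        ``#`` comment lines skipped), SDF (V2000) or MOL2 format.
    format:
        ``smiles``, ``sdf`` or ``mol2``; inferred from the extension
        when omitted.
    delimiter:
        Column delimiter for SMILES files (default: any whitespace).

    Individual unparseable records are logged with a WARN line and kept
    in ``failed`` with their original position; a missing file or a file
    with zero parseable molecules raises.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = _EXTENSION_FORMATS.get(os.path.splitext(path)[1].lower())
        if format is None:
            raise ValueError(
                f"cannot infer molecule format from {path!r}; pass format=")
    format = format.lower()
    if format == "smiles":
        parsed, failed = _read_smiles_file(path, delimiter)
    elif format == "sdf":
        parsed, failed = _read_sdf_file(path)
    elif format == "mol2":
        parsed, failed = _read_mol2_file(path)
    else:
        raise ValueError(f"unsupported molecule format: {format!r}")

    for position, reason in failed:
        logger.warning("skipping record %d of %s: %s", position, path, reason)
    if not parsed:
        raise ValueError(f"no parseable molecules in {path!r}")

    records = [MoleculeRecord(i, mol, name, src)
               for i, (mol, name, src) in enumerate(parsed)]
    return MoleculeSet(records=records, failed=failed,
                       n_input=len(parsed) + len(failed))


def _normalize_binary_labels(values: Sequence) -> np.ndarray:
    out = np.empty(len(values), dtype=bool)
    for i, v in enumerate(values):
        key = str(v).strip().lower()
        if key in ACTIVE_LABELS:
            out[i] = True
        elif key in INACTIVE_LABELS:
            out[i] = False
        else:
            raise ValueError(f"unrecognizable activity label: {v!r}")
    return out


def attach_activities(molset: MoleculeSet, values: Sequence,
                      kind: str = "auto") -> MoleculeSet:
    """Attach an activity vector given in ORIGINAL input order.

    Values at positions that failed to parse are dropped so the stored
    vector is parallel to the kept molecules.  ``kind`` is ``binary``,
    ``continuous`` or ``auto`` (binary iff every value is a recognizable
    label).  Binary labels are normalized to booleans (active=True).
    """
    values = list(values)
    if len(values) != molset.n_input:
        raise ValueError(
            f"activity vector has {len(values)} entries but the input file "
            f"had {molset.n_input} records (before failure removal)")
    failed_positions = {pos for pos, _ in molset.failed}
    kept = [v for i, v in enumerate(values) if i not in failed_positions]

    if kind == "auto":
        all_labels = all(str(v).strip().lower() in ACTIVE_LABELS | INACTIVE_LABELS
                         for v in kept)
        kind = "binary" if all_labels else "continuous"
    if kind == "binary":
        activities = _normalize_binary_labels(kept)
    elif kind == "continuous":
        activities = np.asarray(kept, dtype=float)
    else:
        raise ValueError(f"unknown activity kind: {kind!r}")
    return MoleculeSet(records=molset.records, activities=activities,
                       activity_kind=kind, failed=molset.failed,
                       n_input=molset.n_input)


def read_activities(path: str | os.PathLike) -> list:
    """Read an activity vector from a single- or two-column (id,value) CSV."""
    import pandas as pd

    frame = pd.read_csv(path, header=None)
    # tolerate an optional header row of non-numeric text in 2-column files
    if frame.shape[1] > 2:
        raise ValueError("activity file must have one or two columns")
    col = frame.iloc[:, -1]
    if frame.shape[1] == 2 and isinstance(col.iloc[0], str):
        try:
            float(col.iloc[0])
        except ValueError:
            if col.iloc[0].strip().lower() not in ACTIVE_LABELS | INACTIVE_LABELS:
                col = col.iloc[1:]
    return col.tolist()


def sdf_tag_activities(path: str | os.PathLike, tag: str) -> list:
    """Extract one property tag per record of an SDF, in file order.

    Failed records contribute a None placeholder so the vector stays
    parallel to the original record order expected by
    :func:`attach_activities`.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    values = []
    for mol in supplier:
        if mol is None:
            values.append(None)
        elif mol.HasProp(tag):
            values.append(mol.GetProp(tag))
        else:
            raise ValueError(f"SDF record missing activity tag {tag!r}")
    return values


def as_molecule_list(X) -> list[Chem.Mol]:
    """Coerce a MoleculeSet, list of Mol, or list of SMILES to RDKit mols."""
    if isinstance(X, MoleculeSet):
        return X.mols
    mols = []
    for i, item in enumerate(X):
        if isinstance(item, Chem.Mol):
            mols.append(item)
        elif isinstance(item, MoleculeRecord):
            mols.append(item.mol)
        elif isinstance(item, str):
            mol = Chem.MolFromSmiles(item)
            if mol is None:
                raise ValueError(f"unparseable SMILES at position {i}: {item!r}")
            mols.append(mol)
        else:
            raise TypeError(f"cannot interpret {type(item).__name__} as a molecule")
    if not mols:
        raise ValueError("empty molecule collection")
    return mols
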