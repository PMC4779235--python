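"""Hashed and unhashed (keyed) circular fingerprints.

Hashed fingerprints map each atom-environment identifier to the array
position ``identifier mod size``; collisions are part of the scheme.
Unhashed (keyed) fingerprints give every distinct substructure its own
column, so each column is chemically interpretable; the column basis can
be frozen on a training set and new compounds projected onto it, with
out-of-basis substructures dropped (an INFO line reports how many).

Both schemes come in count format (number of environment occurrences,
i.e. root atoms, per molecule) and binary format (indicator of a nonzero
count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .molecule_io import (
    MoleculeRecord,
    MoleculeSet,
    SubstructureIndex,
    as_molecule_list,
    enumerate_atom_environments,
    environment_smiles,
    extract_substructure_information,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintMatrix",
    "SubstructureCatalog",
    "HashedMorganFingerprinter",
    "UnhashedMorganFingerprinter",
    "calculate_hashed_fps",
    "calculate_unhashed_fps",
    "fold",
    "render_substructure_smiles",
    "depict_substructure",
]


@dataclass
class FingerprintMatrix:
    """Molecules x substructure-columns matrix.

    ``scheme`` is ``"hashed"`` (columns are array positions 0..L-1) or
    ``"keyed"`` (columns are substructure identifiers in ascending
    order).  Binary matrices contain only 0/1.
    """

    values: np.ndarray
    fmt: str  # "binary" | "count"
    scheme: str  # "hashed" | "keyed"
    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.fmt == "binary" and self.values.size:
            assert set(np.unique(self.values)) <= {0, 1}
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("matrix shape inconsistent with column labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SubstructureCatalog:
    """Identifier -> SMILES map for the columns of a keyed matrix."""

    smiles: dict[int, str]
    example: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __contains__(self, identifier: int) -> bool:
        return identifier in self.smiles

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"identifier": list(self.smiles), "smiles": list(self.smiles.values())}
        ).sort_values("identifier").to_csv(path, index=False)


def _occurrence_counts(mols, radii) -> list[dict[int, int]]:
    counts = []
    for mol in mols:
        per: dict[int, int] = {}
        for env in enumerate_atom_environments(mol, radii):
            per[env.identifier] = per.get(env.identifier, 0) + 1
        counts.append(per)
    return counts


class HashedMorganFingerprinter(TransformerMixin, BaseEstimator):
    """Fixed-length circular fingerprints folded by ``identifier mod size``.

    Stateless transformer: ``fit`` only validates parameters.

    Parameters
    ----------
    size:
        Fingerprint length L (columns are positions 0..L-1).
    max_radius:
        Environments of all radii 0..max_radius are folded in.
    fmt:
        ``"count"`` accumulates occurrence counts of every environment
        mapping to a position; ``"binary"`` is the indicator of a
        nonzero count.
    """

    def __init__(self, size: int = 2048, max_radius: int = 2,
                 fmt: str = "count"):
        self.size = size
        self.max_radius = max_radius
        self.fmt = fmt

    def _validate(self):
        if int(self.size) < 1:
            raise ValueError("fingerprint size must be >= 1")
        if self.fmt not in ("binary", "count"):
            raise ValueError("fmt must be 'binary' or 'count'")
        if int(self.max_radius) < 0:
            raise ValueError("max_radius must be >= 0")

    def fit(self, X, y=None):
        self._validate()
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        self._validate()
        mols = as_molecule_list(X)
        radii = range(int(self.max_radius) + 1)
        out = np.zeros((len(mols), int(self.size)), dtype=np.int64)
        for row, per in enumerate(_occurrence_counts(mols, radii)):
            for identifier, count in per.items():
                out[row, identifier % int(self.size)] += count
        if self.fmt == "binary":
            out = (out > 0).astype(np.int64)
        return out


class UnhashedMorganFingerprinter(TransformerMixin, BaseEstimator):
    """Keyed circular fingerprints on a frozen training basis.

    ``fit`` builds the basis: the distinct substructure identifiers of
    the training molecules at the requested radii, ordered ascending.
    ``transform`` projects molecules onto that basis; substructures not
    in the basis are dropped (a summary INFO line reports the count of
    distinct dropped identifiers).

    Fitted attributes
    -----------------
    basis_ : SubstructureIndex of the training set
    columns_ : tuple of identifiers, ascending
    catalog_ : SubstructureCatalog covering every column
    """

    def __init__(self, radii: Iterable[int] = (0, 1, 2), fmt: str = "count"):
        self.radii = radii
        self.fmt = fmt

    def _validate(self):
        if self.fmt not in ("binary", "count"):
            raise ValueError("fmt must be 'binary' or 'count'")
        radii = tuple(sorted(set(int(r) for r in self.radii)))
        if not radii:
            raise ValueError("radii must be non-empty")
        return radii

    def fit(self, X, y=None):
        radii = self._validate()
        mols = as_molecule_list(X)
        self.basis_ = extract_substructure_information(mols, radii)
        return self._from_basis(self.basis_)

    def _from_basis(self, basis: SubstructureIndex):
        if not len(basis):
            raise ValueError("empty substructure basis")
        self.basis_ = basis
        self.columns_ = tuple(sorted(basis.entries))
        self.catalog_ = SubstructureCatalog(
            smiles={i: basis.smiles_of[i] for i in self.columns_},
            example={i: basis.example_of[i] for i in self.columns_
                     if i in basis.example_of},
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        radii = self._validate()
        if not hasattr(self, "columns_"):
            raise ValueError("transform called before fit")
        mols = as_molecule_list(X)
        position = {identifier: j for j, identifier in enumerate(self.columns_)}
        out = np.zeros((len(mols), len(self.columns_)), dtype=np.int64)
        dropped: set[int] = set()
        for row, per in enumerate(_occurrence_counts(mols, radii)):
            for identifier, count in per.items():
                j = position.get(identifier)
                if j is None:
                    dropped.add(identifier)
                else:
                    out[row, j] = count
        if dropped:
            logger.info("dropped %d distinct substructures absent from the "
                        "training basis", len(dropped))
        if self.fmt == "binary":
            out = (out > 0).astype(np.int64)
        return out


def calculate_hashed_fps(molset, size: int, max_radius: int = 2,
                         fmt: str = "count") -> FingerprintMatrix:
    """Hashed fingerprints of a molecule set (see the class docs)."""
    values = HashedMorganFingerprinter(size=size, max_radius=max_radius,
                                       fmt=fmt).fit(molset).transform(molset)
    return FingerprintMatrix(values, fmt=fmt, scheme="hashed",
                             columns=tuple(range(int(size))))


def calculate_unhashed_fps(
    molset,
    radii: Iterable[int],
    basis: SubstructureIndex | None = None,
    fmt: str = "count",
) -> tuple[FingerprintMatrix, SubstructureCatalog]:
    """Keyed fingerprints, optionally on a frozen training basis.

    Without ``basis`` the columns are the distinct substructures of the
    molecule set itself; with ``basis`` they are exactly the basis
    identifiers (ascending) and novel substructures are dropped.
    """
    est = UnhashedMorganFingerprinter(radii=radii, fmt=fmt)
    if basis is None:
        est.fit(molset)
    else:
        if frozenset(int(r) for r in radii) != basis.radii_allowed:
            raise ValueError("radii do not match the ones the basis was "
                             "built with")
        est._validate()
        est._from_basis(basis)
    values = est.transform(molset)
    matrix = FingerprintMatrix(values, fmt=fmt, scheme="keyed",
                               columns=est.columns_)
    return matrix, est.catalog_


def fold(fp: FingerprintMatrix, size: int) -> FingerprintMatrix:
    """Fold a keyed count matrix into a hashed one of length ``size``.

    Column with identifier ``id`` contributes its counts to position
    ``id mod size``.
    """
    if fp.scheme != "keyed":
        raise ValueError("fold applies to keyed fingerprints only")
    if fp.fmt != "count":
        raise ValueError("fold applies to count-format fingerprints only")
    if int(size) < 1:
        raise ValueError("fingerprint size must be >= 1")
    out = np.zeros((fp.values.shape[0], int(size)), dtype=np.int64)
    for j, identifier in enumerate(fp.columns):
        out[:, identifier % int(size)] += fp.values[:, j]
    return FingerprintMatrix(out, fmt="count", scheme="hashed",
                             columns=tuple(range(int(size))))


def render_substructure_smiles(source, identifier: int) -> str:
    """SMILES of a substructure known to an index or catalog."""
    if isinstance(source, SubstructureCatalog):
        table = source.smiles
    elif isinstance(source, SubstructureIndex):
        table = source.smiles_of
    else:
        table = dict(source)
    if identifier not in table:
        raise KeyError(f"unknown substructure identifier: {identifier}")
    return table[identifier]


def _locate_environment(mol: Chem.Mol, identifier: int,
                        max_radius: int = 6) -> tuple[int, int]:
    for env in enumerate_atom_environments(mol, range(max_radius + 1)):
        if env.identifier == identifier:
            return env.root_atom, env.radius
    raise KeyError(f"substructure {identifier} does not occur in the molecule")


def depict_substructure(record: MoleculeRecord | Chem.Mol, identifier: int,
                        outfile, fmt: str | None = None) -> None:
    """Draw the molecule with the substructure's atoms/bonds highlighted.

    Writes SVG by default; ``fmt="pdf"`` (or a ``.pdf`` outfile) uses the
    Cairo drawer and Pillow.  Raises if the identifier does not occur in
    the molecule, without creating a file.
    """
    from rdkit.Chem.Draw import rdMolDraw2D

    mol = record.mol if isinstance(record, MoleculeRecord) else record
    root, radius = _locate_environment(mol, identifier)
    highlight_atoms = {root}
    highlight_bonds = []
    if radius > 0:
        highlight_bonds = list(
            Chem.FindAtomEnvironmentOfRadiusN(mol, radius, root))
        for b in highlight_bonds:
            bond = mol.GetBondWithIdx(b)
            highlight_atoms.add(bond.GetBeginAtomIdx())
            highlight_atoms.add(bond.GetEndAtomIdx())

    outfile = str(outfile)
    if fmt is None:
        fmt = "pdf" if outfile.lower().endswith(".pdf") else "svg"
    mol = Chem.Mol(mol)
    rdMolDraw2D.PrepareMolForDrawing(mol)
    if fmt == "svg":
        drawer = rdMolDraw2D.MolDraw2DSVG(400, 350)
    elif fmt == "pdf":
        drawer = rdMolDraw2D.MolDraw2DCairo(800, 700)
    else:
        raise ValueError("depiction format must be 'svg' or 'pdf'")
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, highlightAtoms=sorted(highlight_atoms),
        highlightBonds=highlight_bonds)
    drawer.FinishDrawing()
    if fmt == "svg":
        with open(outfile, "w") as fh:
            fh.write(drawer.GetDrawingText())
    else:
        import io

        from PIL import Image

        image = Image.open(io.BytesIO(drawer.GetDrawingText()))
        image.convert("RGB").save(outfile, "PDF")
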