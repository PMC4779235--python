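"""Synthetic molecule sets with planted alert fragments.

Generates chemically valid molecules by joining a planted fragment (by
default a nitroaromatic, a classic mutagenicity toxicophore) onto
drug-like scaffolds from a fixed built-in library, with activity
structure under the generator's control:

* categorical mode — binary labels with configurable carrier
  probabilities P(fragment | active) and P(fragment | inactive), so the
  fragment can be made enriched among actives or independent of them;
* continuous mode — activity = baseline + shift * (carries fragment) +
  Normal(0, noise_sd).

All randomness flows through one ``numpy.random.default_rng(seed)``, so
a seed reproduces molecule lists and activities exactly, across
platforms.  The scaffold library deliberately contains no nitro group,
so the planted fragment contributes substructure identifiers present in
carriers and absent in every non-carrier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .molecule_io import (
    MoleculeRecord,
    MoleculeSet,
    enumerate_atom_environments,
)

__all__ = [
    "FixtureSpec",
    "SCAFFOLD_SMILES",
    "DEFAULT_FRAGMENT",
    "attach_fragment",
    "generate_categorical_set",
    "generate_continuous_set",
    "probe_set",
    "fragment_marker_ids",
]

# ~20 hand-written drug-like scaffolds; none contains a nitro group.
SCAFFOLD_SMILES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",     # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "c1ccc2ncccc2c1",                 # quinoline
    "Cc1ccc(S(N)(=O)=O)cc1",          # toluenesulfonamide
    "COc1ccc(CCN)cc1",                # methoxyphenethylamine
    "O=C(NCCO)c1ccccc1",              # benzamide ethanolamine
    "CN1CCN(c2ccccc2)CC1",            # phenylpiperazine
    "O=C(O)c1ccccc1O",                # salicylic acid
    "Clc1ccccc1CN1CCOCC1",            # chlorobenzyl morpholine
    "c1ccc2c(c1)OCO2",                # benzodioxole
    "CCOC(=O)c1ccccc1N",              # benzocaine
    "CC(C)NCC(O)COc1ccccc1",          # propranolol-like ether
    "O=S(=O)(c1ccccc1)N1CCCC1",       # phenylsulfonyl pyrrolidine
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine
    "OCC1OC(O)C(O)C(O)C1O",           # pyranose sugar
    "CC(N)Cc1ccccc1",                 # amphetamine
    "O=C1CC(=O)NC(=O)N1",             # barbituric acid
    "Cc1ccccc1NC(=O)CN1CCCC1",        # anilide pyrrolidine
    "COc1cc(C=CC(=O)O)ccc1O",         # ferulic acid
)

# nitrobenzene: the nitro nitrogen/oxygens mark carriers unambiguously
DEFAULT_FRAGMENT = "O=[N+]([O-])c1ccccc1"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic data set.

    Categorical mode uses ``active_fraction`` and the two conditional
    planting probabilities; continuous mode uses ``carrier_fraction``,
    ``shift`` (activity offset of fragment carriers, e.g. pIC50 units),
    ``noise_sd`` and ``baseline``.
    """

    n_molecules: int
    fragment_smiles: str = DEFAULT_FRAGMENT
    # categorical mode
    active_fraction: float = 0.5
    p_frag_given_active: float | None = None
    p_frag_given_inactive: float | None = None
    # continuous mode
    carrier_fraction: float | None = None
    shift: float | None = None
    noise_sd: float = 0.3
    baseline: float = 6.0
    seed: int = 0

    def fragment_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.fragment_smiles)
        if mol is None:
            raise ValueError(
                f"invalid fragment SMILES: {self.fragment_smiles!r}")
        return mol


def _attachment_candidates(mol: Chem.Mol) -> list[int]:
    """Carbons with a spare hydrogen; aromatic ones preferred."""
    aromatic, aliphatic = [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() >= 1:
            (aromatic if atom.GetIsAromatic() else aliphatic).append(
                atom.GetIdx())
    return aromatic or aliphatic


def attach_fragment(scaffold: Chem.Mol | str, fragment: Chem.Mol | str,
                    rng: np.random.Generator | None = None) -> Chem.Mol:
    """Join fragment to scaffold by a single bond at CH attachment atoms.

    The scaffold attachment atom is drawn from the candidate carbons
    (seeded ``rng``; first candidate when ``rng`` is None); the fragment
    attaches at its first candidate carbon.  The joined molecule is
    sanitized before being returned.
    """
    if isinstance(scaffold, str):
        scaffold = Chem.MolFromSmiles(scaffold)
    if isinstance(fragment, str):
        fragment = Chem.MolFromSmiles(fragment)
    if scaffold is None or fragment is None:
        raise ValueError("invalid scaffold or fragment")
    s_candidates = _attachment_candidates(scaffold)
    f_candidates = _attachment_candidates(fragment)
    if not s_candidates or not f_candidates:
        raise ValueError("no attachment carbon with a spare hydrogen")
    s_at = (s_candidates[0] if rng is None
            else int(rng.choice(s_candidates)))
    f_at = f_candidates[0]
    combo = Chem.RWMol(Chem.CombineMols(scaffold, fragment))
    combo.AddBond(s_at, scaffold.GetNumAtoms() + f_at, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _build_molecule(carrier: bool, fragment: Chem.Mol,
                    rng: np.random.Generator) -> Chem.Mol:
    # rejected joins are resampled with a different scaffold/site
    for _ in range(50):
        scaffold = Chem.MolFromSmiles(
            SCAFFOLD_SMILES[int(rng.integers(len(SCAFFOLD_SMILES)))])
        if not carrier:
            return scaffold
        try:
            return attach_fragment(scaffold, fragment, rng)
        except (ValueError, Chem.rdchem.MolSanitizeException):
            continue
    raise RuntimeError("could not build a valid carrier molecule")


def generate_categorical_set(spec: FixtureSpec) -> MoleculeSet:
    """Molecules with binary labels and label-conditional fragment planting.

    Exactly ``round(active_fraction * n)`` molecules are active (order
    randomized); each molecule carries the fragment with probability
    P(fragment | its label), so observed conditional frequencies match
    the spec within binomial sampling error.
    """
    if spec.p_frag_given_active is None or spec.p_frag_given_inactive is None:
        raise ValueError("categorical mode needs p_frag_given_active and "
                         "p_frag_given_inactive")
    for p in (spec.p_frag_given_active, spec.p_frag_given_inactive,
              spec.active_fraction):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    fragment = spec.fragment_mol()
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_molecules)
    n_active = round(spec.active_fraction * n)
    labels = np.zeros(n, dtype=bool)
    labels[:n_active] = True
    labels = labels[rng.permutation(n)]

    records = []
    for i in range(n):
        p_frag = (spec.p_frag_given_active if labels[i]
                  else spec.p_frag_given_inactive)
        carrier = bool(rng.random() < p_frag)
        mol = _build_molecule(carrier, fragment, rng)
        records.append(MoleculeRecord(i, mol, name=f"mol{i}",
                                      source="synthetic"))
    return MoleculeSet(records=records, activities=labels,
                       activity_kind="binary")


def generate_continuous_set(spec: FixtureSpec) -> MoleculeSet:
    """Molecules with activity = baseline + shift * carrier + noise."""
    if spec.carrier_fraction is None or spec.shift is None:
        raise ValueError("continuous mode needs carrier_fraction and shift")
    if not 0 <= spec.carrier_fraction <= 1:
        raise ValueError("carrier_fraction must lie in [0, 1]")
    if spec.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    fragment = spec.fragment_mol()
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_molecules)

    records, carrier = [], np.zeros(n, dtype=bool)
    for i in range(n):
        carrier[i] = bool(rng.random() < spec.carrier_fraction)
        mol = _build_molecule(bool(carrier[i]), fragment, rng)
        records.append(MoleculeRecord(i, mol, name=f"mol{i}",
                                      source="synthetic"))
    activities = (spec.baseline + spec.shift * carrier.astype(float)
                  + rng.normal(0.0, spec.noise_sd, size=n))
    return MoleculeSet(records=records, activities=activities,
                       activity_kind="continuous")


def probe_set(spec: FixtureSpec, n: int = 1) -> MoleculeSet:
    """A small test set of fragment carriers, seeded independently of
    the training draw (seed offset keeps both below 2**31)."""
    fragment = spec.fragment_mol()
    rng = np.random.default_rng((spec.seed + 777_000_003) % (2**31))
    records = [MoleculeRecord(i, _build_molecule(True, fragment, rng),
                              name=f"probe{i}", source="synthetic")
               for i in range(int(n))]
    return MoleculeSet(records=records)


def fragment_marker_ids(spec: FixtureSpec | str,
                        radii=(0,)) -> frozenset[int]:
    """Substructure identifiers that mark fragment carriers.

    Radius-0 environments of the free fragment whose identifier occurs
    in no scaffold; by construction (atom-level invariants do not see
    beyond the root at radius 0) these occur in every carrier and in no
    non-carrier.  Higher radii are context-dependent near the attachment
    bond and are excluded by default.
    """
    smiles = spec if isinstance(spec, str) else spec.fragment_smiles
    fragment = Chem.MolFromSmiles(smiles)
    if fragment is None:
        raise ValueError(f"invalid fragment SMILES: {smiles!r}")
    frag_ids = {env.identifier
                for env in enumerate_atom_environments(fragment, radii)}
    scaffold_ids: set[int] = set()
    for s in SCAFFOLD_SMILES:
        scaffold_ids |= {env.identifier for env in
                         enumerate_atom_environments(Chem.MolFromSmiles(s),
                                                     radii)}
    markers = frozenset(frag_ids - scaffold_ids)
    if not markers:
        raise ValueError("fragment shares all its environments with the "
                         "scaffold library; pick a more distinctive one")
    return markers
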