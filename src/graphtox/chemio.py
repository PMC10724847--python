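"""Molecule ingestion and description.

Wraps RDKit for SMILES parsing/canonicalization, Bemis-Murcko scaffolds,
path-based (Daylight-style) topological fingerprints and molecular weights,
and reads labelled CSV/TSV tables into a :class:`DatasetTable`.

Conventions: heavy-atom graphs only (hydrogens implicit as counts), 0-based
atom indices, stereochemistry not encoded.  Dot-disconnected SMILES (salts,
mixtures) keep the largest fragment by heavy-atom count, ties broken by
molecular weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "SmilesParseError",
    "DatasetError",
    "Atom",
    "Bond",
    "Molecule",
    "Fingerprint",
    "DatasetTable",
    "parse_smiles",
    "molecular_weight",
    "murcko_scaffold",
    "topological_fingerprint",
    "read_dataset",
    "read_smiles_list",
]

_BOND_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised for unparsable or valence-violating SMILES; carries the input."""

    def __init__(self, smiles: str, reason: str = "could not be parsed"):
        self.smiles = smiles
        super().__init__(f"SMILES {smiles!r} {reason}")


class DatasetError(ValueError):
    """Raised for malformed dataset tables (missing columns, bad labels)."""


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    aromatic: bool
    degree: int
    n_hydrogens: int


@dataclass(frozen=True)
class Bond:
    atom_i: int
    atom_j: int
    order: str  # single | double | triple | aromatic
    in_ring: bool
    conjugated: bool


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom molecular graph with its canonical SMILES identity key."""

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    canonical_smiles: str
    _rdmol: Chem.Mol = field(repr=False, compare=False, hash=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def __eq__(self, other):
        return isinstance(other, Molecule) and self.canonical_smiles == other.canonical_smiles

    def __hash__(self):
        return hash(self.canonical_smiles)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary topological structure vector."""

    bits: np.ndarray  # uint8 vector of {0,1}
    n_bits: int

    def __post_init__(self):
        if self.bits.shape != (self.n_bits,):
            raise ValueError("fingerprint length does not match n_bits")

    def __eq__(self, other):
        return (
            isinstance(other, Fingerprint)
            and self.n_bits == other.n_bits
            and bool(np.array_equal(self.bits, other.bits))
        )

    def popcount(self) -> int:
        return int(self.bits.sum())


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))


def parse_smiles(smiles: str) -> Molecule:
    """Parse one SMILES string into a canonicalized heavy-atom Molecule.

    Aromaticity is perceived, valence is checked, and salts/mixtures are
    reduced to their largest fragment.  Raises :class:`SmilesParseError`
    for anything RDKit rejects.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "is empty")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(smiles)
    if rdmol.GetNumHeavyAtoms() == 0:
        raise SmilesParseError(smiles, "contains no heavy atoms")
    rdmol = _largest_fragment(rdmol)
    atoms = tuple(
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            degree=a.GetDegree(),
            n_hydrogens=a.GetTotalNumHs(),
        )
        for a in rdmol.GetAtoms()
    )
    bonds = tuple(
        Bond(
            atom_i=b.GetBeginAtomIdx(),
            atom_j=b.GetEndAtomIdx(),
            order=_BOND_ORDER_NAMES.get(b.GetBondType(), "single"),
            in_ring=b.IsInRing(),
            conjugated=b.GetIsConjugated(),
        )
        for b in rdmol.GetBonds()
    )
    return Molecule(
        atoms=atoms,
        bonds=bonds,
        canonical_smiles=Chem.MolToSmiles(rdmol),
        _rdmol=rdmol,
    )


def molecular_weight(mol: Molecule) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    return float(Descriptors.MolWt(mol._rdmol))


def murcko_scaffold(mol: Molecule) -> str:
    """Bemis-Murcko scaffold key: ring systems plus linkers, side chains
    removed, as canonical SMILES.  Acyclic molecules map to the empty string
    (one shared scaffold group)."""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol._rdmol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def topological_fingerprint(mol: Molecule, n_bits: int = 2048) -> Fingerprint:
    """Hashed path-based binary fingerprint (RDKit topological/Daylight-style).

    Deterministic and invariant to the atom ordering of the input SMILES.
    """
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    bv = Chem.RDKFingerprint(mol._rdmol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return Fingerprint(bits=arr, n_bits=n_bits)


MISSING = None  # sentinel for a missing endpoint label

_TRUE_TOKENS = {"1", "1.0"}
_FALSE_TOKENS = {"0", "0.0"}
_MISSING_TOKENS = {"", "nan", "na", "none"}


def _parse_label(value) -> int | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    token = str(value).strip().lower()
    if token in _MISSING_TOKENS:
        return None
    if token in _TRUE_TOKENS:
        return 1
    if token in _FALSE_TOKENS:
        return 0
    raise DatasetError(f"unrecognized label value {value!r}; expected 0, 1 or missing")


@dataclass
class Record:
    molecule: Molecule
    labels: dict[str, int | None]


@dataclass
class DatasetTable:
    """Parsed labelled dataset: one record per successfully parsed SMILES.

    Rejected rows are retained in ``skipped`` (row index, SMILES) and counted;
    they are never silently dropped.
    """

    records: list[Record]
    endpoint_names: list[str]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def molecules(self) -> list[Molecule]:
        return [r.molecule for r in self.records]

    def labels_array(self, endpoint: str) -> np.ndarray:
        """Float array of labels for one endpoint; missing mapped to NaN."""
        if endpoint not in self.endpoint_names:
            raise DatasetError(f"unknown endpoint {endpoint!r}")
        return np.array(
            [np.nan if r.labels[endpoint] is None else float(r.labels[endpoint]) for r in self.records]
        )

    def label_counts(self, endpoint: str) -> dict[str, int]:
        arr = self.labels_array(endpoint)
        return {
            "positive": int(np.nansum(arr == 1.0)),
            "negative": int(np.nansum(arr == 0.0)),
            "missing": int(np.isnan(arr).sum()),
        }

    def summary(self) -> dict:
        """JSON-serializable dataset summary."""
        return {
            "n_records": len(self.records),
            "n_skipped": len(self.skipped),
            "endpoints": {name: self.label_counts(name) for name in self.endpoint_names},
        }

    def subset(self, indices) -> "DatasetTable":
        return DatasetTable(
            records=[self.records[i] for i in indices],
            endpoint_names=list(self.endpoint_names),
        )

    @classmethod
    def from_records(cls, smiles: list[str], labels: list[dict[str, int | None]], endpoint_names: list[str]) -> "DatasetTable":
        records, skipped = [], []
        for i, (smi, lab) in enumerate(zip(smiles, labels)):
            try:
                mol = parse_smiles(smi)
            except SmilesParseError:
                skipped.append((i, smi))
                continue
            records.append(Record(mol, {k: lab.get(k) for k in endpoint_names}))
        return cls(records=records, endpoint_names=list(endpoint_names), skipped=skipped)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"smiles": r.molecule.canonical_smiles}
            for name in self.endpoint_names:
                v = r.labels[name]
                row[name] = "" if v is None else v
            rows.append(row)
        return pd.DataFrame(rows, columns=["smiles"] + self.endpoint_names)


def read_dataset(path: str | Path, smiles_column: str = "smiles", endpoint_columns: list[str] | None = None) -> DatasetTable:
    """Read a CSV/TSV table (dialect chosen by extension) into a DatasetTable.

    Unparsable SMILES rows are skipped with a warning count; missing named
    columns raise :class:`DatasetError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if smiles_column not in df.columns:
        raise DatasetError(f"column {smiles_column!r} not found in {path}")
    if endpoint_columns is None:
        endpoint_columns = [c for c in df.columns if c != smiles_column]
    for col in endpoint_columns:
        if col not in df.columns:
            raise DatasetError(f"endpoint column {col!r} not found in {path}")

    labels = [
        {col: _parse_label(df.iloc[i][col]) for col in endpoint_columns}
        for i in range(len(df))
    ]
    table = DatasetTable.from_records(list(df[smiles_column]), labels, endpoint_columns)
    if table.skipped:
        logger.warning("skipped %d unparsable SMILES rows in %s", len(table.skipped), path)
    for name in endpoint_columns:
        counts = table.label_counts(name)
        if counts["positive"] + counts["negative"] == 0:
            logger.warning("endpoint %r has no non-missing labels", name)
    return table


def read_smiles_list(path: str | Path) -> list[str]:
    """Plain-text one-SMILES-per-line list (unlabeled pretraining pools)."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]
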