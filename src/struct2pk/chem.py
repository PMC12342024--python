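"""Structure ingestion, standardization and featurization.

Compounds arrive as raw SMILES, frequently as salts. Before any modeling
they are stripped to their largest organic fragment, neutralized where
chemically valid, and canonicalized. Models then consume either a 1024-bit
Morgan (circular, radius 2) fingerprint, the full named RDKit physico-
chemical descriptor panel, or an undirected molecular graph 3-tuple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator
from rdkit.Chem.Descriptors import MolWt
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

FINGERPRINT_BITS = 1024
FINGERPRINT_RADIUS = 2

#: Canonical descriptor name order: the RDKit descriptor registry order.
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _ in Descriptors._descList)

_HALOGENS = frozenset(("F", "Cl", "Br", "I"))

# measured-parameter columns understood in compound CSV files, with units
MEASURED_COLUMNS = {
    "cl_invivo": "mL/min/kg",
    "vdss": "mL/kg",
    "clint": "uL/min/mg",
    "pka_acid": "",
    "pka_base": "",
    "fu": "fraction",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardizes to nothing."""

    def __init__(self, smiles: str, compound_id: str | None = None, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        self.compound_id = compound_id
        ctx = f" (compound {compound_id})" if compound_id else ""
        super().__init__(f"{reason}: {smiles!r}{ctx}")


@dataclass
class CompoundRecord:
    """One molecule with raw and standardized structure and optional measurements.

    ``measured`` keys: cl_invivo [mL/min/kg], vdss [mL/kg], clint
    [uL/min/mg protein], pka_acid, pka_base, fu [fraction in (0, 1]].
    """

    compound_id: str
    smiles_raw: str
    smiles_std: str = ""
    measured: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.smiles_std:
            self.smiles_std = standardize_smiles(self.smiles_raw, compound_id=self.compound_id)
        for key, value in self.measured.items():
            if key not in MEASURED_COLUMNS:
                raise ValueError(f"unknown measured parameter {key!r} on {self.compound_id}")
            if key == "fu" and not (0.0 < value <= 1.0):
                raise ValueError(f"fu must lie in (0, 1], got {value} for {self.compound_id}")
            if key in ("cl_invivo", "vdss", "clint") and value <= 0:
                raise ValueError(f"{key} must be > 0, got {value} for {self.compound_id}")

    def has(self, key: str) -> bool:
        return key in self.measured and np.isfinite(self.measured[key])


@dataclass
class FeatureVector:
    """A molecular representation: fingerprint, descriptor panel, or graph."""

    kind: str  # fingerprint | descriptors | graph
    fingerprint: np.ndarray | None = None  # uint8, length 1024
    descriptors: pd.Series | None = None  # named, DESCRIPTOR_NAMES order
    graph: tuple | None = None  # (atom_features, bond_features, pair_indices)


_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()
_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


def _mol_from_smiles(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, compound_id)
    return mol


def standardize_smiles(smiles_raw: str, compound_id: str | None = None) -> str:
    """Canonical SMILES of the largest fragment after salt stripping.

    Cleanup, largest-fragment (salt/solvent) stripping by heavy-atom count
    (ties by molecular weight, then lexicographic canonical SMILES), and
    charge neutralization where chemically valid. Stereochemistry present in
    the input is retained. Idempotent.
    """
    mol = _mol_from_smiles(smiles_raw, compound_id)
    mol = rdMolStandardize.Cleanup(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles_raw, compound_id, "empty structure after standardization")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(
            frags,
            key=lambda m: (m.GetNumHeavyAtoms(), MolWt(m), Chem.MolToSmiles(m)),
        )
    mol = _uncharger.uncharge(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles_raw, compound_id, "empty structure after standardization")
    return Chem.MolToSmiles(mol)


def featurize(smiles_std: str, kind: str = "fingerprint") -> FeatureVector:
    """Turn a standardized SMILES into one of the three representations.

    ``fingerprint``: Morgan radius 2 hashed to 1024 bits (uint8 0/1 array).
    ``descriptors``: the full named RDKit descriptor panel in registry order;
    non-finite values are left as produced (imputation is a modeling-time
    concern so the training-set median can be used).
    ``graph``: (atom_features, bond_features, pair_indices) where atom
    features are (atomic number, degree, formal charge, is_aromatic),
    bond features are (bond order, is_aromatic) and pair_indices is an
    (n_bonds, 2) integer array of endpoint atom indices.
    """
    mol = _mol_from_smiles(smiles_std)
    if kind == "fingerprint":
        fp = _fp_generator.GetFingerprintAsNumPy(mol).astype(np.uint8)
        return FeatureVector(kind=kind, fingerprint=fp)
    if kind == "descriptors":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values = Descriptors.CalcMolDescriptors(mol)
        series = pd.Series({name: float(values[name]) for name in DESCRIPTOR_NAMES})
        return FeatureVector(kind=kind, descriptors=series)
    if kind == "graph":
        atoms = np.array(
            [
                (a.GetAtomicNum(), a.GetDegree(), a.GetFormalCharge(), int(a.GetIsAromatic()))
                for a in mol.GetAtoms()
            ],
            dtype=np.int64,
        )
        bonds = np.array(
            [(b.GetBondTypeAsDouble(), int(b.GetIsAromatic())) for b in mol.GetBonds()],
            dtype=np.float64,
        ).reshape(-1, 2)
        pairs = np.array(
            [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()],
            dtype=np.int64,
        ).reshape(-1, 2)
        return FeatureVector(kind=kind, graph=(atoms, bonds, pairs))
    raise ValueError(f"unknown representation kind {kind!r}")


def compute_logp(smiles_std: str) -> float:
    """Crippen atom-contribution logP."""
    return float(Crippen.MolLogP(_mol_from_smiles(smiles_std)))


def compute_mw(smiles_std: str) -> float:
    """Average molecular weight in g/mol, implicit hydrogens included."""
    return float(MolWt(_mol_from_smiles(smiles_std)))


def count_halogens(smiles_std: str) -> int:
    """Number of F, Cl, Br and I atoms."""
    mol = _mol_from_smiles(smiles_std)
    return sum(1 for atom in mol.GetAtoms() if atom.GetSymbol() in _HALOGENS)


def count_aromatic_rings(smiles_std: str) -> int:
    mol = _mol_from_smiles(smiles_std)
    ring_info = mol.GetRingInfo()
    n = 0
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            n += 1
    return n


def tanimoto_similarity(a: FeatureVector | np.ndarray, b: FeatureVector | np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two 1024-bit fingerprints."""
    fa = a.fingerprint if isinstance(a, FeatureVector) else np.asarray(a)
    fb = b.fingerprint if isinstance(b, FeatureVector) else np.asarray(b)
    if fa is None or fb is None or fa.shape != (FINGERPRINT_BITS,) or fb.shape != (FINGERPRINT_BITS,):
        raise ValueError(f"both fingerprints must have length {FINGERPRINT_BITS}")
    fa = fa.astype(bool)
    fb = fb.astype(bool)
    union = int(np.sum(fa | fb))
    if union == 0:
        warnings.warn("both fingerprints are all-zero; Tanimoto defined as 0")
        return 0.0
    return float(np.sum(fa & fb) / union)


# ---------------------------------------------------------------------------
# tabular I/O

def read_compound_csv(path) -> list[CompoundRecord]:
    """Read a compound table (compound_id, smiles, optional measured columns)."""
    df = pd.read_csv(path)
    if "compound_id" not in df.columns or "smiles" not in df.columns:
        raise ValueError("compound CSV requires 'compound_id' and 'smiles' columns")
    records = []
    for _, row in df.iterrows():
        measured = {
            key: float(row[key])
            for key in MEASURED_COLUMNS
            if key in df.columns and pd.notna(row[key])
        }
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                smiles_raw=str(row["smiles"]),
                smiles_std=str(row["smiles_std"]) if "smiles_std" in df.columns and pd.notna(row.get("smiles_std")) else "",
                measured=measured,
            )
        )
    return records


def read_compound_sdf(path) -> list[CompoundRecord]:
    """Read structures from an SDF file; the molecule title becomes the id."""
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"skipping unparseable SDF record #{i}")
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"SDF{i:04d}"
        smiles = Chem.MolToSmiles(mol)
        records.append(CompoundRecord(compound_id=cid, smiles_raw=smiles))
    return records


def compounds_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"compound_id": rec.compound_id, "smiles": rec.smiles_raw, "smiles_std": rec.smiles_std}
        row.update(rec.measured)
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(records: Sequence[CompoundRecord], kind: str) -> pd.DataFrame:
    """Feature matrix indexed by compound id.

    Fingerprints become integer 0/1 columns fp_0000..fp_1023; descriptors
    keep their registry names.
    """
    if kind == "fingerprint":
        data = np.stack([featurize(r.smiles_std, "fingerprint").fingerprint for r in records])
        cols = [f"fp_{i:04d}" for i in range(FINGERPRINT_BITS)]
        return pd.DataFrame(data, index=[r.compound_id for r in records], columns=cols)
    if kind == "descriptors":
        rows = [featurize(r.smiles_std, "descriptors").descriptors for r in records]
        return pd.DataFrame(rows, index=[r.compound_id for r in records])
    raise ValueError(f"no tabular form for representation kind {kind!r}")
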