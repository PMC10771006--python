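"""Molecule standardization and training-set assembly.

The cleaning pipeline mirrors the three-step preparation used when curating
drug / non-drug training tables:

1. salts are converted to the parent acid or base (counter-ion stripping plus
   charge neutralization where a neutral parent exists),
2. mixtures and inorganic substances are removed,
3. SMILES are canonicalized and duplicates dropped.

Identity everywhere in this package is equality of canonical SMILES produced
by :func:`standardize`; one fixed canonicalization routine (RDKit's default
isomeric canonical SMILES) is used for the whole package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import SaltRemover
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: reasons a record can be rejected
REJECT_UNPARSEABLE = "unparseable"
REJECT_MIXTURE = "mixture"
REJECT_INORGANIC = "inorganic"

FIX_SALT_STRIPPED = "salt_stripped"
FIX_NEUTRALIZED = "neutralized"

_SALT_REMOVER = SaltRemover.SaltRemover()  # RDKit's published default salt list
_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass(frozen=True)
class RawRecord:
    """An input molecule as read from a SMI/CSV table."""

    smiles: str
    label: Optional[int] = None  # 1 = drug, 0 = non-drug
    source: str = ""

    def __post_init__(self) -> None:
        if not self.smiles or not self.smiles.strip():
            raise ValueError("smiles must be non-empty text")


@dataclass(frozen=True)
class StandardizedMolecule:
    """A cleaned, canonical, single-fragment organic structure."""

    canonical_smiles: str
    label: Optional[int] = None
    source: str = ""
    applied_fixes: tuple = ()

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass(frozen=True)
class Rejection:
    """A record that failed standardization, with the reason why."""

    smiles: str
    reason: str
    label: Optional[int] = None
    source: str = ""


@dataclass
class LabeledDataset:
    """A balanced (or deliberately imbalanced) labeled training table."""

    records: list  # of StandardizedMolecule, all labeled
    replicate_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        smiles = [r.canonical_smiles for r in self.records]
        if len(set(smiles)) != len(smiles):
            raise ValueError("duplicate canonical_smiles in dataset")
        if any(r.label is None for r in self.records):
            raise ValueError("every record must carry a label")

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def standardize(
    smiles: str,
    label: Optional[int] = None,
    source: str = "",
) -> Union[StandardizedMolecule, Rejection]:
    """Standardize one SMILES string.

    Counter-ions on the default salt list are stripped; records that remain
    multi-fragment afterwards are mixtures and rejected rather than reduced to
    their largest fragment.  Protonation states with a neutral parent are
    neutralized; permanent charges (e.g. quaternary ammonium) are kept.
    Structures without a carbon atom are rejected as inorganic.

    Returns a :class:`StandardizedMolecule` on success, else a
    :class:`Rejection` with reason ``unparseable``, ``mixture`` or
    ``inorganic``.
    """
    if not smiles or not smiles.strip():
        return Rejection(smiles, REJECT_UNPARSEABLE, label, source)
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        return Rejection(smiles, REJECT_UNPARSEABLE, label, source)

    fixes = []
    n_frags_in = len(Chem.GetMolFrags(mol))
    if n_frags_in > 1:
        stripped = _SALT_REMOVER.StripMol(mol, dontRemoveEverything=True)
        if stripped.GetNumAtoms() == 0:
            stripped = mol
        if len(Chem.GetMolFrags(stripped)) > 1:
            return Rejection(smiles, REJECT_MIXTURE, label, source)
        if stripped.GetNumAtoms() < mol.GetNumAtoms():
            fixes.append(FIX_SALT_STRIPPED)
        mol = stripped

    if not _has_carbon(mol):
        return Rejection(smiles, REJECT_INORGANIC, label, source)

    before = Chem.MolToSmiles(mol)
    mol = _UNCHARGER.uncharge(mol)
    canonical = Chem.MolToSmiles(mol)
    if canonical != before:
        fixes.append(FIX_NEUTRALIZED)

    return StandardizedMolecule(canonical, label, source, tuple(fixes))


def deduplicate(records: Sequence[StandardizedMolecule]) -> list:
    """Drop repeat canonical structures, keeping the first occurrence.

    Cross-class duplicates (same structure labeled both drug and non-drug)
    keep the drug (label 1) record: approved drugs are curated ground truth,
    while non-drug sets are sampled and may contain drugs by chance.  Such
    collisions are logged.
    """
    by_smiles: dict = {}
    order: list = []
    for rec in records:
        key = rec.canonical_smiles
        if key not in by_smiles:
            by_smiles[key] = rec
            order.append(key)
        else:
            kept = by_smiles[key]
            if kept.label == 0 and rec.label == 1:
                logger.info(
                    "cross-class duplicate %s: keeping drug record over non-drug", key
                )
                by_smiles[key] = rec
    return [by_smiles[k] for k in order]


def assemble_dataset(
    positives: Sequence[StandardizedMolecule],
    negatives: Sequence[StandardizedMolecule],
    n_negative: int,
    replicate_id: int = 0,
    seed: int = 0,
) -> LabeledDataset:
    """Down-sample negatives to build one balanced training replicate.

    All positives are retained; exactly ``n_negative`` negatives are drawn
    without replacement.  The draw is seeded by ``seed XOR replicate_id`` so
    that replicate 0, 1, 2 of the same seed give three parallel down-samples,
    each reproducible.
    """
    if n_negative > len(negatives):
        raise ValueError(
            f"n_negative={n_negative} exceeds available negatives ({len(negatives)})"
        )
    rng = np.random.default_rng(seed ^ replicate_id)
    idx = rng.choice(len(negatives), size=n_negative, replace=False)
    pos = [
        StandardizedMolecule(r.canonical_smiles, 1, r.source, r.applied_fixes)
        for r in positives
    ]
    neg = [
        StandardizedMolecule(
            negatives[i].canonical_smiles, 0, negatives[i].source,
            negatives[i].applied_fixes,
        )
        for i in sorted(idx)
    ]
    return LabeledDataset(records=pos + neg, replicate_id=replicate_id, seed=seed)


# ---------------------------------------------------------------------------
# I/O


def read_molecule_table(path: Union[str, Path]) -> list:
    """Read a SMI (one SMILES [+ optional id] per line) or CSV molecule table.

    CSV must have a ``smiles`` column; ``label`` and ``source`` are optional.
    Returns a list of :class:`RawRecord`.
    """
    path = Path(path)
    records = []
    if path.suffix.lower() in {".smi", ".txt"}:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            name = parts[1] if len(parts) > 1 else ""
            records.append(RawRecord(smiles=parts[0], source=name))
    else:
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path}: CSV needs a 'smiles' column")
        for _, row in df.iterrows():
            label = row.get("label")
            if pd.isna(label):
                label = None
            elif not isinstance(label, (int, np.integer)):
                key = str(label).strip().lower()
                mapping = {"drug": 1, "non-drug": 0, "nondrug": 0}
                label = mapping[key] if key in mapping else int(float(key))
            records.append(
                RawRecord(
                    smiles=str(row["smiles"]),
                    label=None if label is None else int(label),
                    source=str(row.get("source", "") or ""),
                )
            )
    return records


def standardize_table(records: Iterable[RawRecord]) -> pd.DataFrame:
    """Standardize a batch, reporting every record (accepted or rejected)."""
    rows = []
    for rec in records:
        out = standardize(rec.smiles, rec.label, rec.source)
        if isinstance(out, StandardizedMolecule):
            rows.append(
                dict(
                    smiles_in=rec.smiles,
                    canonical_smiles=out.canonical_smiles,
                    status="accepted",
                    reason="",
                    applied_fixes=";".join(out.applied_fixes),
                    label=rec.label,
                    source=rec.source,
                )
            )
        else:
            rows.append(
                dict(
                    smiles_in=rec.smiles,
                    canonical_smiles="",
                    status="rejected",
                    reason=out.reason,
                    applied_fixes="",
                    label=rec.label,
                    source=rec.source,
                )
            )
    return pd.DataFrame(rows)
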