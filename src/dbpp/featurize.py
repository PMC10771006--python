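"""Molecular representations: physicochemical profile, 200-descriptor vector,
five fingerprints, and dataset-diversity statistics (Tanimoto, Murcko).

All featurizers are pure functions of the canonical SMILES: the same input
always yields the same output, with no hidden state.  Donor/acceptor and
rotatable-bond counts use Lipinski-style definitions (amide C–N bonds
non-rotatable), matching the definitional family of the weighted-QED
publication.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chemprep import StandardizedMolecule

PHYSCHEM_NAMES = ("mw", "logp", "tpsa", "hba", "hbd", "nrot")

FINGERPRINT_KINDS = ("MACCS", "Morgan", "AtomPairs", "RDKFingerprint", "TopoTorsion")
FINGERPRINT_NBITS = {
    "MACCS": 166,
    "Morgan": 2048,
    "AtomPairs": 2048,
    "RDKFingerprint": 2048,
    "TopoTorsion": 2048,
}
MORGAN_RADIUS = 2  # ECFP4-equivalent


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, StandardizedMolecule):
        mol = mol.mol()
    elif isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
    if mol is None:
        raise ValueError("molecule could not be parsed")
    return mol


@dataclass(frozen=True)
class PhyschemProfile:
    """The six physicochemical values of the property-profile PC block.

    mw is in g/mol, tpsa in Å²; logp is the Crippen octanol–water estimate;
    hba/hbd/nrot are Lipinski-style counts.
    """

    mw: float
    logp: float
    tpsa: float
    hba: int
    hbd: int
    nrot: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mw, self.logp, self.tpsa, self.hba, self.hbd, self.nrot],
            dtype=float,
        )


def physchem_profile(mol) -> PhyschemProfile:
    """Compute the 6-value physicochemical profile from topology only."""
    m = _as_mol(mol)
    return PhyschemProfile(
        mw=Descriptors.MolWt(m),
        logp=Descriptors.MolLogP(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
        hba=Lipinski.NumHAcceptors(m),
        hbd=Lipinski.NumHDonors(m),
        nrot=Lipinski.NumRotatableBonds(m),
    )


def physchem_matrix(mols: Sequence) -> np.ndarray:
    """Stack physchem profiles into an (n, 6) array in PHYSCHEM_NAMES order."""
    return np.vstack([physchem_profile(m).as_array() for m in mols])


# ---------------------------------------------------------------------------
# 200-descriptor vector

_DESCRIPTOR_NAMES: Optional[Tuple[str, ...]] = None


def descriptor_names() -> Tuple[str, ...]:
    """The pinned, ordered manifest of the 200 descriptor names."""
    global _DESCRIPTOR_NAMES
    if _DESCRIPTOR_NAMES is None:
        text = resources.files("dbpp.data").joinpath("descriptors_200.txt").read_text()
        names = tuple(line.strip() for line in text.splitlines() if line.strip())
        if len(names) != 200:
            raise RuntimeError(f"descriptor manifest has {len(names)} names, not 200")
        _DESCRIPTOR_NAMES = names
    return _DESCRIPTOR_NAMES


_DESC_FUNCS: Optional[Dict[str, callable]] = None


def _descriptor_functions() -> Dict[str, callable]:
    global _DESC_FUNCS
    if _DESC_FUNCS is None:
        available = dict(Descriptors._descList)
        funcs = {}
        for name in descriptor_names():
            if name not in available:
                raise RuntimeError(f"descriptor {name!r} not available in RDKit")
            funcs[name] = available[name]
        _DESC_FUNCS = funcs
    return _DESC_FUNCS


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: Tuple[str, ...]
    normalized: bool = False


def descriptor_vector(mol, scaler=None) -> DescriptorVector:
    """Compute the length-200 descriptor vector.

    With a fitted ``scaler`` (see :func:`fit_descriptor_scaler`), values are
    z-scored against the training distribution; zero-variance training
    features map to 0.  A non-finite descriptor value raises, naming the
    offending descriptor.
    """
    m = _as_mol(mol)
    names = descriptor_names()
    funcs = _descriptor_functions()
    values = np.empty(len(names), dtype=float)
    for i, name in enumerate(names):
        try:
            values[i] = funcs[name](m)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"descriptor {name!r} failed: {exc}") from exc
        if not np.isfinite(values[i]):
            raise ValueError(f"descriptor {name!r} is non-finite for this molecule")
    if scaler is not None:
        values = scaler.transform(values[None, :])[0]
        return DescriptorVector(values, names, normalized=True)
    return DescriptorVector(values, names, normalized=False)


def descriptor_matrix(mols: Sequence, scaler=None) -> np.ndarray:
    return np.vstack([descriptor_vector(m, scaler=scaler).values for m in mols])


def fit_descriptor_scaler(train_matrix: np.ndarray):
    """Fit a z-score scaler on training descriptors only.

    Zero-variance features are mapped to 0 at transform time (sklearn's
    StandardScaler leaves them centered at 0 by construction).
    """
    from sklearn.preprocessing import StandardScaler

    scaler = StandardScaler()
    scaler.fit(np.asarray(train_matrix, dtype=float))
    return scaler


# ---------------------------------------------------------------------------
# Fingerprints


@dataclass
class Fingerprint:
    kind: str
    bits: np.ndarray  # uint8 0/1

    @property
    def nbits(self) -> int:
        return self.bits.size

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def _fp_object(m: Chem.Mol, kind: str):
    if kind == "MACCS":
        return rdMolDescriptors.GetMACCSKeysFingerprint(m)
    if kind == "Morgan":
        return AllChem.GetMorganFingerprintAsBitVect(m, MORGAN_RADIUS, nBits=2048)
    if kind == "AtomPairs":
        return rdMolDescriptors.GetHashedAtomPairFingerprintAsBitVect(m, nBits=2048)
    if kind == "RDKFingerprint":
        return Chem.RDKFingerprint(m, fpSize=2048)
    if kind == "TopoTorsion":
        return rdMolDescriptors.GetHashedTopologicalTorsionFingerprintAsBitVect(
            m, nBits=2048
        )
    raise ValueError(f"unknown fingerprint kind {kind!r}; choose from {FINGERPRINT_KINDS}")


def fingerprint(mol, kind: str) -> Fingerprint:
    """One of the five binary fingerprints (MACCS 166 bits, others 2048)."""
    m = _as_mol(mol)
    fp = _fp_object(m, kind)
    arr = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    if kind == "MACCS":
        # RDKit's MACCS vector has a phantom bit 0; the published key set is 166
        arr = arr[1:]
    return Fingerprint(kind=kind, bits=arr)


# ---------------------------------------------------------------------------
# Dataset diversity


def tanimoto_stats(mols: Sequence) -> Tuple[np.ndarray, float]:
    """MACCS Tanimoto similarity matrix and its mean off-diagonal similarity.

    The mean is over the upper triangle excluding the unit diagonal.
    """
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules")
    fps = [_fp_object(_as_mol(m), "MACCS") for m in mols]
    n = len(fps)
    sim = np.ones((n, n), dtype=float)
    for i in range(n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        for j, s in enumerate(row, start=i + 1):
            sim[i, j] = sim[j, i] = s
    mean = float(sim[np.triu_indices(n, k=1)].mean())
    return sim, mean


@dataclass
class ScaffoldSummary:
    n_molecules: int
    n_scaffolds: int
    scaffold_counts: Dict[str, int]
    acyclic_count: int

    def top_scaffolds(self, k: int = 150):
        """Most frequent scaffolds first — the 'molecular cloud' table."""
        return sorted(self.scaffold_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def molecules_per_scaffold(self) -> Dict[int, int]:
        """Histogram: scaffold multiplicity -> number of scaffolds."""
        hist: Dict[int, int] = {}
        for c in self.scaffold_counts.values():
            hist[c] = hist.get(c, 0) + 1
        return hist


def murcko_summary(mols: Sequence) -> ScaffoldSummary:
    """Murcko scaffold census: ring systems + linkers, side chains removed.

    Acyclic molecules have an empty scaffold and are counted separately.
    """
    counts: Dict[str, int] = {}
    acyclic = 0
    n = 0
    for m in mols:
        n += 1
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(
            mol=_as_mol(m), includeChirality=False
        )
        if scaffold == "":
            acyclic += 1
        else:
            counts[scaffold] = counts.get(scaffold, 0) + 1
    return ScaffoldSummary(
        n_molecules=n,
        n_scaffolds=len(counts),
        scaffold_counts=counts,
        acyclic_count=acyclic,
    )
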