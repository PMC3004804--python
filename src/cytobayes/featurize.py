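"""Circular-fingerprint and descriptor featurization.

Molecules are encoded as sparse sets of hashed circular-fingerprint
identifiers plus a small vector of physicochemical descriptors. The
default scheme is a functional-class circular fingerprint of diameter 6
(Morgan radius 3 over pharmacophoric atom invariants) with unfolded
hashed ids, together with a logP estimate, molecular weight, H-bond
donor/acceptor counts, rotatable bonds, and fractional polar surface
area. Presence/absence only — no counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

from .data_model import MoleculeRecord

DEFAULT_DESCRIPTORS = ("AlogP", "MW", "HBD", "HBA", "RotB", "fPSA")


@dataclass(frozen=True)
class FeaturizerConfig:
    """Pins the featurization scheme so results are reproducible.

    radius 3 means neighbourhood diameter 6; ``functional`` invariants
    abstract atoms to pharmacophoric roles (donor, acceptor, aromatic,
    halogen, basic, acidic) before hashing, ``connectivity`` uses plain
    element/connectivity invariants. ``fold_size`` of None keeps the raw
    hashed identifier space (the naive Bayes learner copes with sparse
    unbounded vocabularies); when set it must be a power of two >= 1024.
    """

    radius: int = 3
    atom_invariants: str = "functional"
    fold_size: int | None = None
    descriptor_list: tuple[str, ...] = DEFAULT_DESCRIPTORS

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.atom_invariants not in {"functional", "connectivity"}:
            raise ValueError(f"unknown atom_invariants {self.atom_invariants!r}")
        if self.fold_size is not None:
            n = self.fold_size
            if n < 1024 or n & (n - 1):
                raise ValueError("fold_size must be a power of two >= 1024")


class FeaturizationError(ValueError):
    """A molecule could not be parsed or featurized."""


def _generator(config: FeaturizerConfig):
    kwargs = {"radius": config.radius, "includeChirality": False}
    if config.atom_invariants == "functional":
        kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    return rdFingerprintGenerator.GetMorganGenerator(**kwargs)


def _descriptors(mol: Chem.Mol, names: Sequence[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for name in names:
        if name == "AlogP":
            out[name] = Crippen.MolLogP(mol)
        elif name == "MW":
            out[name] = Descriptors.MolWt(mol)
        elif name == "HBD":
            out[name] = float(Lipinski.NumHDonors(mol))
        elif name == "HBA":
            out[name] = float(Lipinski.NumHAcceptors(mol))
        elif name == "RotB":
            out[name] = float(Lipinski.NumRotatableBonds(mol))
        elif name == "fPSA":
            # polar fraction of the Labute approximate surface area:
            # N/O atom contributions over the whole-molecule surface
            contribs, h_contrib = rdMolDescriptors._CalcLabuteASAContribs(mol)
            contribs = list(contribs)
            total = sum(contribs) + h_contrib
            polar = sum(
                c for atom, c in zip(mol.GetAtoms(), contribs)
                if atom.GetAtomicNum() in (7, 8)
            )
            out[name] = polar / total if total > 0 else 0.0
        else:
            raise ValueError(f"unknown descriptor {name!r}")
    return out


def featurize_molecule(
    smiles: str,
    config: FeaturizerConfig | None = None,
    mol_id: str = "",
) -> MoleculeRecord:
    """Featurize one SMILES into a :class:`MoleculeRecord`.

    Deterministic for a fixed config and toolkit version, and invariant
    to atom ordering of the input SMILES (rdkit canonicalizes internally
    before hashing environments).
    """
    config = config or FeaturizerConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    # sparse count fingerprint keys are the raw unsigned environment hashes;
    # presence/absence only, so the counts themselves are discarded
    fp = _generator(config).GetSparseCountFingerprint(mol)
    features = {int(b) for b in fp.GetNonzeroElements()}
    if config.fold_size is not None:
        features = {b % config.fold_size for b in features}
    return MoleculeRecord(
        id=mol_id or smiles,
        smiles=smiles,
        features=frozenset(features),
        descriptors=_descriptors(mol, config.descriptor_list),
    )


@dataclass
class BatchResult:
    records: list[MoleculeRecord] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)


def featurize_batch(
    smiles_by_id: dict[str, str], config: FeaturizerConfig | None = None
) -> BatchResult:
    """Featurize many molecules; per-molecule failures are collected, not fatal."""
    result = BatchResult()
    for cid, smi in smiles_by_id.items():
        try:
            result.records.append(featurize_molecule(smi, config, mol_id=cid))
        except FeaturizationError as exc:
            result.errors[cid] = str(exc)
    return result


def featurize_sdf(path: str | Path, config: FeaturizerConfig | None = None) -> BatchResult:
    """Featurize molecules from an SDF file; ids from the title line or _Name."""
    result = BatchResult()
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        name = f"sdf{i + 1}"
        if mol is None:
            result.errors[name] = "unparsable SDF record"
            continue
        if mol.HasProp("_Name") and mol.GetProp("_Name"):
            name = mol.GetProp("_Name")
        result.records.append(
            featurize_molecule(Chem.MolToSmiles(mol), config, mol_id=name)
        )
    return result


def tanimoto(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| between two binary feature sets.

    Two empty sets score 0 by convention (nothing in common is knowable);
    a similarity of 1 does not necessarily imply identical compounds.
    """
    if not a and not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def write_feature_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write the portable feature table: id, space-joined feature ids, descriptors.

    Simulated and real molecules share this format, so structure-free
    workflows can bypass rdkit entirely.
    """
    records = list(records)
    names: list[str] = []
    for r in records:
        for k in r.descriptors:
            if k not in names:
                names.append(k)
    with Path(path).open("w") as fh:
        fh.write("compound_id\tfeatures\t" + "\t".join(names) + "\n")
        for r in records:
            feats = " ".join(str(f) for f in sorted(r.features))
            descs = "\t".join(
                repr(r.descriptors[n]) if n in r.descriptors else "" for n in names
            )
            fh.write(f"{r.id}\t{feats}\t{descs}\n")


def read_feature_table(path: str | Path) -> list[MoleculeRecord]:
    records = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[2:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cid, feats = parts[0], parts[1]
            descs = {
                n: float(v) for n, v in zip(names, parts[2:]) if v != ""
            }
            records.append(
                MoleculeRecord(
                    id=cid,
                    features=frozenset(int(f) for f in feats.split()) if feats else frozenset(),
                    descriptors=descs,
                )
            )
    return records
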