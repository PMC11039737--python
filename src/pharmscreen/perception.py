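"""SMARTS-based pharmacophoric feature perception.

Derives typed 3D feature points (aromatic / hydrophobic centers, H-bond
donors and acceptors, metal ligators) from a 3D small molecule.  The rule
set is a documented, overridable approximation: commercial modeling suites
each use their own proprietary typing, so quantitative fitting scores are
not expected to transfer between implementations.  Quantitative pipeline
guarantees in this package therefore rest on synthetic point-feature
inputs; perception is validated qualitatively.

Molecules are RDKit ``Mol`` objects carrying one or more 3D conformers —
the field-standard container for SDF records and embedded SMILES.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import List, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .features import FeatureSet, PerceivedFeature
from .model import FeatureKind

__all__ = [
    "PerceptionRule",
    "PerceptionRules",
    "default_rules",
    "load_rules",
    "perceive",
    "read_molecules",
    "mol_from_smiles",
    "fixture_drugs",
    "PerceptionError",
]

#: merge radius for co-located features of different kinds, Å
MERGE_RADIUS = 0.5

#: default conformer count when embedding line-notation input
DEFAULT_N_CONFS = 10

#: fixed seed for 3D embedding of packaged fixtures
EMBED_SEED = 42


class PerceptionError(ValueError):
    pass


@dataclass(frozen=True)
class PerceptionRule:
    """One substructure pattern: kind, SMARTS, and placement.

    placement ∈ {"atom" (first matched atom), "centroid" (centroid of all
    matched atoms), "ring_centroid" (alias of centroid, for ring patterns)}.
    """

    kind: FeatureKind
    smarts: str
    placement: str = "atom"

    def __post_init__(self):
        if self.placement not in ("atom", "centroid", "ring_centroid"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise ValueError(f"SMARTS does not parse: {self.smarts!r}")


@dataclass
class PerceptionRules:
    rules: List[PerceptionRule]

    def __post_init__(self):
        kinds = {r.kind for r in self.rules}
        missing = set(FeatureKind) - kinds
        if missing:
            raise ValueError(f"no pattern for kinds: {sorted(k.value for k in missing)}")

    def by_kind(self, kind: FeatureKind):
        return [r for r in self.rules if r.kind == kind]


_DEFAULT_RULES = [
    # aromatic ring centers
    (FeatureKind.Aro, "a1aaaaa1", "ring_centroid"),
    (FeatureKind.Aro, "a1aaaa1", "ring_centroid"),
    # hydrophobes: small aliphatic carbocycles (incl. cyclopropyl),
    # halogens on carbon, and chains of >=2 non-polar sp3 carbons
    (FeatureKind.Hyd, "[CX4]1[CX4][CX4]1", "centroid"),
    (FeatureKind.Hyd, "[CX4]1[CX4][CX4][CX4]1", "centroid"),
    (FeatureKind.Hyd, "[CX4]1[CX4][CX4][CX4][CX4]1", "centroid"),
    (FeatureKind.Hyd, "[CX4]1[CX4][CX4][CX4][CX4][CX4]1", "centroid"),
    (FeatureKind.Hyd, "[F,Cl,Br,I;$(*[#6])]", "atom"),
    (FeatureKind.Hyd, "[CX4;!$(C[!#6;!#1])][CX4;!$(C[!#6;!#1])]", "centroid"),
    # H-bond donors: N-H, O-H
    (FeatureKind.Don, "[#7;!H0]", "atom"),
    (FeatureKind.Don, "[#8;!H0]", "atom"),
    # H-bond acceptors: O and N with an available lone pair,
    # excluding amide and sulfonamide N and pyrrole-type aromatic N
    (FeatureKind.Acc, "[OX2]", "atom"),
    (FeatureKind.Acc, "[OX1]", "atom"),
    (FeatureKind.Acc, "[nX2]", "atom"),
    (FeatureKind.Acc, "[NX3;!$(N[CX3]=[OX1]);!$(NS=O);!$(N=*);!$([N+])]", "atom"),
    (FeatureKind.Acc, "[NX1]", "atom"),
    (FeatureKind.Acc, "[NX2;$(N=C)]", "atom"),
    # metal ligators: carboxylic/carboxylate O, pyridine/imidazole-type N,
    # thiol(ate) S, phenol(ate) O
    (FeatureKind.ML, "[OX2H1;$(OC=O)]", "atom"),
    (FeatureKind.ML, "[OX1;$(O=C[OX2H1,OX1-])]", "atom"),
    (FeatureKind.ML, "[OX1-]", "atom"),
    (FeatureKind.ML, "[nX2]", "atom"),
    (FeatureKind.ML, "[SX2H1,SX1-]", "atom"),
    (FeatureKind.ML, "[OX2H1;$(Oc)]", "atom"),
]


def default_rules() -> PerceptionRules:
    """The built-in perception rule set (documented approximation)."""
    return PerceptionRules([PerceptionRule(k, s, p) for k, s, p in _DEFAULT_RULES])


def load_rules(path) -> PerceptionRules:
    """Load a rules file: JSON list of {kind, smarts, placement}."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return PerceptionRules(
        [PerceptionRule(FeatureKind(r["kind"]), r["smarts"], r.get("placement", "atom")) for r in doc]
    )


def _prepare(mol: Chem.Mol) -> Chem.Mol:
    """Sanitize and add explicit hydrogens (donor perception needs them)."""
    if mol is None:
        raise PerceptionError("molecule is None (unparseable input record)")
    mol = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as e:  # rdkit raises several sanitization error types
        raise PerceptionError(f"sanitization failed: {e}") from e
    if mol.GetNumConformers() > 0:
        mol = Chem.AddHs(mol, addCoords=True)
    else:
        mol = Chem.AddHs(mol)
    return mol


def perceive(mol: Chem.Mol, conformer: int = 0, rules: Optional[PerceptionRules] = None) -> FeatureSet:
    """Perceive pharmacophoric features on one conformer of *mol*.

    Matches of the same kind on the same atom set are deduplicated;
    features of different kinds within ``MERGE_RADIUS`` (0.5 Å) of each
    other are merged into one composite feature with the union of kinds.
    """
    rules = rules or default_rules()
    mol = _prepare(mol)
    if conformer >= mol.GetNumConformers():
        raise PerceptionError(f"molecule has no conformer {conformer}")
    conf = mol.GetConformer(conformer)
    coords = conf.GetPositions()

    raw = []  # (kind, atom tuple, position)
    seen = set()
    for rule in rules.rules:
        patt = Chem.MolFromSmarts(rule.smarts)
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            atoms = (match[0],) if rule.placement == "atom" else tuple(sorted(match))
            key = (rule.kind, frozenset(atoms))
            if key in seen:
                continue
            seen.add(key)
            pos = coords[list(atoms)].mean(axis=0)
            raw.append((rule.kind, atoms, pos))

    # deterministic order, then greedy merge of co-located features
    raw.sort(key=lambda t: (min(t[1]), t[0].value, t[1]))
    merged = []  # [set kinds, list positions, set atoms]
    for kind, atoms, pos in raw:
        placed = False
        for m in merged:
            if min(np.linalg.norm(pos - p) for p in m[1]) <= MERGE_RADIUS:
                m[0].add(kind)
                m[1].append(pos)
                m[2].update(atoms)
                placed = True
                break
        if not placed:
            merged.append([{kind}, [pos], set(atoms)])

    name = mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed"
    feats = [
        PerceivedFeature(frozenset(kinds), np.mean(positions, axis=0), tuple(sorted(atoms)))
        for kinds, positions, atoms in merged
    ]
    return FeatureSet(molecule_id=name, conformer=conformer, features=feats)


def mol_from_smiles(smiles: str, name: str = "", n_confs: int = DEFAULT_N_CONFS,
                    seed: int = EMBED_SEED) -> Chem.Mol:
    """Parse SMILES and embed ``n_confs`` 3D conformers (ETKDG, seeded)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise PerceptionError(f"SMILES does not parse: {smiles!r}")
    mol.SetProp("_Name", name or smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if mol.GetNumConformers() == 0:
        raise PerceptionError(f"3D embedding failed for {name or smiles}")
    return Chem.RemoveHs(mol)


def read_molecules(path, n_confs: int = DEFAULT_N_CONFS, seed: int = EMBED_SEED) -> list:
    """Read an SDF (V2000, 3D as-is) or SMILES file (embedded to 3D).

    SMILES files hold one record per line: ``SMILES [identifier]``.
    Unreadable records yield ``None`` placeholders so callers can report
    per-record errors without aborting a screen.
    """
    path = Path(path)
    mols = []
    if path.suffix.lower() in (".smi", ".smiles", ".txt"):
        for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            name = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            try:
                mols.append(mol_from_smiles(parts[0], name, n_confs=n_confs, seed=seed))
            except PerceptionError:
                mols.append(None)
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for mol in supplier:
            mols.append(mol)
    return mols


# Best ten screened drugs; SMILES from their standard structures.
FIXTURE_DRUG_SMILES = {
    "Trovafloxacin": "NC1C2CN(c3nc4c(cc3F)c(=O)c(C(=O)O)cn4-c3ccc(F)cc3F)CC12",
    "Vilazodone": "N#Cc1ccc2[nH]cc(CCCCN3CCN(c4ccc5cc(C(N)=O)oc5c4)CC3)c2c1",
    "Pitavastatin": "OC(=O)C[C@H](O)C[C@H](O)/C=C/c1c(-c2ccc(F)cc2)c2ccccc2nc1C1CC1",
    "Dasabuvir": "COc1c(cc(cc1-c1ccc2cc(NS(C)(=O)=O)ccc2c1)C(C)(C)C)N1C=CC(=O)NC1=O",
    "Ranolazine": "COc1ccccc1OCC(O)CN1CCN(CC(=O)Nc2c(C)cccc2C)CC1",
    "Acetophenazine": "CC(=O)c1ccc2Sc3ccccc3N(CCCN3CCN(CCO)CC3)c2c1",
    "Dasatinib": "Cc1nc(Nc2ncc(s2)C(=O)Nc2c(C)cccc2Cl)cc(n1)N1CCN(CCO)CC1",
    "Gefitinib": "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1",
    "Apixaban": "COc1ccc(cc1)n1nc(C(N)=O)c2CCN(c3ccc(cc3)N3CCCCC3=O)C(=O)c12",
    "Nefazodone": "CCc1nn(CCCN2CCN(c3cccc(Cl)c3)CC2)c(=O)n1CCOc1ccccc1",
}


@lru_cache(maxsize=1)
def _fixture_drugs_cached(n_confs: int, seed: int) -> tuple:
    return tuple(
        mol_from_smiles(smiles, name, n_confs=n_confs, seed=seed)
        for name, smiles in FIXTURE_DRUG_SMILES.items()
    )


def fixture_drugs(n_confs: int = 3, seed: int = EMBED_SEED) -> list:
    """The ten top-screened approved drugs, embedded to 3D with a fixed seed."""
    return list(_fixture_drugs_cached(n_confs, seed))
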