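"""Lipinski / Veber drug-likeness filtration.

The post-screening filtration stage: oral drug-likeness by Lipinski's rule
of five (MW <= 500 g/mol, logP <= 5, H-bond donors <= 5, acceptors <= 10;
pass with at most one violation, as in the original formulation) and
Veber's rules (rotatable bonds <= 10 and TPSA <= 140 Å², both inclusive).
Descriptors come from molecular connectivity only; logP is the Crippen
atom-contribution estimate (implementation-defined — different software
computes slightly different logP values, so the filter thresholds are
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DescriptorProfile",
    "compute_profile",
    "lipinski_pass",
    "veber_pass",
    "profile_table",
    "DruglikenessFilter",
]


@dataclass
class DescriptorProfile:
    """2D drug-likeness descriptors of one molecule."""

    molecule_id: str
    mw: float        # molecular weight, g/mol
    logp: float      # Crippen logP
    hbd: int         # H-bond donors (Lipinski count)
    hba: int         # H-bond acceptors (Lipinski count)
    rotb: int        # rotatable bonds
    tpsa: float      # topological polar surface area, Å²


def compute_profile(mol: Chem.Mol) -> DescriptorProfile:
    """Compute the descriptor profile from connectivity (2D, deterministic)."""
    if mol is None:
        raise ValueError("molecule is None (unparseable record)")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed"
    return DescriptorProfile(
        molecule_id=name,
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        rotb=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
    )


def lipinski_pass(p: DescriptorProfile, mw_max=500.0, logp_max=5.0, hbd_max=5,
                  hba_max=10, max_violations=1) -> Tuple[bool, List[str]]:
    """Rule-of-five check; pass iff at most ``max_violations`` violations."""
    violations = []
    if p.mw > mw_max:
        violations.append(f"MW {p.mw:.1f} > {mw_max:g}")
    if p.logp > logp_max:
        violations.append(f"logP {p.logp:.2f} > {logp_max:g}")
    if p.hbd > hbd_max:
        violations.append(f"HBD {p.hbd} > {hbd_max}")
    if p.hba > hba_max:
        violations.append(f"HBA {p.hba} > {hba_max}")
    return len(violations) <= max_violations, violations


def veber_pass(p: DescriptorProfile, rotb_max=10, tpsa_max=140.0) -> Tuple[bool, List[str]]:
    """Veber oral-bioavailability check; both bounds inclusive."""
    violations = []
    if p.rotb > rotb_max:
        violations.append(f"RotB {p.rotb} > {rotb_max}")
    if p.tpsa > tpsa_max:
        violations.append(f"TPSA {p.tpsa:.1f} > {tpsa_max:g}")
    return len(violations) == 0, violations


def profile_table(mols: Sequence[Chem.Mol], **thresholds) -> pd.DataFrame:
    """Descriptor + pass/fail table, one row per molecule (TSV-ready)."""
    filt = DruglikenessFilter(**thresholds)
    rows = []
    for mol in mols:
        p = compute_profile(mol)
        lp, _ = lipinski_pass(p, filt.mw_max, filt.logp_max, filt.hbd_max,
                              filt.hba_max, filt.max_lipinski_violations)
        vp, _ = veber_pass(p, filt.rotb_max, filt.tpsa_max)
        rows.append((p.molecule_id, round(p.mw, 2), round(p.logp, 2), p.hbd,
                     p.hba, p.rotb, round(p.tpsa, 2), int(lp), int(vp),
                     int(lp and vp)))
    return pd.DataFrame(rows, columns=[
        "molecule_id", "mw", "logp", "hbd", "hba", "rotb", "tpsa",
        "lipinski", "veber", "pass",
    ])


class DruglikenessFilter(TransformerMixin, BaseEstimator):
    """Drug-likeness filter in scikit-learn form.

    ``transform(X)`` keeps the molecules passing both Lipinski (with the
    configured violation tolerance) and Veber; ``predict(X)`` returns the
    0/1 pass vector.  All thresholds are parameters.
    """

    def __init__(self, mw_max=500.0, logp_max=5.0, hbd_max=5, hba_max=10,
                 max_lipinski_violations=1, rotb_max=10, tpsa_max=140.0):
        self.mw_max = mw_max
        self.logp_max = logp_max
        self.hbd_max = hbd_max
        self.hba_max = hba_max
        self.max_lipinski_violations = max_lipinski_violations
        self.rotb_max = rotb_max
        self.tpsa_max = tpsa_max

    def fit(self, X=None, y=None):
        return self

    def _passes(self, mol) -> bool:
        p = compute_profile(mol)
        lp, _ = lipinski_pass(p, self.mw_max, self.logp_max, self.hbd_max,
                              self.hba_max, self.max_lipinski_violations)
        vp, _ = veber_pass(p, self.rotb_max, self.tpsa_max)
        return lp and vp

    def predict(self, X):
        import numpy as np

        return np.array([int(self._passes(m)) for m in X])

    def transform(self, X):
        return [m for m in X if self._passes(m)]
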