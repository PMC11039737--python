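"""Consensus pharmacophore elucidation from an aligned ligand ensemble.

Given M feature sets sharing one coordinate frame (the aligned actives),
features recurring across ligands are clustered (greedy centroid linkage
within a tolerance radius, 1.15 Å by default) and clusters supported by
more than a threshold fraction of the ligands (50% by default) become
model features.  Highly conserved clusters (>= 90% of ligands by default)
are flagged essential, and ``min_match`` is set to the essential count —
the partial-match rule the screening stage then enforces.

Flexible alignment itself is out of scope: conformational search and
alignment optimization are proprietary, stochastic steps of the modeling
suite; this module requires pre-aligned inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .features import FeatureSet
from .model import (
    FeatureKind,
    OrExpr,
    KindLeaf,
    PharmacophoreFeature,
    PharmacophoreModel,
)

__all__ = ["ConsensusParams", "ConsensusError", "consensus_model", "ConsensusPharmacophore"]

_KIND_ORDER = [FeatureKind.Aro, FeatureKind.Hyd, FeatureKind.ML, FeatureKind.Acc, FeatureKind.Don]


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusParams:
    """Consensus knobs.

    threshold: fraction of ligands a cluster must exceed to become a
        feature (strict >; default 0.5).
    tolerance: complete-linkage clustering radius, Å (default 1.15).
    essential_threshold: support fraction at or above which a feature is
        flagged essential (default 0.9).
    radius_floor: minimum feature radius, Å (default 0.4, the smallest
        radius a model feature is given).
    """

    threshold: float = 0.5
    tolerance: float = 1.15
    essential_threshold: float = 0.9
    radius_floor: float = 0.4

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.essential_threshold < self.threshold:
            raise ValueError("essential_threshold must be >= threshold")


def _kinds_expr(kinds) -> OrExpr:
    leaves = tuple(KindLeaf(k) for k in _KIND_ORDER if k in kinds)
    return leaves[0] if len(leaves) == 1 else OrExpr(leaves)


def consensus_model(ensemble: Sequence[FeatureSet],
                    params: ConsensusParams = ConsensusParams(),
                    name: str = "consensus") -> PharmacophoreModel:
    """Derive a consensus model from >= 2 aligned feature sets.

    Clustering is greedy in deterministic order (ligand index, then
    feature index): a feature joins the first cluster whose running
    kind-intersection it overlaps, whose running centroid lies within
    ``tolerance``, and which holds no feature of the same ligand yet.
    Cluster center = mean position; expression = OR over the
    kind-intersection; radius = max(member deviation, radius_floor);
    essential iff support >= essential_threshold × M.
    """
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise ConsensusError("ensemble must contain at least 2 aligned feature sets")
    M = len(ensemble)

    clusters = []  # each: {kinds, positions [...], ligands set}
    for li, fs in enumerate(ensemble):
        for pf in fs.features:
            placed = False
            for c in clusters:
                if li in c["ligands"]:
                    continue
                if not (c["kinds"] & pf.kinds):
                    continue
                centroid = np.mean(c["positions"], axis=0)
                if np.linalg.norm(pf.position - centroid) <= params.tolerance:
                    c["kinds"] = c["kinds"] & pf.kinds
                    c["positions"].append(pf.position)
                    c["ligands"].add(li)
                    placed = True
                    break
            if not placed:
                clusters.append({
                    "kinds": frozenset(pf.kinds),
                    "positions": [pf.position],
                    "ligands": {li},
                })

    kept = [c for c in clusters if len(c["ligands"]) > params.threshold * M]
    if not kept:
        raise ConsensusError(
            f"no cluster exceeds the support threshold ({params.threshold:.0%} of {M} ligands)"
        )
    # order by support desc, then by first-appearance (stable: clusters were
    # created in deterministic order)
    kept.sort(key=lambda c: -len(c["ligands"]))

    feats = []
    supports = []
    for i, c in enumerate(kept, start=1):
        pts = np.array(c["positions"])
        center = pts.mean(axis=0)
        spread = float(np.linalg.norm(pts - center, axis=1).max()) if len(pts) > 1 else 0.0
        support = len(c["ligands"])
        feats.append(PharmacophoreFeature(
            id=f"F{i}",
            expr=_kinds_expr(c["kinds"]),
            center=center,
            radius=max(spread, params.radius_floor),
            essential=support >= params.essential_threshold * M,
        ))
        supports.append(support)

    n_essential = sum(f.essential for f in feats)
    model = PharmacophoreModel(
        features=feats,
        min_match=max(1, n_essential),
        name=name,
    )
    model.support = dict(zip((f.id for f in feats), supports))  # type: ignore[attr-defined]
    return model


class ConsensusPharmacophore(BaseEstimator):
    """Consensus model builder in scikit-learn form.

    ``fit(X)`` takes a sequence of aligned :class:`FeatureSet` objects and
    exposes the derived model as ``model_`` with per-feature ligand support
    in ``support_``.
    """

    def __init__(self, threshold=0.5, tolerance=1.15, essential_threshold=0.9,
                 radius_floor=0.4):
        self.threshold = threshold
        self.tolerance = tolerance
        self.essential_threshold = essential_threshold
        self.radius_floor = radius_floor

    def fit(self, X: Sequence[FeatureSet], y=None):
        params = ConsensusParams(self.threshold, self.tolerance,
                                 self.essential_threshold, self.radius_floor)
        self.model_ = consensus_model(X, params)
        self.support_ = dict(self.model_.support)
        self.n_ligands_ = len(list(X))
        return self

    def to_screener(self, **match_kwargs):
        """A :class:`~pharmscreen.matching.PharmacophoreScreener` over model_."""
        from .matching import PharmacophoreScreener

        return PharmacophoreScreener(model=self.model_, **match_kwargs).fit()
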