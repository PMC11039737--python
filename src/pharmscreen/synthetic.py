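"""Seeded synthetic actives/decoys benchmark generator.

The validation design this package targets screens 56 known actives and
207 presumed-inactive decoys whose chemical structures were never
published.  This module generates abstract point-feature stand-ins with
the statistical structure that validation assumes:

* actives — one typed point per model feature, positionally jittered
  (isotropic Gaussian), with the non-essential feature(s) stochastically
  dropped, under a random rigid motion;
* decoys — three configurable failure modes: ``type_scramble`` (correct
  geometry, feature types rearranged so the essential features cannot all
  be satisfied), ``geometry_inflate`` (correct types, all inter-feature
  distances scaled up), and ``feature_deficit`` (two or more essential
  features deleted).

Everything is driven by one integer seed and regenerates bit-identically
from the recorded provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .features import FeatureSet, PerceivedFeature
from .model import FeatureKind, PharmacophoreModel, expr_satisfied

__all__ = ["GeneratorParams", "SyntheticBenchmark", "synth_active", "synth_decoy",
           "make_benchmark", "synth_aligned_ensemble", "minimal_satisfying_kind_sets"]

DECOY_MODES = ("type_scramble", "geometry_inflate", "feature_deficit", "mixed")


@dataclass
class GeneratorParams:
    """Benchmark generation conditions.

    Defaults mirror the validation design being emulated: 56 actives and
    207 decoys; 0.2 Å positional jitter and 0.3 non-essential-feature
    dropout for actives; decoys drawn round-robin from the three failure
    modes with a 3x geometry inflation.
    """

    n_actives: int = 56
    n_decoys: int = 207
    jitter_sd: float = 0.2
    dropout_prob: float = 0.3
    decoy_mode: str = "mixed"
    inflate_factor: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not (0 <= self.dropout_prob <= 1):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.decoy_mode not in DECOY_MODES:
            raise ValueError(f"decoy_mode must be one of {DECOY_MODES}")
        if self.inflate_factor <= 1:
            raise ValueError("inflate_factor must be > 1")


@dataclass
class SyntheticBenchmark:
    """Labeled feature sets plus the provenance that regenerates them."""

    feature_sets: List[FeatureSet]
    labels: dict                      # molecule_id -> "active" | "decoy"
    provenance: dict = field(default_factory=dict)


def minimal_satisfying_kind_sets(expr) -> List[frozenset]:
    """All minimal kind sets satisfying a feature-type expression."""
    kinds = list(FeatureKind)
    satisfying = []
    for r in range(1, len(kinds) + 1):
        for combo in combinations(kinds, r):
            s = frozenset(combo)
            if expr_satisfied(expr, s) and not any(t < s for t in satisfying):
                satisfying.append(s)
    return satisfying


def _random_rigid(rng) -> Tuple[np.ndarray, np.ndarray]:
    rot = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-10.0, 10.0, size=3)
    return rot, t


def _sample_kinds(model: PharmacophoreModel, rng) -> list:
    """One minimal satisfying kind set per model feature."""
    out = []
    for f in model.features:
        options = minimal_satisfying_kind_sets(f.expr)
        out.append(options[rng.integers(len(options))])
    return out


def synth_active(model: PharmacophoreModel, params: GeneratorParams,
                 rng: np.random.Generator, mol_id: str = "active") -> FeatureSet:
    """One active-like feature set: jittered model points under rigid motion."""
    kinds = _sample_kinds(model, rng)
    noise = params.jitter_sd * rng.standard_normal((model.n_features, 3))
    keep = [
        f.essential or rng.random() >= params.dropout_prob
        for f in model.features
    ]
    rot, t = _random_rigid(rng)
    feats = [
        PerceivedFeature(kinds[i], rot @ (model.features[i].center + noise[i]) + t)
        for i in range(model.n_features)
        if keep[i]
    ]
    return FeatureSet(molecule_id=mol_id, features=feats)


def synth_decoy(model: PharmacophoreModel, params: GeneratorParams,
                rng: np.random.Generator, mol_id: str = "decoy",
                mode: Optional[str] = None) -> FeatureSet:
    """One decoy-like feature set guaranteed not to fit the model."""
    mode = mode or params.decoy_mode
    if mode == "mixed":
        mode = ("type_scramble", "geometry_inflate", "feature_deficit")[
            rng.integers(3)
        ]
    centers = model.centers()
    noise = params.jitter_sd * rng.standard_normal(centers.shape)
    rot, t = _random_rigid(rng)

    if mode == "type_scramble":
        # correct geometry; type layout leaves the aromatic/hydrophobic
        # essentials short-handed (only 2 such points) and removes every
        # metal ligator, so no essential-complete assignment can exist
        pool = [frozenset({FeatureKind.Aro}), frozenset({FeatureKind.Hyd})]
        polar = [frozenset({FeatureKind.Acc}), frozenset({FeatureKind.Don})]
        while len(pool) < model.n_features:
            pool.append(polar[rng.integers(2)])
        order = rng.permutation(model.n_features)
        feats = [
            PerceivedFeature(pool[order[i]], rot @ (centers[i] + noise[i]) + t)
            for i in range(model.n_features)
        ]
    elif mode == "geometry_inflate":
        kinds = _sample_kinds(model, rng)
        mean = centers.mean(axis=0)
        inflated = mean + params.inflate_factor * (centers - mean)
        feats = [
            PerceivedFeature(kinds[i], rot @ inflated[i] + t)
            for i in range(model.n_features)
        ]
    elif mode == "feature_deficit":
        kinds = _sample_kinds(model, rng)
        ess = [i for i, f in enumerate(model.features) if f.essential]
        drop = set(rng.choice(ess, size=2, replace=False))
        feats = [
            PerceivedFeature(kinds[i], rot @ (centers[i] + noise[i]) + t)
            for i in range(model.n_features)
            if i not in drop
        ]
    else:
        raise ValueError(f"unknown decoy mode {mode!r}")
    return FeatureSet(molecule_id=mol_id, features=feats)


def _expr_leaf_kinds(expr) -> frozenset:
    from .model import KindLeaf

    if isinstance(expr, KindLeaf):
        return frozenset({expr.kind})
    out = set()
    for t in expr.terms:
        out |= _expr_leaf_kinds(t)
    return frozenset(out)


def synth_aligned_ensemble(model: PharmacophoreModel, n_ligands: int = 12,
                           jitter_sd: float = 0.3, n_dropout: int = 5,
                           seed: int = 0) -> List[FeatureSet]:
    """Aligned actives ensemble for consensus derivation.

    Jittered copies of the model's feature points in one shared frame (no
    rigid motion — the ensemble emulates the output of flexible alignment).
    Each feature carries the union of kinds named in its expression; the
    non-essential features are omitted from the first ``n_dropout`` ligands,
    so their consensus support is ``n_ligands - n_dropout``.
    """
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_ligands):
        feats = [
            PerceivedFeature(
                _expr_leaf_kinds(f.expr),
                f.center + jitter_sd * rng.standard_normal(3),
            )
            for f in model.features
            if f.essential or i >= n_dropout
        ]
        sets.append(FeatureSet(molecule_id=f"ligand_{i:02d}", features=feats))
    return sets


def make_benchmark(model: PharmacophoreModel,
                   params: GeneratorParams = GeneratorParams()) -> SyntheticBenchmark:
    """A labeled benchmark of ``n_actives + n_decoys`` feature sets.

    Deterministic per seed: the same params regenerate bit-identical
    coordinates.  In ``mixed`` decoy mode the three failure modes are
    assigned round-robin (decoy index mod 3) so every mode is exercised.
    """
    rng = np.random.default_rng(params.seed)
    sets, labels = [], {}
    for i in range(params.n_actives):
        mid = f"active_{i:04d}"
        sets.append(synth_active(model, params, rng, mid))
        labels[mid] = "active"
    modes = ("type_scramble", "geometry_inflate", "feature_deficit")
    for i in range(params.n_decoys):
        mid = f"decoy_{i:04d}"
        mode = modes[i % 3] if params.decoy_mode == "mixed" else params.decoy_mode
        sets.append(synth_decoy(model, params, rng, mid, mode=mode))
        labels[mid] = "decoy"
    return SyntheticBenchmark(
        feature_sets=sets,
        labels=labels,
        provenance={"params": asdict(params), "model": model.name},
    )
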