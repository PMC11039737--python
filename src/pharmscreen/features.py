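"""Perceived-feature containers and their JSON-lines serialization.

A :class:`FeatureSet` is the abstraction the matcher consumes: the typed 3D
points (kind set + position) perceived on one conformer of one molecule,
decoupled from how they were obtained (SMARTS perception, or the synthetic
generator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .model import FeatureKind

__all__ = ["PerceivedFeature", "FeatureSet", "write_feature_sets", "read_feature_sets"]


@dataclass
class PerceivedFeature:
    """One chemical feature of a conformer: kind set, position (Å), source atoms.

    ``kinds`` is a set because co-located sites are composite — a carboxylate
    oxygen is simultaneously an H-bond acceptor and a metal ligator.
    """

    kinds: frozenset
    position: np.ndarray
    source_atoms: tuple = ()

    def __post_init__(self):
        self.kinds = frozenset(FeatureKind(k) for k in self.kinds)
        if not self.kinds:
            raise ValueError("kinds must be non-empty")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")


@dataclass
class FeatureSet:
    """All perceived features of one conformer of one molecule."""

    molecule_id: str
    conformer: int = 0
    features: list = field(default_factory=list)

    def __len__(self):
        return len(self.features)

    def positions(self) -> np.ndarray:
        if not self.features:
            return np.zeros((0, 3))
        return np.array([f.position for f in self.features])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FeatureSet":
        """Return a rigidly moved copy (positions → R·p + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        return FeatureSet(
            molecule_id=self.molecule_id,
            conformer=self.conformer,
            features=[
                PerceivedFeature(f.kinds, rotation @ f.position + translation, f.source_atoms)
                for f in self.features
            ],
        )


def write_feature_sets(sets: Iterable[FeatureSet], path) -> None:
    """Write feature sets as JSON lines, one record per set."""
    with open(path, "w", encoding="utf-8") as fh:
        for fs in sets:
            rec = {
                "molecule_id": fs.molecule_id,
                "conformer": fs.conformer,
                "features": [
                    {
                        "kinds": sorted(k.value for k in f.kinds),
                        "position": [float(x) for x in f.position],
                    }
                    for f in fs.features
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_feature_sets(path) -> list:
    sets = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        sets.append(
            FeatureSet(
                molecule_id=rec["molecule_id"],
                conformer=rec.get("conformer", 0),
                features=[
                    PerceivedFeature(frozenset(f["kinds"]), np.array(f["position"]))
                    for f in rec["features"]
                ],
            )
        )
    return sets
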