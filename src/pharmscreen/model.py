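"""Pharmacophore model representation and geometry.

A pharmacophore model is an ordered list of typed spherical features: each
feature has a boolean type expression over the five primitive feature kinds
(aromatic center, hydrophobic center, H-bond acceptor, H-bond donor, metal
ligator), a 3D centroid in Å, a tolerance radius in Å, and an essentiality
flag.  A candidate molecule is a hit when at least ``min_match`` features —
always including every essential one — are satisfied within their radii.

The built-in dual hIDO1/hTDO2 inhibitor model ships as
:func:`builtin_dual_model`: five features (three aromatic/hydrophobic
centers, one metal-ligator-or-H-bonding point, and one essential
metal-ligator that must also H-bond) of which only F4 may be dropped.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "FeatureKind",
    "FeatureTypeExpr",
    "KindLeaf",
    "OrExpr",
    "AndExpr",
    "parse_type_expr",
    "expr_satisfied",
    "ExprParseError",
    "ModelValidationError",
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "GeometryRelation",
    "builtin_dual_model",
    "load_model",
    "save_model",
    "feature_distance",
    "feature_angle",
    "geometry_report",
]

MODEL_FORMAT_VERSION = 1


class FeatureKind(str, Enum):
    """The five primitive pharmacophoric feature kinds."""

    Aro = "Aro"  # aromatic ring center
    Hyd = "Hyd"  # hydrophobic center
    Acc = "Acc"  # hydrogen-bond acceptor
    Don = "Don"  # hydrogen-bond donor
    ML = "ML"    # metal ligator (heme-iron coordinating atom)


class ExprParseError(ValueError):
    """Malformed feature-type expression; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class FeatureTypeExpr:
    """Boolean expression over :class:`FeatureKind`.

    ``|`` is OR, ``&`` is AND; ``&`` binds tighter, parentheses override.
    """

    def satisfied_by(self, kinds: Iterable[FeatureKind]) -> bool:
        raise NotImplementedError

    def serialize(self) -> str:
        raise NotImplementedError

    def __eq__(self, other):
        return isinstance(other, FeatureTypeExpr) and self.serialize() == other.serialize()

    def __hash__(self):
        return hash(self.serialize())

    def __repr__(self):
        return f"{type(self).__name__}({self.serialize()!r})"


@dataclass(frozen=True, eq=False, repr=False)
class KindLeaf(FeatureTypeExpr):
    kind: FeatureKind

    def satisfied_by(self, kinds):
        return self.kind in set(kinds)

    def serialize(self):
        return self.kind.value


@dataclass(frozen=True, eq=False, repr=False)
class OrExpr(FeatureTypeExpr):
    terms: tuple

    def satisfied_by(self, kinds):
        ks = set(kinds)
        return any(t.satisfied_by(ks) for t in self.terms)

    def serialize(self):
        return "|".join(t.serialize() for t in self.terms)


@dataclass(frozen=True, eq=False, repr=False)
class AndExpr(FeatureTypeExpr):
    terms: tuple

    def satisfied_by(self, kinds):
        ks = set(kinds)
        return all(t.satisfied_by(ks) for t in self.terms)

    def serialize(self):
        parts = []
        for t in self.terms:
            s = t.serialize()
            if isinstance(t, OrExpr):
                s = f"({s})"
            parts.append(s)
        return "&".join(parts)


def _tokenize(text: str):
    tokens = []  # (token, position)
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "|&()":
            tokens.append((c, i))
            i += 1
            continue
        if c.isalpha():
            j = i
            while j < n and text[j].isalpha():
                j += 1
            tokens.append((text[i:j], i))
            i = j
            continue
        raise ExprParseError(f"unexpected character {c!r}", i)
    return tokens


def parse_type_expr(text: str) -> FeatureTypeExpr:
    """Parse a feature-type expression such as ``"ML&(Acc|Don)"``.

    OR (``|``) binds looser than AND (``&``); parentheses group.  Raises
    :class:`ExprParseError` naming the offending position on malformed input.
    """
    if not text or not text.strip():
        raise ExprParseError("empty expression", 0)
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() == "|":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else OrExpr(tuple(terms))

    def parse_and():
        terms = [parse_atom()]
        while peek() == "&":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else AndExpr(tuple(terms))

    def parse_atom():
        if pos >= len(tokens):
            raise ExprParseError("unexpected end of expression", len(text))
        tok, at = take()
        if tok == "(":
            inner = parse_or()
            if peek() != ")":
                raise ExprParseError("unbalanced parentheses", at)
            take()
            return inner
        if tok in FeatureKind.__members__:
            return KindLeaf(FeatureKind(tok))
        raise ExprParseError(f"unexpected token {tok!r}", at)

    expr = parse_or()
    if pos < len(tokens):
        tok, at = tokens[pos]
        raise ExprParseError(f"unexpected trailing token {tok!r}", at)
    return expr


def expr_satisfied(expr: FeatureTypeExpr, kinds: Iterable[FeatureKind]) -> bool:
    """Evaluate *expr* against a set of perceived feature kinds."""
    return expr.satisfied_by(kinds)


class ModelValidationError(ValueError):
    """Raised when a model violates its invariants; lists all violations."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid pharmacophore model: " + "; ".join(self.violations))


@dataclass
class PharmacophoreFeature:
    """One spherical model feature: type expression, centroid, tolerance."""

    id: str
    expr: FeatureTypeExpr
    center: np.ndarray
    radius: float
    essential: bool = True

    def __post_init__(self):
        if isinstance(self.expr, str):
            self.expr = parse_type_expr(self.expr)
        self.center = np.asarray(self.center, dtype=float)

    def validate(self) -> list:
        v = []
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            v.append(f"feature {self.id}: center must be a finite 3-vector")
        if not (isinstance(self.radius, (int, float)) and math.isfinite(self.radius) and self.radius > 0):
            v.append(f"feature {self.id}: radius must be > 0, got {self.radius}")
        return v


@dataclass
class PharmacophoreModel:
    """Ordered feature list plus the partial-match threshold ``min_match``.

    A hit must satisfy at least ``min_match`` features including every
    essential one; with the built-in model (min_match 4, F4 the only
    non-essential feature) this is exactly "all five or the four essentials".
    """

    features: list
    min_match: int
    name: str = "pharmacophore"

    def __post_init__(self):
        violations = self.validate()
        if violations:
            raise ModelValidationError(violations)

    def validate(self) -> list:
        v = []
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            v.append("feature ids must be unique")
        for f in self.features:
            v.extend(f.validate())
        n = len(self.features)
        n_ess = sum(f.essential for f in self.features)
        if not (1 <= self.min_match <= n):
            v.append(f"min_match must be in [1, {n}], got {self.min_match}")
        elif n_ess > self.min_match:
            v.append(f"essential feature count {n_ess} exceeds min_match {self.min_match}")
        return v

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def essential_ids(self) -> list:
        return [f.id for f in self.features if f.essential]

    def feature(self, fid: str) -> PharmacophoreFeature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(f"no feature with id {fid!r}")

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])


@dataclass(frozen=True)
class GeometryRelation:
    """One inter-feature distance (Å) or apex angle (degrees)."""

    kind: str            # "distance" | "angle"
    feature_ids: tuple   # (a, b) for distance; (apex, a, b) for angle
    value: float


# Printed dual hIDO1/hTDO2 model: expressions, radii (Å), centroids (Å).
_BUILTIN = [
    ("F1", "Aro|Hyd", (0.6502, 2.0583, 2.4823), 1.5, True),
    ("F2", "Aro|Hyd", (-4.1278, -0.8281, -1.5894), 1.5, True),
    ("F3", "Aro|Hyd", (-0.6952, -2.0007, 0.1855), 0.7, True),
    ("F4", "ML|Acc|Don", (-0.636, 1.2624, -0.8650), 1.3, False),
    ("F5", "ML&(Acc|Don)", (-0.9913, -2.8787, 0.6632), 0.4, True),
]


def builtin_dual_model() -> PharmacophoreModel:
    """The five-feature dual hIDO1/hTDO2 inhibitor pharmacophore.

    Three aromatic/hydrophobic centers (F1, F2, F3), a non-essential
    metal-ligator/acceptor/donor point (F4), and an essential metal ligator
    that must simultaneously accept or donate a hydrogen bond (F5, the
    heme-iron anchor).  Partial match: at least four features, F4 the only
    one that may be dropped.
    """
    feats = [
        PharmacophoreFeature(fid, expr, np.array(center), radius, essential)
        for fid, expr, center, radius, essential in _BUILTIN
    ]
    return PharmacophoreModel(features=feats, min_match=4, name="dual-hIDO1-hTDO2")


def save_model(model: PharmacophoreModel, path) -> None:
    """Write a model as JSON (format_version 1); full float precision."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "name": model.name,
        "min_match": model.min_match,
        "features": [
            {
                "id": f.id,
                "expr": f.expr.serialize(),
                "center": [float(x) for x in f.center],
                "radius": float(f.radius),
                "essential": bool(f.essential),
            }
            for f in model.features
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_model(path) -> PharmacophoreModel:
    """Load a model JSON file, validating every invariant.

    A feature record omitting ``essential`` defaults to ``True`` with a
    warning (a conservative default: unknown features are treated as
    mandatory).  All violations are collected into one
    :class:`ModelValidationError`.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ModelValidationError([f"not valid JSON: {e}"]) from e
    violations = []
    for key in ("name", "min_match", "features"):
        if key not in doc:
            violations.append(f"missing top-level key {key!r}")
    if violations:
        raise ModelValidationError(violations)
    feats = []
    for i, rec in enumerate(doc["features"]):
        fid = rec.get("id", f"<feature {i}>")
        missing = [k for k in ("id", "expr", "center", "radius") if k not in rec]
        if missing:
            violations.extend(f"feature {fid}: missing field {k!r}" for k in missing)
            continue
        if "essential" not in rec:
            warnings.warn(
                f"feature {fid}: 'essential' not specified, defaulting to true",
                stacklevel=2,
            )
        try:
            expr = parse_type_expr(rec["expr"])
        except ExprParseError as e:
            violations.append(f"feature {fid}: bad expression: {e}")
            continue
        center = np.asarray(rec["center"], dtype=float)
        radius = rec["radius"]
        f = PharmacophoreFeature(fid, expr, center, radius, rec.get("essential", True))
        violations.extend(f.validate())
        feats.append(f)
    if violations:
        raise ModelValidationError(violations)
    try:
        return PharmacophoreModel(features=feats, min_match=doc["min_match"], name=doc["name"])
    except ModelValidationError:
        raise


def feature_distance(model: PharmacophoreModel, a: str, b: str) -> float:
    """Euclidean distance (Å) between the centroids of features *a* and *b*."""
    return float(np.linalg.norm(model.feature(a).center - model.feature(b).center))


def feature_angle(model: PharmacophoreModel, apex: str, a: str, b: str) -> float:
    """Angle (degrees, in [0, 180]) at *apex* between directions to *a* and *b*."""
    p = model.feature(apex).center
    u = model.feature(a).center - p
    v = model.feature(b).center - p
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError(
            f"degenerate geometry: apex {apex} coincides with {a if nu == 0 else b}"
        )
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# Relations reported for the built-in model: the five nearest-neighbour
# distances and the apex angle at each feature between its two neighbours.
_REPORT_DISTANCES = [("F1", "F3"), ("F1", "F4"), ("F2", "F4"), ("F2", "F5"), ("F3", "F5")]
_REPORT_ANGLES = [
    ("F1", "F3", "F4"),
    ("F2", "F4", "F5"),
    ("F3", "F1", "F5"),
    ("F4", "F1", "F2"),
    ("F5", "F2", "F3"),
]


def geometry_report(model: PharmacophoreModel) -> list:
    """Audit table of inter-feature distances and apex angles.

    For a five-feature model laid out like the built-in one this emits the
    ten canonical relations (five distances, five angles); for other models
    all pairwise distances and, where at least three features exist, the
    apex angles over consecutive feature triples.
    """
    ids = [f.id for f in model.features]
    relations = []
    if set(ids) == {"F1", "F2", "F3", "F4", "F5"}:
        for a, b in _REPORT_DISTANCES:
            relations.append(GeometryRelation("distance", (a, b), feature_distance(model, a, b)))
        for apex, a, b in _REPORT_ANGLES:
            relations.append(GeometryRelation("angle", (apex, a, b), feature_angle(model, apex, a, b)))
        return relations
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            relations.append(GeometryRelation("distance", (a, b), feature_distance(model, a, b)))
    for i, apex in enumerate(ids):
        a, b = ids[(i - 1) % len(ids)], ids[(i + 1) % len(ids)]
        if len(ids) >= 3 and len({apex, a, b}) == 3:
            relations.append(GeometryRelation("angle", (apex, a, b), feature_angle(model, apex, a, b)))
    return relations
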