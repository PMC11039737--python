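"""Partial-match pharmacophore fitting and library screening.

A molecule fits the model when some injective, type-compatible assignment
of its perceived features to model features — covering at least
``min_match`` features and every essential one — can be rigidly superposed
so that each matched feature falls inside its model feature's tolerance
radius.  The fitting score is ``n_matched / n_features`` (e.g. "4/5").

Candidate assignments are enumerated by backtracking with pairwise
inter-feature-distance pruning; each surviving assignment is scored by
weighted least-squares rigid superposition (Kabsch, proper rotations only;
weights 1/radius², so tight-tolerance features dominate the alignment) and
accepted on per-feature radius containment.  Radius containment after
superposition is the central approximation of this package: commercial
suites do not document their internal acceptance rule, and the tolerance
radii are the only printed tolerances.

:class:`PharmacophoreScreener` exposes screening as a scikit-learn style
classifier over feature sets or RDKit molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import FeatureSet
from .model import PharmacophoreModel, builtin_dual_model, expr_satisfied, load_model

__all__ = [
    "MatchParams",
    "MatchResult",
    "superpose",
    "enumerate_correspondences",
    "best_match",
    "screen_library",
    "PharmacophoreScreener",
    "SCREEN_COLUMNS",
]

SCREEN_COLUMNS = ["molecule_id", "hit", "n_matched", "fitting", "rmsd_A", "conformer"]


@dataclass
class MatchParams:
    """Matching knobs.

    min_match: minimum matched features (default: the model's own).
    radius_scale: dimensionless multiplier on all tolerance radii.
    pair_slack: extra Å allowed in pairwise-distance pruning, so pruning
        never discards an assignment the radius-containment test could
        still accept.
    """

    min_match: Optional[int] = None
    radius_scale: float = 1.0
    pair_slack: float = 1.0

    def __post_init__(self):
        if self.min_match is not None and self.min_match < 1:
            raise ValueError("min_match must be >= 1")
        if self.radius_scale <= 0:
            raise ValueError("radius_scale must be > 0")
        if self.pair_slack < 0:
            raise ValueError("pair_slack must be >= 0")


@dataclass
class MatchResult:
    """Best accepted fit of one molecule against the model."""

    molecule_id: str
    conformer: int
    correspondence: dict           # model feature id -> perceived feature index
    n_matched: int
    fitting: str                   # "n/N"
    residuals: np.ndarray          # per matched feature, Å, model order
    rmsd: float                    # Å
    rotation: np.ndarray           # 3x3 proper rotation
    translation: np.ndarray        # 3-vector


def superpose(model_points: np.ndarray, perceived_points: np.ndarray,
              weights: Optional[np.ndarray] = None):
    """Least-squares optimal proper rigid transform of perceived onto model.

    Returns ``(rotation, translation, residuals, rmsd)`` with
    ``aligned = rotation @ p + translation``; ``det(rotation) = +1``
    (mirror images are never used).  ``weights`` are optional per-pair
    least-squares weights; residuals and RMSD are always unweighted.
    """
    m = np.asarray(model_points, float).reshape(-1, 3)
    p = np.asarray(perceived_points, float).reshape(-1, 3)
    if len(m) != len(p) or len(m) < 1:
        raise ValueError("need >= 1 point pair of equal length")
    if weights is None:
        w = np.ones(len(m))
    else:
        w = np.asarray(weights, float)
    mu_m = np.average(m, axis=0, weights=w)
    mu_p = np.average(p, axis=0, weights=w)
    if len(m) == 1:
        rot = np.eye(3)
    else:
        with warnings.catch_warnings():
            # 2-point sets have a non-unique optimum; any optimizer is fine
            warnings.simplefilter("ignore", UserWarning)
            r, _ = Rotation.align_vectors(m - mu_m, p - mu_p, weights=w)
        rot = r.as_matrix()
    t = mu_m - rot @ mu_p
    aligned = p @ rot.T + t
    residuals = np.linalg.norm(aligned - m, axis=1)
    rmsd = float(np.sqrt(np.mean(residuals ** 2)))
    return rot, t, residuals, rmsd


def _effective_min_match(model: PharmacophoreModel, params: MatchParams) -> int:
    return params.min_match if params.min_match is not None else model.min_match


def enumerate_correspondences(fs: FeatureSet, model: PharmacophoreModel,
                              params: MatchParams = MatchParams()) -> List[dict]:
    """All injective type-compatible assignments surviving distance pruning.

    Every returned map has size >= min_match, includes every essential
    model feature, and satisfies the pairwise pruning bound
    ``|d_perceived - d_model| <= radius_scale*(r_i + r_j) + pair_slack``
    for each mapped pair.  Maximal (largest) maps are returned first.
    """
    min_match = _effective_min_match(model, params)
    n_model = model.n_features
    n_perc = len(fs)
    if n_perc == 0:
        return []
    positions = fs.positions()
    centers = model.centers()
    radii = np.array([f.radius for f in model.features])
    # type-compatibility table
    compat = [
        [expr_satisfied(mf.expr, pf.kinds) for pf in fs.features]
        for mf in model.features
    ]
    pd_perc = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    pd_model = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)

    results = []
    assignment = {}  # model index -> perceived index

    def feasible(mi, pi):
        if not compat[mi][pi]:
            return False
        for mj, pj in assignment.items():
            bound = params.radius_scale * (radii[mi] + radii[mj]) + params.pair_slack
            if abs(pd_perc[pi, pj] - pd_model[mi, mj]) > bound:
                return False
        return True

    def backtrack(mi):
        if mi == n_model:
            if len(assignment) >= min_match:
                results.append(dict(assignment))
            return
        mf = model.features[mi]
        remaining = n_model - mi  # features left including this one
        for pi in range(n_perc):
            if pi in assignment.values():
                continue
            if feasible(mi, pi):
                assignment[mi] = pi
                backtrack(mi + 1)
                del assignment[mi]
        # skipping is allowed only for non-essential features, and only if
        # min_match can still be reached
        if not mf.essential and len(assignment) + remaining - 1 >= min_match:
            backtrack(mi + 1)

    backtrack(0)
    results.sort(key=lambda a: (-len(a), sorted(a.items())))
    ids = [f.id for f in model.features]
    return [{ids[mi]: pi for mi, pi in sorted(a.items())} for a in results]


def _evaluate(fs: FeatureSet, model: PharmacophoreModel, params: MatchParams,
              corr: dict) -> Optional[MatchResult]:
    """Superpose one correspondence; accept on radius containment."""
    mids = list(corr.keys())
    mfeats = [model.feature(fid) for fid in mids]
    mpts = np.array([f.center for f in mfeats])
    ppts = np.array([fs.features[corr[fid]].position for fid in mids])
    radii = np.array([f.radius for f in mfeats])
    rot, t, residuals, rmsd = superpose(mpts, ppts, weights=1.0 / radii ** 2)
    if np.all(residuals <= params.radius_scale * radii + 1e-12):
        return MatchResult(
            molecule_id=fs.molecule_id,
            conformer=fs.conformer,
            correspondence=corr,
            n_matched=len(corr),
            fitting=f"{len(corr)}/{model.n_features}",
            residuals=residuals,
            rmsd=rmsd,
            rotation=rot,
            translation=t,
        )
    return None


def best_match(feature_sets: Union[FeatureSet, Sequence[FeatureSet]],
               model: PharmacophoreModel,
               params: MatchParams = MatchParams()) -> Optional[MatchResult]:
    """Best accepted fit over all conformers, or ``None`` when nothing fits.

    Among accepted correspondences: highest ``n_matched``, then lowest
    RMSD, then lowest conformer index.
    """
    if isinstance(feature_sets, FeatureSet):
        feature_sets = [feature_sets]
    best = None
    for fs in feature_sets:
        for corr in enumerate_correspondences(fs, model, params):
            res = _evaluate(fs, model, params, corr)
            if res is None:
                continue
            key = (-res.n_matched, res.rmsd, res.conformer)
            if best is None or key < (-best.n_matched, best.rmsd, best.conformer):
                best = res
    return best


def _as_feature_sets(item, rules):
    """One library entry -> (molecule id, [FeatureSet per conformer]) or error."""
    from .perception import perceive

    if isinstance(item, FeatureSet):
        return item.molecule_id, [item], None
    if item is None:
        return "<unreadable>", [], "unreadable record"
    if isinstance(item, Chem.Mol):
        name = item.GetProp("_Name") if item.HasProp("_Name") else "unnamed"
        try:
            sets = [perceive(item, c, rules) for c in range(item.GetNumConformers())]
            if not sets:
                return name, [], "no 3D conformer"
            return name, sets, None
        except Exception as e:
            return name, [], str(e)
    return str(item), [], f"unsupported record type {type(item).__name__}"


def screen_library(library: Sequence, model: PharmacophoreModel,
                   params: MatchParams = MatchParams(), rules=None) -> pd.DataFrame:
    """Screen a library; one row per molecule, hits first.

    Entries may be RDKit molecules (perceived per conformer) or prepared
    :class:`FeatureSet` objects.  Unreadable records are flagged
    ``hit="error"`` and screening continues.  Rows are ordered by
    (hit desc, n_matched desc, RMSD asc) and the result is deterministic.
    """
    rows = []
    for i, item in enumerate(library):
        mol_id, sets, err = _as_feature_sets(item, rules)
        if err is not None:
            rows.append((mol_id, "error", 0, "", np.nan, -1, 2, i))
            continue
        res = best_match(sets, model, params)
        if res is None:
            rows.append((mol_id, 0, 0, f"0/{model.n_features}", np.nan, -1, 1, i))
        else:
            rows.append((mol_id, 1, res.n_matched, res.fitting, res.rmsd,
                         res.conformer, 0, i))
    df = pd.DataFrame(rows, columns=SCREEN_COLUMNS + ["_rank", "_order"])
    df = df.sort_values(
        by=["_rank", "n_matched", "rmsd_A", "_order"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns=["_rank", "_order"]).reset_index(drop=True)
    return df


class PharmacophoreScreener(ClassifierMixin, BaseEstimator):
    """Pharmacophore hit/no-hit classifier in scikit-learn form.

    Parameters
    ----------
    model : "builtin", PharmacophoreModel, or path to a model JSON file
        The pharmacophore to screen against; "builtin" is the packaged
        dual hIDO1/hTDO2 model.
    min_match, radius_scale, pair_slack : see :class:`MatchParams`.
    rules : PerceptionRules or None
        Used only when ``X`` entries are RDKit molecules.

    ``X`` is a sequence of :class:`FeatureSet` objects (or RDKit molecules
    with 3D conformers); ``predict`` returns 1 for hits, 0 for misses.
    """

    def __init__(self, model="builtin", min_match=None, radius_scale=1.0,
                 pair_slack=1.0, rules=None):
        self.model = model
        self.min_match = min_match
        self.radius_scale = radius_scale
        self.pair_slack = pair_slack
        self.rules = rules

    def fit(self, X=None, y=None):
        """Resolve and validate the model; no parameters are estimated."""
        if isinstance(self.model, PharmacophoreModel):
            self.model_ = self.model
        elif self.model == "builtin":
            self.model_ = builtin_dual_model()
        else:
            self.model_ = load_model(self.model)
        self.params_ = MatchParams(self.min_match, self.radius_scale, self.pair_slack)
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            self.fit()

    def match(self, X) -> list:
        """Per-entry :class:`MatchResult` (or ``None``), no table."""
        self._check_fitted()
        out = []
        for item in X:
            _, sets, err = _as_feature_sets(item, self.rules)
            out.append(None if err else best_match(sets, self.model_, self.params_))
        return out

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return np.array([0 if m is None else 1 for m in self.match(X)])

    def screen(self, X) -> pd.DataFrame:
        """Full screening table (TSV-ready, see :data:`SCREEN_COLUMNS`)."""
        self._check_fitted()
        return screen_library(X, self.model_, self.params_, self.rules)
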