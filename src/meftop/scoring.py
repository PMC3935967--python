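"""Feature assembly, the weighted SVR quality predictor, and the Z/P/M scores.

The 37 features are assembled in a fixed published grouping (14 traditional
1D, 10 traditional 2D, 6 SSE contact, 7 topology).  An epsilon-SVR with RBF
kernel, fitted on min-max scaled features with per-model sample weights
equal to the TM-score label, predicts model quality (the P-score, a
TM-score estimate).  The threading raw score is standardized per target
pool (Z-score) and combined linearly as M = Z + n * P for final selection;
``n`` and the SVR hyperparameters are selected with a cost function that
rewards ranking the native first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from .features_sse import SSE_FEATURE_NAMES, sse_features
from .features_topology import TOPOLOGY_FEATURE_NAMES, topology_features
from .features_traditional import (
    TRADITIONAL_1D_NAMES,
    TRADITIONAL_2D_NAMES,
    traditional_features,
)
from .io_structures import StructureModel, annotate
from .target_profile import TargetProfile

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "ScorerConfig",
    "TrainedScorer",
    "ScoredModel",
    "DecoySet",
    "assemble_features",
    "feature_matrix",
    "z_score",
    "train",
    "p_score",
    "m_score",
    "cost_F",
    "select_mscore_weight",
    "rank_models",
]

FEATURE_GROUPS = {
    "traditional_1d": list(TRADITIONAL_1D_NAMES),
    "traditional_2d": list(TRADITIONAL_2D_NAMES),
    "sse_contact": list(SSE_FEATURE_NAMES),
    "topology_3d": list(TOPOLOGY_FEATURE_NAMES),
}

FEATURE_NAMES = [name for group in FEATURE_GROUPS.values() for name in group]

SCORER_FORMAT_VERSION = 1


def assemble_features(profile: TargetProfile, model: StructureModel) -> np.ndarray:
    """The 37-entry feature vector for one (profile, model) pair.

    The model is annotated in place if its SS/RSA states are missing.  Any
    NaN from a degenerate sub-feature is replaced by 0 with a warning.
    """
    if len(profile) != model.length:
        raise ValueError(
            f"profile length {len(profile)} != model length {model.length}"
        )
    if any(r.ss_state is None or r.rsa_state is None for r in model.residues):
        annotate(model)
    values: dict[str, float] = {}
    values.update(traditional_features(profile, model))
    values.update(sse_features(profile, model))
    values.update(topology_features(profile, model))
    vec = np.array([values[name] for name in FEATURE_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        warnings.warn("non-finite feature values replaced by 0")
        vec = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
    return vec


def feature_matrix(profile: TargetProfile, models) -> np.ndarray:
    """Stack feature vectors for a list of models of one target."""
    return np.array([assemble_features(profile, m) for m in models])


def z_score(raw_scores) -> np.ndarray:
    """Standardize raw threading scores over one target's model pool.

    Population standard deviation; a constant pool maps to all zeros.
    Fewer than two scores is an error.
    """
    s = np.asarray(raw_scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 raw scores to standardize")
    sd = s.std()
    if sd == 0.0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


@dataclass
class ScorerConfig:
    """SVR hyperparameters and the M-score weight."""

    C: float = 10.0
    gamma: float = 0.25
    epsilon: float = 0.05
    mscore_weight: float = 1.0


@dataclass
class TrainedScorer:
    svr: SVR
    scaler: MinMaxScaler
    config: ScorerConfig
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    version: int = SCORER_FORMAT_VERSION

    def predict(self, X: np.ndarray, clip: bool = True) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        raw = self.svr.predict(self.scaler.transform(X))
        return np.clip(raw, 0.0, 1.0) if clip else raw

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedScorer":
        scorer = joblib.load(path)
        if not isinstance(scorer, TrainedScorer):
            raise ValueError(f"{path} does not hold a TrainedScorer")
        if scorer.version != SCORER_FORMAT_VERSION:
            raise ValueError(f"unsupported scorer format version {scorer.version}")
        return scorer


def train(X: np.ndarray, tm_labels, config: ScorerConfig | None = None,
          sample_weight=None) -> TrainedScorer:
    """Fit the weighted epsilon-SVR quality predictor.

    Features are min-max scaled to [0, 1] (learned on the training split).
    The per-instance weight defaults to the TM-score label itself, so better
    models pull the regression harder.  Requires >= 20 labelled vectors with
    non-degenerate labels in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(tm_labels, dtype=float)
    if len(X) < 20:
        raise ValueError("need at least 20 labelled feature vectors")
    if (y < 0).any() or (y > 1).any():
        raise ValueError("TM-score labels must lie in [0, 1]")
    if np.ptp(y) == 0.0:
        raise ValueError("degenerate labels: all TM-scores equal")
    if config is None:
        config = ScorerConfig()
    if sample_weight is None:
        sample_weight = y
    scaler = MinMaxScaler().fit(X)
    svr = SVR(kernel="rbf", C=config.C, gamma=config.gamma, epsilon=config.epsilon)
    svr.fit(scaler.transform(X), y, sample_weight=np.asarray(sample_weight, dtype=float))
    return TrainedScorer(svr=svr, scaler=scaler, config=config)


def p_score(scorer: TrainedScorer, x: np.ndarray) -> float:
    """Predicted TM-score of a single feature vector, clipped to [0, 1]."""
    return float(scorer.predict(np.atleast_2d(x))[0])


def m_score(z: float, p: float, n: float) -> float:
    """Combined selection metric M = Z + n * P (n >= 0)."""
    if n < 0:
        raise ValueError("M-score weight must be >= 0")
    return float(z + n * p)


def cost_F(ranks_of_native, z_svm, n_weight: float = 1.0, missed: int | None = None,
           lam: float = 1.0) -> float:
    """Training cost: mean native rank - n * mean standardized predictor score
    of the native + lambda * number of targets whose native is not ranked 1st."""
    ranks = np.asarray(list(ranks_of_native), dtype=float)
    zs = np.asarray(list(z_svm), dtype=float)
    if len(ranks) == 0:
        raise ValueError("empty target set")
    if missed is None:
        missed = int(np.sum(ranks > 1))
    return float(ranks.mean() - n_weight * zs.mean() + lam * missed)


def select_mscore_weight(z_by_target, p_by_target, tm_by_target,
                         grid=None, cutoff: float = 0.4) -> float:
    """Pick the M-score weight maximizing Top1% on validation targets.

    Grid defaults to 0.5 .. 10 in steps of 0.5; ties take the smaller weight.
    """
    if grid is None:
        grid = np.arange(0.5, 10.0 + 1e-9, 0.5)
    best_n, best_top1 = None, -1.0
    for n in grid:
        hits = 0
        for z, p, tm in zip(z_by_target, p_by_target, tm_by_target):
            sel = int(np.argmax(np.asarray(z) + n * np.asarray(p)))
            if tm[sel] > cutoff:
                hits += 1
        top1 = hits / len(tm_by_target)
        if top1 > best_top1:
            best_top1, best_n = top1, float(n)
    return best_n


@dataclass
class DecoySet:
    """All candidate models of one target, with optional labels and scores."""

    target_id: str
    models: list[StructureModel]
    raw_scores: np.ndarray | None = None
    tm_scores: np.ndarray | None = None
    native: StructureModel | None = None
    profile: TargetProfile | None = None

    def __post_init__(self):
        for name in ("raw_scores", "tm_scores"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != len(self.models):
                    raise ValueError(f"{name} not aligned with models")
                setattr(self, name, arr)
        if self.tm_scores is not None and ((self.tm_scores < 0).any() or (self.tm_scores > 1).any()):
            raise ValueError("tm_scores must lie in [0, 1]")


@dataclass
class ScoredModel:
    model_id: str
    p_score: float | None = None
    z_score: float | None = None
    m_score: float | None = None


def rank_models(decoys: DecoySet, scorer: TrainedScorer | None = None,
                metric: str = "m", profile: TargetProfile | None = None) -> list[ScoredModel]:
    """Score every model of a decoy set and sort descending by the chosen
    metric (z, p or m); ties are broken by model_id, so ranking is stable."""
    if metric not in ("z", "p", "m"):
        raise ValueError("metric must be one of z, p, m")
    profile = profile or decoys.profile
    zs = ps = None
    if metric in ("z", "m"):
        if decoys.raw_scores is None:
            raise ValueError(f"metric {metric!r} requires raw threading scores")
        zs = z_score(decoys.raw_scores)
    if metric in ("p", "m"):
        if scorer is None or profile is None:
            raise ValueError(f"metric {metric!r} requires a trained scorer and a target profile")
        ps = scorer.predict(feature_matrix(profile, decoys.models))
    scored = []
    for i, model in enumerate(decoys.models):
        z = float(zs[i]) if zs is not None else None
        p = float(ps[i]) if ps is not None else None
        m = m_score(z, p, scorer.config.mscore_weight) if (z is not None and p is not None) else None
        scored.append(ScoredModel(model.model_id, p_score=p, z_score=z, m_score=m))
    key = {"z": "z_score", "p": "p_score", "m": "m_score"}[metric]
    return sorted(scored, key=lambda s: (-getattr(s, key), s.model_id))
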