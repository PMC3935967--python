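"""Secondary-structure-element (SSE) contact features.

Six features describing how the spatial arrangement of SSEs in a model
agrees with what the sequence-side contact predictions imply: the overall
SSE contact-strength match score f_SSE, cosine and correlation of SSE
contact-number vectors, a Gaussian similarity of SSE pair distances, and two
length ratios over corresponding SSEs.

An SSE is a maximal run of at least four consecutive residues sharing the
helix or strand state.  Model and target SSEs are put in one-to-one
correspondence greedily along the sequence by minimal start-position
difference (ties favour the earlier target SSE; matching never crosses);
only corresponding SSEs enter the features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features_traditional import correlation, cosine
from .io_structures import MIN_SEPARATION, StructureModel
from .target_profile import TargetProfile

__all__ = [
    "SSE",
    "identify_sses",
    "correspond_sses",
    "sse_contact_strength_model",
    "sse_contact_strength_sequence",
    "normalize_strength",
    "f_sse",
    "sse_contact_numbers",
    "sse_pair_distance_model",
    "sse_pair_distance_sequence",
    "sse_distance_similarity",
    "sse_length_ratios",
    "sse_features",
    "SSE_FEATURE_NAMES",
]

MIN_SSE_LENGTH = 4

#: Model-side SSE contact-strength distance threshold (A).  Kept equal to the
#: 8 A contact class by default so a prediction that exactly matches the model
#: geometry scores f_SSE = 1; a looser 8.5 A cut can be passed explicitly.
MODEL_STRENGTH_THRESHOLD = 8.0

# Predicted SSE-pair distance transform: D = D0 + k*(Dm - D0)*(P0 - p),
# clipped to [D0, D_CAP].  p is the maximum predicted contact probability
# over the residue pairs of the SSE pair.
DIST_DM = 8.0
DIST_D0 = 3.8
DIST_P0 = 1.0
DIST_K = 1.0
DIST_CAP = 20.0
DIST_SIGMA = 4.0  # A, width of the pair-distance Gaussian similarity


@dataclass(frozen=True)
class SSE:
    kind: str  # H or E
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residue_indices(self) -> np.ndarray:
        """0-based residue indices covered by this SSE."""
        return np.arange(self.start - 1, self.end)


def identify_sses(ss_states: str, min_len: int = MIN_SSE_LENGTH) -> list[SSE]:
    """Maximal runs of identical H or E state with length >= min_len."""
    sses: list[SSE] = []
    i, n = 0, len(ss_states)
    while i < n:
        s = ss_states[i]
        j = i
        while j < n and ss_states[j] == s:
            j += 1
        if s in "HE" and j - i >= min_len:
            sses.append(SSE(kind=s, start=i + 1, end=j))
        i = j
    return sses


def correspond_sses(model_sses: list[SSE], target_sses: list[SSE]) -> list[tuple[int, int]]:
    """Greedy order-preserving one-to-one matching by minimal |start difference|.

    Returns (model_index, target_index) pairs (0-based into the input lists).
    """
    pairs: list[tuple[int, int]] = []
    next_target = 0
    for im, ms in enumerate(model_sses):
        if next_target >= len(target_sses):
            break
        diffs = [abs(ms.start - target_sses[it].start) for it in range(next_target, len(target_sses))]
        best = int(np.argmin(diffs))  # argmin takes the first minimum: earlier SSE wins ties
        pairs.append((im, next_target + best))
        next_target += best + 1
    return pairs


def sse_contact_strength_model(
    sses: list[SSE], model: StructureModel, threshold: float = MODEL_STRENGTH_THRESHOLD
) -> np.ndarray:
    """Raw model-side strengths: count of SCM pairs under the threshold with
    sequence separation >= 6, for every ordered SSE pair."""
    k = len(sses)
    scm = model.scm_coords
    d = np.linalg.norm(scm[:, None, :] - scm[None, :, :], axis=2)
    n = model.length
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    eligible = (d < threshold) & (sep >= MIN_SEPARATION)
    strength = np.zeros((k, k))
    for a in range(k):
        ia = sses[a].residue_indices()
        for b in range(k):
            if a == b:
                continue
            ib = sses[b].residue_indices()
            strength[a, b] = eligible[np.ix_(ia, ib)].sum()
    return strength


def sse_contact_strength_sequence(sses: list[SSE], contact_prob: np.ndarray) -> np.ndarray:
    """Raw sequence-side strengths: sum of predicted contact probabilities
    over the residue pairs of every ordered SSE pair (the probability map is
    already zero inside the separation band)."""
    k = len(sses)
    strength = np.zeros((k, k))
    for a in range(k):
        ia = sses[a].residue_indices()
        for b in range(k):
            if a == b:
                continue
            ib = sses[b].residue_indices()
            strength[a, b] = contact_prob[np.ix_(ia, ib)].sum()
    return strength


def normalize_strength(strength: np.ndarray, sses: list[SSE]) -> np.ndarray:
    """Row-normalize: entry (i, j) divided by the length of SSE i."""
    lengths = np.array([s.length for s in sses], dtype=float)
    return strength / lengths[:, None]


def f_sse(cs_norm: np.ndarray, ns_norm: np.ndarray) -> float:
    """Overall SSE contact-strength match score in [0, 1].

    ``1 - sum|C_S - N_S| / sum max(C_S, N_S)`` over ordered pairs i != j of
    corresponding SSEs.  Fewer than two corresponding SSEs -> 0; both sides
    all-zero -> 1 (vacuous agreement).
    """
    k = cs_norm.shape[0]
    if k < 2:
        return 0.0
    off = ~np.eye(k, dtype=bool)
    num = np.abs(cs_norm - ns_norm)[off].sum()
    den = np.maximum(cs_norm, ns_norm)[off].sum()
    if den == 0.0:
        return 1.0
    return float(max(0.0, 1.0 - num / den))


def sse_contact_numbers(strength: np.ndarray) -> np.ndarray:
    """Contact-number vector: row sums of the raw strength matrix."""
    return strength.sum(axis=1)


def sse_pair_distance_model(sses: list[SSE], model: StructureModel) -> np.ndarray:
    """Minimum SCM-SCM distance (A) between the residues of every SSE pair."""
    k = len(sses)
    scm = model.scm_coords
    d = np.linalg.norm(scm[:, None, :] - scm[None, :, :], axis=2)
    out = np.zeros((k, k))
    for a in range(k):
        ia = sses[a].residue_indices()
        for b in range(a + 1, k):
            ib = sses[b].residue_indices()
            out[a, b] = out[b, a] = d[np.ix_(ia, ib)].min()
    return out


def sse_pair_distance_sequence(
    sses: list[SSE],
    contact_prob: np.ndarray,
    d_m: float = DIST_DM,
    d_0: float = DIST_D0,
    p_0: float = DIST_P0,
    k_const: float = DIST_K,
    cap: float = DIST_CAP,
) -> np.ndarray:
    """Predicted SSE-pair distances from the contact probability map.

    ``D = D0 + k*(Dm - D0)*(P0 - p)`` with p the maximum predicted contact
    probability over the residue pairs of the SSE pair, clipped to [D0, cap].
    """
    k = len(sses)
    out = np.zeros((k, k))
    for a in range(k):
        ia = sses[a].residue_indices()
        for b in range(a + 1, k):
            ib = sses[b].residue_indices()
            p = contact_prob[np.ix_(ia, ib)].max() if len(ia) and len(ib) else 0.0
            dist = d_0 + k_const * (d_m - d_0) * (p_0 - p)
            out[a, b] = out[b, a] = float(np.clip(dist, d_0, cap))
    return out


def sse_distance_similarity(d_model: np.ndarray, d_target: np.ndarray,
                            sigma: float = DIST_SIGMA) -> float:
    """Mean over SSE pairs of exp(-(D_model - D_target)^2 / sigma^2); 0 without pairs."""
    k = d_model.shape[0]
    if k < 2:
        return 0.0
    iu = np.triu_indices(k, 1)
    diff = d_model[iu] - d_target[iu]
    return float(np.mean(np.exp(-(diff ** 2) / sigma ** 2)))


def sse_length_ratios(model_sses: list[SSE], target_sses: list[SSE],
                      pairs: list[tuple[int, int]]):
    """(sum-min over sum-max, mean of per-pair min/max) length ratios; (0, 0) without pairs."""
    if not pairs:
        return 0.0, 0.0
    lm = np.array([model_sses[im].length for im, _ in pairs], dtype=float)
    lt = np.array([target_sses[it].length for _, it in pairs], dtype=float)
    r1 = np.minimum(lm, lt).sum() / np.maximum(lm, lt).sum()
    r2 = float(np.mean(np.minimum(lm, lt) / np.maximum(lm, lt)))
    return float(r1), r2


def sse_features(
    profile: TargetProfile,
    model: StructureModel,
    model_threshold: float = MODEL_STRENGTH_THRESHOLD,
) -> dict[str, float]:
    """All 6 SSE contact features as an ordered name -> value mapping."""
    model_sses = identify_sses(model.ss_string)
    target_sses = identify_sses(profile.ss_pred)
    pairs = correspond_sses(model_sses, target_sses)
    if not pairs:
        return dict.fromkeys(SSE_FEATURE_NAMES, 0.0)
    msel = [model_sses[im] for im, _ in pairs]
    tsel = [target_sses[it] for _, it in pairs]

    s_model = sse_contact_strength_model(msel, model, threshold=model_threshold)
    s_target = sse_contact_strength_sequence(tsel, profile.contact_prob_8)
    out: dict[str, float] = {}
    out["f_sse"] = f_sse(normalize_strength(s_target, tsel), normalize_strength(s_model, msel))
    fm = sse_contact_numbers(s_model)
    ft = sse_contact_numbers(s_target)
    out["sse_cn_cosine"] = cosine(fm, ft)
    out["sse_cn_correlation"] = correlation(fm, ft)
    out["sse_dist_similarity"] = sse_distance_similarity(
        sse_pair_distance_model(msel, model),
        sse_pair_distance_sequence(tsel, profile.contact_prob_8),
    )
    r1, r2 = sse_length_ratios(model_sses, target_sses, pairs)
    out["sse_len_ratio_total"] = r1
    out["sse_len_ratio_mean"] = r2
    return out


SSE_FEATURE_NAMES = [
    "f_sse",
    "sse_cn_cosine",
    "sse_cn_correlation",
    "sse_dist_similarity",
    "sse_len_ratio_total",
    "sse_len_ratio_mean",
]
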