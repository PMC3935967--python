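"""Traditional sequence-vs-model agreement features.

24 features in two groups: 14 one-dimensional composition features (SS and
RSA state fractions on both sides plus four similarity transforms of the two
composition vectors) and 10 contact-map features (cosine/correlation of
per-residue contact-order and contact-number profiles at the 8 A and 12 A
classes, plus the overall residue contact match score f_res at each class).
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_structures import MIN_SEPARATION, StructureModel, contact_map
from .target_profile import TargetProfile

__all__ = [
    "composition_1d",
    "vector_similarities",
    "contact_profiles",
    "contact_profile_similarities",
    "f_res",
    "traditional_features",
    "TRADITIONAL_1D_NAMES",
    "TRADITIONAL_2D_NAMES",
]

CONTACT_THRESHOLDS = (8.0, 12.0)


def composition_1d(ss_states: str, rsa_states: str) -> np.ndarray:
    """Fractions (helix, strand, coil, exposed, buried) of one side."""
    n = len(ss_states)
    if n == 0 or len(rsa_states) != n:
        raise ValueError("empty input or SS/RSA length mismatch")
    ss = np.array([ss_states.count(s) / n for s in "HEC"])
    rsa = np.array([rsa_states.count("e") / n, rsa_states.count("b") / n])
    return np.concatenate([ss, rsa])


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; 0 when either vector is zero."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; 0 when either side has zero variance."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) < 2:
        return 0.0
    su, sv = u.std(), v.std()
    if su == 0.0 or sv == 0.0:
        return 0.0
    return float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))


def vector_similarities(u: np.ndarray, v: np.ndarray, gamma: float = 1.0):
    """(cosine, Pearson correlation, Gaussian kernel exp(-gamma*||u-v||^2), dot)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    gauss = float(np.exp(-gamma * np.sum((u - v) ** 2)))
    return cosine(u, v), correlation(u, v), gauss, float(np.dot(u, v))


def contact_profiles(cmap: np.ndarray):
    """Per-residue (contact_order, contact_number) profiles of a contact map.

    ``contact_number_i = sum_j C_ij``;
    ``contact_order_i = sum_j C_ij * |i-j| / contact_number_i`` (0 when the
    residue has no contacts).  Accepts binary or probabilistic maps.
    """
    cmap = np.asarray(cmap, dtype=float)
    n = cmap.shape[0]
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    number = cmap.sum(axis=1)
    weighted = (cmap * sep).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        order = np.where(number > 0, weighted / np.where(number > 0, number, 1.0), 0.0)
    return order, number


def contact_profile_similarities(profile: TargetProfile, model: StructureModel,
                                 thresholds=CONTACT_THRESHOLDS) -> dict[str, float]:
    """Cosine + correlation of contact-order and contact-number profiles at
    each distance class: 8 features."""
    out: dict[str, float] = {}
    for t in thresholds:
        c = profile.contact_prob(t)
        nmat = contact_map(model, t).matrix
        order_t, number_t = contact_profiles(c)
        order_m, number_m = contact_profiles(nmat)
        key = f"{int(t)}"
        out[f"co_cosine_{key}"] = cosine(order_t, order_m)
        out[f"co_correlation_{key}"] = correlation(order_t, order_m)
        out[f"cn_cosine_{key}"] = cosine(number_t, number_m)
        out[f"cn_correlation_{key}"] = correlation(number_t, number_m)
    return out


def f_res(c: np.ndarray, nmat: np.ndarray) -> float:
    """Overall residue contact match score in [0, 1].

    Mean over eligible pairs (i < j, |i-j| >= 6) of the agreement term
    ``C_ij * N_ij + (1 - C_ij) * (1 - N_ij)``.  Returns 0 with a warning when
    there are no eligible pairs (chains shorter than 7 residues).
    """
    c = np.asarray(c, dtype=float)
    nmat = np.asarray(nmat, dtype=float)
    n = c.shape[0]
    ii, jj = np.triu_indices(n, k=MIN_SEPARATION)
    if len(ii) == 0:
        warnings.warn("no residue pairs at separation >= 6; f_res defined as 0")
        return 0.0
    cv = c[ii, jj]
    nv = nmat[ii, jj]
    return float(np.mean(cv * nv + (1.0 - cv) * (1.0 - nv)))


def traditional_features(profile: TargetProfile, model: StructureModel,
                         gamma: float = 1.0) -> dict[str, float]:
    """All 24 traditional features as an ordered name -> value mapping."""
    comp_seq = composition_1d(profile.ss_pred, profile.rsa_pred)
    comp_mod = composition_1d(model.ss_string, model.rsa_string)
    cos, corr, gauss, dot = vector_similarities(comp_seq, comp_mod, gamma=gamma)
    out: dict[str, float] = {}
    for name, val in zip(
        ("ss_helix_seq", "ss_strand_seq", "ss_coil_seq", "rsa_exposed_seq", "rsa_buried_seq"),
        comp_seq,
    ):
        out[name] = float(val)
    for name, val in zip(
        ("ss_helix_mod", "ss_strand_mod", "ss_coil_mod", "rsa_exposed_mod", "rsa_buried_mod"),
        comp_mod,
    ):
        out[name] = float(val)
    out["comp_cosine"] = cos
    out["comp_correlation"] = corr
    out["comp_gaussian"] = gauss
    out["comp_dot"] = dot
    out.update(contact_profile_similarities(profile, model))
    for t in CONTACT_THRESHOLDS:
        out[f"f_res_{int(t)}"] = f_res(profile.contact_prob(t), contact_map(model, t).matrix)
    return out


TRADITIONAL_1D_NAMES = [
    "ss_helix_seq", "ss_strand_seq", "ss_coil_seq", "rsa_exposed_seq", "rsa_buried_seq",
    "ss_helix_mod", "ss_strand_mod", "ss_coil_mod", "rsa_exposed_mod", "rsa_buried_mod",
    "comp_cosine", "comp_correlation", "comp_gaussian", "comp_dot",
]

TRADITIONAL_2D_NAMES = [
    "co_cosine_8", "co_correlation_8", "cn_cosine_8", "cn_correlation_8",
    "co_cosine_12", "co_correlation_12", "cn_cosine_12", "cn_correlation_12",
    "f_res_8", "f_res_12",
]
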