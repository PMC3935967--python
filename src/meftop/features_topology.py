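"""Three-dimensional topology features.

Seven features describing whether a model has the global shape a sequence of
its length and composition should fold into: two radius-of-gyration
agreement scores against the globular power law R = k * L^m, three
hydrophobic-core descriptors (gyration radius, residue count and number of
contributing SSEs of the largest spatial cluster of hydrophobic side-chain
centroids, each as a min/max ratio against a sequence-side expectation), and
two local fragment-conformation potentials over 5-residue windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .features_sse import identify_sses
from .geometry import virtual_torsions
from .io_structures import StructureModel
from .target_profile import TargetProfile

__all__ = [
    "HydrophobicCore",
    "gyration_features",
    "detect_hc",
    "hc_features",
    "fragment_potentials",
    "topology_features",
    "TOPOLOGY_FEATURE_NAMES",
    "HYDROPHOBIC",
]

HYDROPHOBIC = frozenset("AVLIMFWC")

# Globular-protein radius-of-gyration power law R = RG_K * L**RG_M (A).
RG_K = 2.2
RG_M = 0.38
RG_REL_SIGMA = 0.2  # Gaussian width as a fraction of the predicted radius

HC_LINKAGE_CUTOFF = 6.5  # A, single-linkage distance between hydrophobic SCMs
#: Expected fraction of the sequence's hydrophobic residues inside the core
#: of a well-formed fold (calibrated on idealized globular folds, where a
#: single core collects nearly all inward-facing hydrophobic side chains).
HC_RHO = 0.9

FRAG_WINDOW = 5
FRAG_IDEAL_D14 = {"H": 6.2, "E": 12.4}  # ideal CA(i)-CA(i+4) distance (A)
FRAG_SIGMA = 2.0  # A
FRAG_HELIX_TAU = (45.0, 65.0)  # canonical helical virtual-torsion band (deg)
FRAG_STRAND_TAU_ABS = 150.0  # canonical strand band: |tau| >= 150 deg


def _rg(points: np.ndarray) -> float:
    if len(points) == 0:
        return 0.0
    c = points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((points - c) ** 2, axis=1))))


def _ratio(a: float, b: float) -> float:
    """min/max ratio in [0, 1]; 0 when either side is 0."""
    if a <= 0.0 or b <= 0.0:
        return 0.0
    return float(min(a, b) / max(a, b))


def gyration_features(model: StructureModel, seq_length: int,
                      k: float = RG_K, m: float = RG_M,
                      rel_sigma: float = RG_REL_SIGMA):
    """Two agreement scores between the model radius of gyration and the
    length-predicted radius: a Gaussian similarity and a min/max ratio."""
    ca = model.ca_coords
    r_model = _rg(ca)
    r_pred = k * seq_length ** m
    sigma = rel_sigma * r_pred
    s1 = float(np.exp(-((r_model - r_pred) ** 2) / sigma ** 2))
    s2 = _ratio(r_model, r_pred)
    return s1, s2


@dataclass
class HydrophobicCore:
    member_residues: list[int] = field(default_factory=list)  # 0-based indices
    radius: float = 0.0
    n_residues: int = 0
    n_sses: int = 0


def detect_hc(model: StructureModel, cutoff: float = HC_LINKAGE_CUTOFF) -> HydrophobicCore:
    """Largest single-linkage cluster (at ``cutoff`` A) of hydrophobic SCMs.

    Single-linkage clusters at a fixed cutoff are the connected components of
    the thresholded distance graph.  Size ties are broken toward the cluster
    containing the lowest residue index.  The SSE count uses the model's own
    assigned secondary structure.
    """
    hydro_idx = np.array([i for i, r in enumerate(model.residues) if r.aa in HYDROPHOBIC])
    if len(hydro_idx) == 0:
        return HydrophobicCore()
    pts = model.scm_coords[hydro_idx]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    adj = (d <= cutoff).astype(np.int8)
    n_comp, labels = connected_components(adj, directed=False)
    best = None
    for comp in range(n_comp):
        members = hydro_idx[labels == comp]
        key = (len(members), -members.min())  # bigger cluster, then lower min index
        if best is None or key > best[0]:
            best = (key, members)
    members = best[1]
    sses = identify_sses(model.ss_string)
    n_sses = sum(1 for s in sses if np.any((members >= s.start - 1) & (members <= s.end - 1)))
    return HydrophobicCore(
        member_residues=[int(i) for i in members],
        radius=_rg(model.scm_coords[members]),
        n_residues=int(len(members)),
        n_sses=int(n_sses),
    )


def hc_features(hc: HydrophobicCore, profile: TargetProfile,
                rho: float = HC_RHO, k: float = RG_K, m: float = RG_M):
    """Three min/max ratios (radius, residue count, SSE count) between the
    detected core and sequence-side expectations.

    Expectations: the core holds ``rho`` of the sequence's hydrophobic
    residues, has the power-law radius for that count, and spans the number
    of predicted SSEs containing at least two hydrophobic residues.
    """
    n_hydro = sum(1 for a in profile.sequence if a in HYDROPHOBIC)
    exp_count = rho * n_hydro
    exp_radius = k * exp_count ** m if exp_count > 0 else 0.0
    exp_nsse = 0
    for s in identify_sses(profile.ss_pred):
        if sum(1 for i in range(s.start - 1, s.end) if profile.sequence[i] in HYDROPHOBIC) >= 2:
            exp_nsse += 1
    return (
        _ratio(hc.radius, exp_radius),
        _ratio(float(hc.n_residues), exp_count),
        _ratio(float(hc.n_sses), float(exp_nsse)),
    )


def fragment_potentials(model: StructureModel, sigma: float = FRAG_SIGMA):
    """Two local-conformation potentials over all 5-residue windows.

    Each window takes the majority SS state of its residues (H/E ties go to
    H; majority-coil windows are skipped).  Feature A transforms the mean
    squared deviation of the CA(i)-CA(i+4) distance from the state's ideal
    into exp(-msd / sigma^2); feature B is the fraction of windows whose
    virtual CA torsion lies in the state's canonical band.  Models shorter
    than 5 residues, or with no non-coil window, give (0, 0).
    """
    n = model.length
    if n < FRAG_WINDOW:
        return 0.0, 0.0
    ca = model.ca_coords
    ss = model.ss_string
    tau = np.degrees(virtual_torsions(ca))
    sq_devs = []
    canonical = []
    for i in range(n - FRAG_WINDOW + 1):
        window = ss[i : i + FRAG_WINDOW]
        counts = {s: window.count(s) for s in "HEC"}
        state = max("HEC", key=lambda s: (counts[s], -"HEC".index(s)))
        if state == "C":
            continue
        d14 = float(np.linalg.norm(ca[i + 4] - ca[i]))
        sq_devs.append((d14 - FRAG_IDEAL_D14[state]) ** 2)
        t = tau[i]
        if state == "H":
            canonical.append(FRAG_HELIX_TAU[0] <= t <= FRAG_HELIX_TAU[1])
        else:
            canonical.append(abs(t) >= FRAG_STRAND_TAU_ABS)
    if not sq_devs:
        return 0.0, 0.0
    a = float(np.exp(-np.mean(sq_devs) / sigma ** 2))
    b = float(np.mean(canonical))
    return a, b


def topology_features(profile: TargetProfile, model: StructureModel) -> dict[str, float]:
    """All 7 topology features as an ordered name -> value mapping."""
    s1, s2 = gyration_features(model, len(profile))
    hc = detect_hc(model)
    hr, hcnt, hsse = hc_features(hc, profile)
    fa, fb = fragment_potentials(model)
    return {
        "rg_gauss": s1,
        "rg_ratio": s2,
        "hc_radius_ratio": hr,
        "hc_count_ratio": hcnt,
        "hc_sse_ratio": hsse,
        "frag_dist_potential": fa,
        "frag_torsion_fraction": fb,
    }


TOPOLOGY_FEATURE_NAMES = [
    "rg_gauss", "rg_ratio", "hc_radius_ratio", "hc_count_ratio", "hc_sse_ratio",
    "frag_dist_potential", "frag_torsion_fraction",
]
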