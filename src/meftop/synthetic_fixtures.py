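"""Generated toy folds, decoy ensembles and noisy predictions.

Every benchmark in this package runs on idealized folds built here: helices
and paired strands packed side by side in alternating directions, connected
by short loops, with side-chain centroids facing the fold centre assigned
hydrophobic residue types.  Decoys are produced by perturbing the CA trace
in internal (torsion/angle) coordinates at graded magnitudes, so bond
geometry stays plausible while the global topology degrades; raw threading
scores are the true quality corrupted with Gaussian noise, emulating a
threading engine whose score becomes unreliable on low-confidence targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import tm_score
from .geometry import internal_coords, pseudo_cb_directions, rebuild_chain
from .io_structures import SCM_DISTANCE, Residue, StructureModel, annotate
from .target_profile import ProfileNoise, TargetProfile, profile_from_structure

__all__ = [
    "FixtureSpec",
    "SyntheticTarget",
    "build_native",
    "make_decoys",
    "make_raw_scores",
    "make_target",
    "random_layout",
    "generate_benchmark",
]

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST = np.radians(100.0)
STRAND_RISE = 3.1
STRAND_PLEAT = 1.1
SPACING = {("E", "E"): 4.9, ("H", "H"): 9.8, ("H", "E"): 9.0, ("E", "H"): 9.0}
CA_BOND = 3.8

HYDROPHOBIC_CYCLE = "LVIFMA"
POLAR_CYCLE = "EKSQNTDR"
LOOP_CYCLE = "GSNP"

#: Default torsion-noise grades (radians), cycled over the decoys of a pool;
#: grade 0 would reproduce the native.  The mix is weighted toward heavy
#: perturbation so that native-like models (TM > 0.4) are a minority of each
#: pool, as in a low-confidence threading search space.
DEFAULT_GRADES = (0.1, 0.9, 1.5, 0.6, 0.25, 1.1, 1.7, 0.7, 1.3, 1.0)
PERTURB_FRACTION = 0.35

#: Default raw-score model S = RAW_SCALE * TM + N(0, z_noise).  The default
#: noise makes the raw threading score only weakly informative (selecting by
#: Z-score finds a native-like top model for well under 60% of targets),
#: emulating the dawn region.
RAW_SCALE = 10.0
DEFAULT_Z_NOISE = 9.0


@dataclass
class FixtureSpec:
    """Conditions for one generated benchmark."""

    n_targets: int = 50
    decoys_per_target: int = 50
    grades: tuple = DEFAULT_GRADES
    noise: ProfileNoise = field(default_factory=ProfileNoise)
    z_noise: float = DEFAULT_Z_NOISE
    seed: int = 0

    def __post_init__(self):
        if self.decoys_per_target < 2:
            raise ValueError("need at least 2 decoys per target")


@dataclass
class SyntheticTarget:
    target_id: str
    native: StructureModel
    profile: TargetProfile
    decoys: list[StructureModel]
    tm_labels: np.ndarray
    raw_scores: np.ndarray


def _parse_layout(layout) -> list[tuple[str, int]]:
    parsed = []
    for item in layout:
        if isinstance(item, str):
            kind, length = item[0].upper(), int(item[1:])
        else:
            kind, length = item
        if kind not in "HE":
            raise ValueError(f"SSE kind must be H or E, got {kind!r}")
        if length < 4:
            raise ValueError(f"SSE length must be >= 4, got {length}")
        parsed.append((kind, int(length)))
    if not parsed:
        raise ValueError("layout must not be empty")
    return parsed


def _sse_coords(kind: str, length: int, x0: float, up: bool) -> np.ndarray:
    """Ideal CA coordinates of one SSE along +/-z at lateral offset x0."""
    t = np.arange(length, dtype=float)
    rise = HELIX_RISE if kind == "H" else STRAND_RISE
    z = rise * t if up else rise * (length - 1 - t)
    if kind == "H":
        # keep the helix right-handed whichever way it runs in z
        sign = 1.0 if up else -1.0
        ca = np.stack(
            [
                x0 + HELIX_RADIUS * np.cos(HELIX_TWIST * t),
                sign * HELIX_RADIUS * np.sin(HELIX_TWIST * t),
                z,
            ],
            axis=1,
        )
    else:
        # pleat along local y, perpendicular to the in-sheet pairing axis (x)
        y = STRAND_PLEAT * np.where(t.astype(int) % 2 == 0, 1.0, -1.0)
        ca = np.stack([np.full(length, x0), y, z], axis=1)
    return ca


def _connect_loop(a: np.ndarray, b: np.ndarray, n_loop: int, bulge_dir: np.ndarray) -> np.ndarray:
    """Loop CAs between fixed anchors a and b with ~3.8 A spacing (FABRIK-style)."""
    pts = np.linspace(a, b, n_loop + 2)[1:-1]
    bulge = max(0.0, (n_loop + 1) * CA_BOND - np.linalg.norm(b - a)) / 2.0
    mid_w = np.sin(np.linspace(0, np.pi, n_loop + 2))[1:-1]
    pts = pts + bulge_dir[None, :] * (bulge * mid_w)[:, None]
    chain = np.vstack([a, pts, b])
    for _ in range(60):
        for i in range(1, len(chain)):  # forward: fix spacing from a
            v = chain[i] - chain[i - 1]
            d = np.linalg.norm(v)
            if d > 1e-9:
                chain[i] = chain[i - 1] + v / d * CA_BOND
        chain[-1] = b
        for i in range(len(chain) - 2, -1, -1):  # backward: fix from b
            v = chain[i] - chain[i + 1]
            d = np.linalg.norm(v)
            if d > 1e-9:
                chain[i] = chain[i + 1] + v / d * CA_BOND
        chain[0] = a
    return chain[1:-1]


def _residues_from_trace(ca: np.ndarray, sequence: str, model_id: str) -> StructureModel:
    """Residues with SCMs placed along pseudo-CB directions at per-type distances."""
    dirs = pseudo_cb_directions(ca)
    residues = []
    for i, aa in enumerate(sequence):
        dist = SCM_DISTANCE.get(aa, SCM_DISTANCE["X"])
        scm = ca[i] + dirs[i] * dist if dist > 0 else ca[i].copy()
        residues.append(Residue(index=i + 1, aa=aa, ca=ca[i].copy(), scm=scm))
    return StructureModel(model_id=model_id, residues=residues)


def build_native(layout, seed: int = 0, model_id: str = "native") -> StructureModel:
    """Build an idealized annotated native fold from an SSE layout.

    ``layout`` is a list like ``["H8", "E5", "E5", "H10"]``.  SSEs are packed
    side by side along x (consecutive strands at sheet-pairing distance,
    helices further apart), alternate running up/down in z so loops stay
    short, and get sequences whose inward-facing residues are hydrophobic.
    Deterministic given the seed (used only for a tiny coordinate jitter).
    """
    parsed = _parse_layout(layout)
    rng = np.random.default_rng(seed)

    # Group consecutive strands into rigid sheet blocks (strands paired at
    # sheet distance with parallel pleats); each helix is its own block.
    groups: list[list[int]] = []
    for k, (kind, _) in enumerate(parsed):
        if kind == "E" and groups and parsed[groups[-1][-1]][0] == "E":
            groups[-1].append(k)
        else:
            groups.append([k])

    group_blocks = []  # local coordinates, laid out along local +x
    group_widths = []
    for members in groups:
        parts = []
        x_local = 0.0
        for j, k in enumerate(members):
            kind, length = parsed[k]
            if j > 0:
                x_local += SPACING[("E", "E")]
            parts.append((k, _sse_coords(kind, length, x_local, up=(k % 2 == 0))))
        group_blocks.append(parts)
        group_widths.append(x_local)

    # Bend the chain of blocks along an arc in the xy-plane so the fold is
    # globular rather than a flat sheet of elements.  Within-block geometry
    # is preserved exactly (rigid placement).
    arcs = [0.0]
    for g in range(1, len(groups)):
        ka = parsed[groups[g - 1][-1]][0]
        kb = parsed[groups[g][0]][0]
        arcs.append(arcs[-1] + group_widths[g - 1] + SPACING[(ka, kb)])
    total = arcs[-1] + group_widths[-1]
    radius = max(total / (1.2 * np.pi), 7.0)

    blocks: list[np.ndarray | None] = [None] * len(parsed)
    for g, parts in enumerate(group_blocks):
        theta = arcs[g] / radius
        phi = theta + np.pi / 2.0  # local +x along the arc tangent
        rot = np.array(
            [
                [np.cos(phi), -np.sin(phi), 0.0],
                [np.sin(phi), np.cos(phi), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        centre = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        for k, block in parts:
            blocks[k] = block @ rot.T + centre

    # Chain them with adaptive loops.
    ca_parts = [blocks[0]]
    sse_ranges = [(0, len(blocks[0]) - 1, parsed[0][0])]
    n_done = len(blocks[0])
    for k in range(1, len(blocks)):
        a = ca_parts[-1][-1]
        b = blocks[k][0]
        gap = np.linalg.norm(b - a)
        n_loop = int(np.clip(np.ceil(gap / 3.5), 3, 8))
        bulge_dir = np.array([0.0, 0.0, 1.0]) if a[2] > (blocks[k][:, 2].mean()) else np.array([0.0, 0.0, -1.0])
        loop = _connect_loop(a, b, n_loop, bulge_dir)
        ca_parts.append(loop)
        ca_parts.append(blocks[k])
        start = n_done + n_loop
        sse_ranges.append((start, start + len(blocks[k]) - 1, parsed[k][0]))
        n_done = start + len(blocks[k])
    ca = np.vstack(ca_parts)
    ca = ca + rng.normal(0.0, 0.03, size=ca.shape)

    # Sequence: SSE residues whose side chain faces the fold centre are
    # hydrophobic, the rest polar; loops cycle through small polar types.
    n = len(ca)
    in_sse = np.zeros(n, dtype=bool)
    for s, e, _ in sse_ranges:
        in_sse[s : e + 1] = True
    dirs = pseudo_cb_directions(ca)
    centroid = ca.mean(axis=0)
    seq = []
    hydro_i = polar_i = loop_i = 0
    for i in range(n):
        if in_sse[i]:
            toward = np.dot(dirs[i], centroid - ca[i])
            if toward > 0:
                seq.append(HYDROPHOBIC_CYCLE[hydro_i % len(HYDROPHOBIC_CYCLE)])
                hydro_i += 1
            else:
                seq.append(POLAR_CYCLE[polar_i % len(POLAR_CYCLE)])
                polar_i += 1
        else:
            seq.append(LOOP_CYCLE[loop_i % len(LOOP_CYCLE)])
            loop_i += 1
    model = _residues_from_trace(ca, "".join(seq), model_id)
    return annotate(model)


def make_decoys(
    native: StructureModel,
    grades=DEFAULT_GRADES,
    n: int = 50,
    seed: int = 0,
    perturb_fraction: float = PERTURB_FRACTION,
):
    """Graded torsion-space decoys of a native fold, with TM labels.

    Decoy d uses grade ``grades[d % len(grades)]`` as the standard deviation
    of Gaussian noise added to the virtual torsions (and, at a quarter of the
    magnitude, bond angles) of a random ``perturb_fraction`` of positions of
    the CA trace; the trace is then rebuilt and side-chain centroids are
    replaced at ideal offsets.  Grade 0 returns the native coordinates
    unchanged.  Returns ``(decoys, tm_labels)``.
    """
    if n < 2:
        raise ValueError("need n >= 2 decoys")
    rng = np.random.default_rng(seed)
    ca0 = native.ca_coords
    d, theta, tau = internal_coords(ca0)
    decoys: list[StructureModel] = []
    labels = np.zeros(n)
    for k in range(n):
        grade = float(grades[k % len(grades)])
        model_id = f"decoy_{k:03d}"
        if grade == 0.0:
            decoy = _residues_from_trace(ca0.copy(), native.sequence, model_id)
            # identical coordinates: keep native SCMs too
            for r, rn in zip(decoy.residues, native.residues):
                r.scm = rn.scm.copy()
            labels[k] = 1.0
        else:
            mask_t = rng.random(len(tau)) < perturb_fraction
            tau_p = tau + rng.normal(0.0, grade, size=len(tau)) * mask_t
            mask_a = rng.random(len(theta)) < perturb_fraction
            theta_p = np.clip(
                theta + rng.normal(0.0, grade * 0.25, size=len(theta)) * mask_a, 0.5, np.pi - 0.2
            )
            ca = rebuild_chain(d, theta_p, tau_p)
            decoy = _residues_from_trace(ca, native.sequence, model_id)
            labels[k] = tm_score(decoy, native)
        annotate(decoy)
        decoys.append(decoy)
    return decoys, labels


def make_raw_scores(tm_labels, z_noise: float, seed: int = 0, scale: float = RAW_SCALE) -> np.ndarray:
    """Raw threading-like scores S = scale * TM + N(0, z_noise)."""
    if z_noise < 0:
        raise ValueError("z_noise must be >= 0")
    rng = np.random.default_rng(seed)
    tm = np.asarray(tm_labels, dtype=float)
    return scale * tm + rng.normal(0.0, z_noise, size=len(tm))


_LAYOUT_POOL = [
    ["H10", "H9", "H11", "H8"],
    ["E5", "E6", "E5", "H10", "H9"],
    ["H11", "E5", "E5", "H9"],
    ["E6", "E5", "E6", "E5"],
    ["H9", "H10", "E5", "E5", "H8"],
    ["H12", "H10", "H9"],
    ["E5", "E5", "H12", "E5", "E6"],
    ["H10", "E6", "E6", "H10", "H8"],
]


def random_layout(rng: np.random.Generator) -> list[str]:
    """A layout drawn from a pool of mixed-architecture folds, with jittered lengths."""
    base = _LAYOUT_POOL[int(rng.integers(len(_LAYOUT_POOL)))]
    out = []
    for item in base:
        kind, length = item[0], int(item[1:])
        out.append(f"{kind}{max(4, length + int(rng.integers(-1, 2)))}")
    return out


def make_target(
    target_id: str,
    layout,
    seed: int,
    decoys_per_target: int = 50,
    grades=DEFAULT_GRADES,
    noise: ProfileNoise | None = None,
    z_noise: float = DEFAULT_Z_NOISE,
) -> SyntheticTarget:
    """Build one complete benchmark target: native, noisy profile, decoys,
    TM labels and raw threading scores."""
    rng = np.random.default_rng(seed)
    s_nat, s_prof, s_dec, s_raw = rng.integers(2**31, size=4)
    native = build_native(layout, seed=int(s_nat))
    profile = profile_from_structure(native, noise=noise, seed=int(s_prof))
    decoys, labels = make_decoys(native, grades=grades, n=decoys_per_target, seed=int(s_dec))
    raw = make_raw_scores(labels, z_noise=z_noise, seed=int(s_raw))
    return SyntheticTarget(target_id, native, profile, decoys, labels, raw)


def generate_benchmark(spec: FixtureSpec) -> list[SyntheticTarget]:
    """Generate ``spec.n_targets`` independent targets from one master seed."""
    rng = np.random.default_rng(spec.seed)
    targets = []
    for t in range(spec.n_targets):
        layout = random_layout(rng)
        seed = int(rng.integers(2**31))
        targets.append(
            make_target(
                f"target_{t:03d}",
                layout,
                seed=seed,
                decoys_per_target=spec.decoys_per_target,
                grades=spec.grades,
                noise=spec.noise,
                z_noise=spec.z_noise,
            )
        )
    return targets
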