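"""Structure-model I/O and per-residue structural annotation.

Reads PDB models (via Biopython), derives the side-chain centre of mass
(SCM) per residue, assigns 3-state secondary structure and 2-state relative
solvent accessibility from geometry, and computes SCM contact maps with the
sequence-separation band (|i-j| >= 6) used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .geometry import pseudo_cb_directions, virtual_torsions

__all__ = [
    "Residue",
    "StructureModel",
    "ContactMap",
    "read_pdb",
    "write_pdb",
    "assign_ss",
    "assign_rsa",
    "annotate",
    "contact_map",
    "radius_of_gyration",
    "apply_dssp",
    "write_contact_map",
    "MIN_SEPARATION",
]

#: Minimum sequence separation for any residue-residue contact.
MIN_SEPARATION = 6

#: Distance (A) from CA to the side-chain centroid, by residue type.  Used
#: when models are built or rebuilt from a CA trace; parsed models take the
#: actual mean of side-chain heavy atoms instead.
SCM_DISTANCE = {
    "G": 0.0, "A": 1.5, "S": 1.9, "C": 2.0, "P": 1.9, "T": 1.9, "V": 2.0,
    "N": 2.5, "D": 2.5, "I": 2.3, "L": 2.6, "M": 2.9, "E": 3.1, "Q": 3.1,
    "H": 3.2, "K": 3.5, "F": 3.4, "R": 4.1, "Y": 3.8, "W": 3.9, "X": 2.4,
}

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_CHAIN_BREAK_CA = 4.5  # A


@dataclass
class Residue:
    """One residue of a structure model (coordinates in Angstrom)."""

    index: int  # 1-based position after re-indexing
    aa: str  # one-letter code
    ca: np.ndarray
    scm: np.ndarray
    n: np.ndarray | None = None
    c: np.ndarray | None = None
    o: np.ndarray | None = None
    ss_state: str | None = None  # H / E / C
    rsa_state: str | None = None  # exposed / buried


@dataclass
class StructureModel:
    model_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def scm_coords(self) -> np.ndarray:
        return np.array([r.scm for r in self.residues], dtype=float)

    @property
    def ss_string(self) -> str:
        if any(r.ss_state is None for r in self.residues):
            raise ValueError("secondary structure not assigned; call annotate()")
        return "".join(r.ss_state for r in self.residues)

    @property
    def rsa_string(self) -> str:
        if any(r.rsa_state is None for r in self.residues):
            raise ValueError("solvent accessibility not assigned; call annotate()")
        return "".join("e" if r.rsa_state == "exposed" else "b" for r in self.residues)


@dataclass
class ContactMap:
    """Symmetric binary contact indicator over residue pairs with |i-j| >= 6."""

    threshold: float
    matrix: np.ndarray  # (n, n) int8


def _scm_from_biopdb_residue(bio_res, ca: np.ndarray) -> np.ndarray:
    side = []
    for atom in bio_res.get_unpacked_list():
        name = atom.get_name()
        if name in _BACKBONE_ATOMS or atom.element == "H":
            continue
        side.append(atom.get_coord())
    if not side:
        return ca.copy()
    return np.mean(np.asarray(side, dtype=float), axis=0)


def read_pdb(path, model_id: str | None = None) -> StructureModel:
    """Parse the first chain of a PDB file into a StructureModel.

    Hetero residues and waters are skipped (MSE is treated as MET);
    insertion codes are collapsed by re-indexing residues 1..n in file
    order; for disordered atoms the highest-occupancy conformer is kept.
    Residues without a CA atom are rejected with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("m", str(path))
    model = next(iter(structure))
    chain = next(iter(model))
    residues: list[Residue] = []
    for bio_res in chain:
        hetflag, _resseq, _icode = bio_res.get_id()
        resname = bio_res.get_resname().strip()
        if hetflag.strip() and resname != "MSE":
            continue
        if resname == "MSE":
            aa = "M"
        else:
            aa = protein_letters_3to1.get(resname, "X")
        if "CA" not in bio_res:
            warnings.warn(f"residue {resname} {_resseq}: no CA atom, skipped")
            continue

        def coord(name):
            if name not in bio_res:
                return None
            atom = bio_res[name]
            if atom.is_disordered():
                atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0)
            return np.asarray(atom.get_coord(), dtype=float)

        ca = coord("CA")
        residues.append(
            Residue(
                index=len(residues) + 1,
                aa=aa,
                ca=ca,
                scm=_scm_from_biopdb_residue(bio_res, ca),
                n=coord("N"),
                c=coord("C"),
                o=coord("O"),
            )
        )
    if not residues:
        raise ValueError(f"{path}: no protein residues with CA atoms found")
    return StructureModel(model_id=model_id or str(path), residues=residues)


_ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items()}


def write_pdb(model: StructureModel, path) -> None:
    """Write a model as PDB ATOM records (CA plus a CB pseudo-atom at the SCM)."""
    lines = []
    serial = 1
    for r in model.residues:
        res3 = _ONE_TO_THREE.get(r.aa, "UNK")
        for name, xyz in (("CA", r.ca), ("CB", r.scm)):
            if name == "CB" and r.aa == "G":
                continue
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3:>3s} A{r.index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _chain_breaks(ca: np.ndarray) -> np.ndarray:
    """Boolean mask over bonds i -> i+1 marking CA-CA breaks (> 4.5 A)."""
    if len(ca) < 2:
        return np.zeros(0, dtype=bool)
    return np.linalg.norm(ca[1:] - ca[:-1], axis=1) > _CHAIN_BREAK_CA


def assign_ss(model: StructureModel) -> StructureModel:
    """Assign 3-state secondary structure from CA-trace geometry (in place).

    Helix: runs of at least two consecutive 4-residue windows whose virtual
    torsion and CA(i)-CA(i+3) distance match helical geometry.  Strand: a
    residue in a locally extended window that is spatially paired with
    another extended residue (|i-j| >= 3, CA within 5.5 A) supported by a
    neighbouring rung (ladder of length >= 2).  Everything else is coil;
    residues flanking a chain break (CA-CA > 4.5 A) are forced to coil.
    """
    n = model.length
    ca = model.ca_coords
    states = ["C"] * n
    if n >= 4:
        tau = np.degrees(virtual_torsions(ca))
        breaks = _chain_breaks(ca)

        def window_broken(i):
            return bool(breaks[i : i + 3].any())

        d13 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
        helix_win = [
            (30.0 <= tau[i] <= 80.0) and (4.2 <= d13[i] <= 6.5) and not window_broken(i)
            for i in range(n - 3)
        ]
        # helix: >=2 consecutive helical windows
        i = 0
        while i < n - 3:
            if helix_win[i]:
                j = i
                while j < n - 3 and helix_win[j]:
                    j += 1
                if j - i >= 2:
                    for k in range(i, j + 3):
                        states[k] = "H"
                i = j
            else:
                i += 1

        # strand: extended windows + spatial pairing ladder
        d02 = np.linalg.norm(ca[2:] - ca[:-2], axis=1)
        extended = np.zeros(n, dtype=bool)
        for i in range(n - 3):
            if abs(tau[i]) >= 140.0 and d02[i] >= 6.0 and d02[i + 1] >= 6.0 and not window_broken(i):
                extended[i : i + 4] = True
        if extended.any():
            dmat = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
            sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
            pair = extended[:, None] & extended[None, :] & (sep >= 3) & (dmat <= 5.5)

            def p(i, j):
                return 0 <= i < n and 0 <= j < n and pair[i, j]

            for i in range(n):
                if states[i] == "H":
                    continue
                for j in np.nonzero(pair[i])[0]:
                    if (
                        p(i + 1, j + 1) or p(i + 1, j - 1)
                        or p(i - 1, j - 1) or p(i - 1, j + 1)
                    ):
                        states[i] = "E"
                        break

        for b in np.nonzero(breaks)[0]:
            states[b] = "C"
            states[b + 1] = "C"

    for r, s in zip(model.residues, states):
        r.ss_state = s
    return model


#: Neighbour counting parameters of the burial proxy.
RSA_NEIGHBOR_RADIUS = 10.0  # A, around the SCM
RSA_MAX_NEIGHBORS = 14.0  # neighbour count mapped to fully buried


def assign_rsa(model: StructureModel, threshold: float = 0.25) -> StructureModel:
    """Assign 2-state relative solvent accessibility (in place).

    Relative accessibility is estimated from a neighbour-count burial proxy:
    ``rsa_i = max(0, 1 - n_i / 14)`` with ``n_i`` the number of other SCMs
    within 10 A of SCM i.  A residue is exposed iff ``rsa_i >= threshold``
    (default 25%), so a threshold of 0 marks every residue exposed.
    """
    scm = model.scm_coords
    n = model.length
    if n == 1:
        counts = np.zeros(1)
    else:
        d = np.linalg.norm(scm[:, None, :] - scm[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        counts = (d <= RSA_NEIGHBOR_RADIUS).sum(axis=1)
    rsa = np.maximum(0.0, 1.0 - counts / RSA_MAX_NEIGHBORS)
    for r, v in zip(model.residues, rsa):
        r.rsa_state = "exposed" if v >= threshold else "buried"
    return model


def annotate(model: StructureModel, rsa_threshold: float = 0.25) -> StructureModel:
    """Assign both secondary structure and solvent accessibility."""
    assign_ss(model)
    assign_rsa(model, threshold=rsa_threshold)
    return model


def contact_map(model: StructureModel, threshold: float) -> ContactMap:
    """Binary SCM contact map: N_ij = 1 iff |i-j| >= 6 and ||scm_i - scm_j|| < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = model.length
    scm = model.scm_coords
    mat = np.zeros((n, n), dtype=np.int8)
    if n > MIN_SEPARATION:
        d = np.linalg.norm(scm[:, None, :] - scm[None, :, :], axis=2)
        sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        mat = ((d < threshold) & (sep >= MIN_SEPARATION)).astype(np.int8)
    return ContactMap(threshold=float(threshold), matrix=mat)


def radius_of_gyration(model: StructureModel) -> float:
    """Mass-unweighted RMS distance of CA atoms from their centroid (A)."""
    ca = model.ca_coords
    if len(ca) == 0:
        raise ValueError("empty model")
    centroid = ca.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((ca - centroid) ** 2, axis=1))))


#: Tien et al. theoretical maximum accessible surface areas (A^2), used to
#: turn DSSP absolute accessibility into relative accessibility.
_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0, "E": 223.0,
    "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0, "L": 201.0, "K": 236.0,
    "M": 224.0, "F": 240.0, "P": 159.0, "S": 155.0, "T": 172.0, "W": 285.0,
    "Y": 263.0, "V": 174.0, "X": 200.0,
}

_DSSP_TO_3STATE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "C",
                   "T": "C", "S": "C", " ": "C", "-": "C"}


def apply_dssp(model: StructureModel, path, threshold: float = 0.25) -> StructureModel:
    """Apply SS/RSA states from a precomputed DSSP output file (in place).

    Accepts classic DSSP text output; the 8-state code is collapsed to
    3 states (helix classes -> H, extended strand -> E, everything else
    including isolated bridges -> C) and the ACC column is converted to
    relative accessibility via theoretical maximum areas, thresholded at
    ``threshold``.  Rows are matched to residues in order; a row count
    mismatch raises an error.
    """
    rows = []
    with open(path) as fh:
        in_table = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 38:
                continue
            aa = line[13]
            if aa == "!":  # chain break record
                continue
            ss = line[16]
            acc = float(line[34:38])
            rows.append((aa, ss, acc))
    if len(rows) != model.length:
        raise ValueError(
            f"{path}: {len(rows)} DSSP rows for a {model.length}-residue model"
        )
    for r, (aa, ss, acc) in zip(model.residues, rows):
        r.ss_state = _DSSP_TO_3STATE.get(ss, "C")
        rel = acc / _MAX_ASA.get(aa.upper(), _MAX_ASA["X"])
        r.rsa_state = "exposed" if rel >= threshold else "buried"
    return model


def write_contact_map(cmap: ContactMap, path) -> None:
    """Write a contact map as 1-based "i j value" triples (upper triangle, nonzero)."""
    n = cmap.matrix.shape[0]
    with open(path, "w") as fh:
        for i in range(n):
            for j in range(i + 1, n):
                if cmap.matrix[i, j]:
                    fh.write(f"{i + 1} {j + 1} {int(cmap.matrix[i, j])}\n")
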