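"""Sequence-side target predictions: secondary structure, accessibility and
residue-residue contact probabilities at the two distance classes.

A :class:`TargetProfile` is what the feature extractor compares a structure
model against.  Profiles can be read from plain-text prediction files or
synthesized from an annotated native structure with controlled noise (the
stand-in for an external predictor when benchmarking on generated folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .io_structures import MIN_SEPARATION, StructureModel, contact_map

__all__ = ["TargetProfile", "ProfileNoise", "read_profile", "write_profile", "profile_from_structure"]

_SS_STATES = "HEC"


@dataclass
class TargetProfile:
    sequence: str
    ss_pred: str  # per-residue H/E/C
    rsa_pred: str  # per-residue e/b
    contact_prob_8: np.ndarray  # symmetric, in [0,1], zero inside |i-j| < 6
    contact_prob_12: np.ndarray

    def __len__(self) -> int:
        return len(self.sequence)

    def contact_prob(self, threshold: float) -> np.ndarray:
        if threshold <= 10.0:
            return self.contact_prob_8
        return self.contact_prob_12

    def validate(self) -> "TargetProfile":
        n = len(self.sequence)
        if len(self.ss_pred) != n:
            raise ValueError("ss_pred length does not match sequence")
        if len(self.rsa_pred) != n:
            raise ValueError("rsa_pred length does not match sequence")
        if set(self.ss_pred) - set(_SS_STATES):
            raise ValueError("ss_pred must contain only H/E/C")
        if set(self.rsa_pred) - set("eb"):
            raise ValueError("rsa_pred must contain only e/b")
        for name in ("contact_prob_8", "contact_prob_12"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} has shape {m.shape}, expected ({n}, {n})")
            if (m < 0).any() or (m > 1).any():
                raise ValueError(f"{name} has entries outside [0, 1]")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} is not symmetric")
            sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
            if m[sep < MIN_SEPARATION].any():
                raise ValueError(f"{name} has nonzero entries at separation < {MIN_SEPARATION}")
        return self


def _read_single_line(path, what: str) -> str:
    with open(path) as fh:
        content = "".join(line.strip() for line in fh if line.strip() and not line.startswith(">"))
    if not content:
        raise ValueError(f"{path}: empty {what} file")
    return content


def _read_contact_file(path, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    banded_dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 'i j p' triple")
            i, j, p = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{path}:{ln}: residue index out of range for length {n}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{path}:{ln}: probability {p} outside [0, 1]")
            if abs(i - j) < MIN_SEPARATION:
                banded_dropped += 1
                continue
            m[i, j] = p
            m[j, i] = p
    if banded_dropped:
        warnings.warn(
            f"{path}: dropped {banded_dropped} contact entries at separation < {MIN_SEPARATION}"
        )
    return m


def read_profile(seq_path, ss_path, rsa_path, cmap8_path, cmap12_path) -> TargetProfile:
    """Load a target profile from FASTA + SS line + RSA line + two contact files.

    Contact files hold whitespace-separated 1-based ``i j p`` triples (upper
    triangle is sufficient).  Entries inside the separation band are zeroed
    with a warning; any length mismatch raises an error naming the file.
    """
    record = next(SeqIO.parse(str(seq_path), "fasta"))
    sequence = str(record.seq)
    n = len(sequence)
    ss = _read_single_line(ss_path, "secondary structure")
    if len(ss) != n:
        raise ValueError(f"{ss_path}: {len(ss)} states for a {n}-residue sequence")
    rsa = _read_single_line(rsa_path, "accessibility")
    if len(rsa) != n:
        raise ValueError(f"{rsa_path}: {len(rsa)} states for a {n}-residue sequence")
    c8 = _read_contact_file(cmap8_path, n)
    c12 = _read_contact_file(cmap12_path, n)
    return TargetProfile(sequence, ss, rsa, c8, c12).validate()


def write_profile(profile: TargetProfile, seq_path, ss_path, rsa_path, cmap8_path, cmap12_path,
                  target_id: str = "target") -> None:
    """Write a profile in the text formats accepted by :func:`read_profile`."""
    with open(seq_path, "w") as fh:
        fh.write(f">{target_id}\n{profile.sequence}\n")
    with open(ss_path, "w") as fh:
        fh.write(profile.ss_pred + "\n")
    with open(rsa_path, "w") as fh:
        fh.write(profile.rsa_pred + "\n")
    for path, m in ((cmap8_path, profile.contact_prob_8), (cmap12_path, profile.contact_prob_12)):
        n = m.shape[0]
        with open(path, "w") as fh:
            for i in range(n):
                for j in range(i + 1, n):
                    if m[i, j] > 0:
                        fh.write(f"{i + 1} {j + 1} {m[i, j]:.6f}\n")


@dataclass
class ProfileNoise:
    """Error model of the synthetic predictor.

    Defaults emulate a realistic sequence-based predictor: ~80% 3-state
    secondary-structure accuracy, ~80% 2-state accessibility accuracy, and
    contact probabilities that are the true contacts with 15% of true
    contacts attenuated, a 3% background probability on non-contacts, and
    Gaussian jitter (sd 0.05).
    """

    ss_flip: float = 0.20
    rsa_flip: float = 0.20
    contact_miss: float = 0.15  # epsilon: attenuation of true contacts
    contact_fp: float = 0.03  # beta: background level on non-contacts
    contact_sigma: float = 0.05  # additive Gaussian noise

    @classmethod
    def zero(cls) -> "ProfileNoise":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


def _noisy_contacts(nmat: np.ndarray, noise: ProfileNoise, rng: np.random.Generator) -> np.ndarray:
    n = nmat.shape[0]
    nmat = nmat.astype(float)
    c = nmat * (1.0 - noise.contact_miss) + (1.0 - nmat) * noise.contact_fp
    if noise.contact_sigma > 0:
        g = rng.normal(0.0, noise.contact_sigma, size=(n, n))
        c = c + np.triu(g, 1) + np.triu(g, 1).T
    c = np.clip(c, 0.0, 1.0)
    c = (c + c.T) / 2.0
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    c[sep < MIN_SEPARATION] = 0.0
    return c


def profile_from_structure(
    native: StructureModel,
    noise: ProfileNoise | None = None,
    seed: int = 0,
) -> TargetProfile:
    """Synthesize a target profile from an annotated native structure.

    SS and RSA states are copied from the native annotation and flipped
    independently with the configured error rates; contact probabilities are
    the smoothed true contact maps.  Reproducible given the seed.
    """
    if noise is None:
        noise = ProfileNoise()
    rng = np.random.default_rng(seed)
    n = native.length
    ss = list(native.ss_string)
    for i in range(n):
        if noise.ss_flip > 0 and rng.random() < noise.ss_flip:
            ss[i] = rng.choice([s for s in _SS_STATES if s != ss[i]])
    rsa = list(native.rsa_string)
    for i in range(n):
        if noise.rsa_flip > 0 and rng.random() < noise.rsa_flip:
            rsa[i] = "e" if rsa[i] == "b" else "b"
    c8 = _noisy_contacts(contact_map(native, 8.0).matrix, noise, rng)
    c12 = _noisy_contacts(contact_map(native, 12.0).matrix, noise, rng)
    return TargetProfile(native.sequence, "".join(ss), "".join(rsa), c8, c12).validate()
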