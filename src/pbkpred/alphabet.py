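"""The 16-letter Protein Blocks (PB) structural alphabet.

Protein Blocks are 16 canonical five-residue backbone conformations,
labelled ``a`` through ``p``, each defined by a prototype vector of 8
backbone dihedral angles ordered

    (psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2))

for a pentapeptide centred on residue *i*.  PBs *m* and *d* correspond
roughly to the cores of alpha-helices and beta-strands.  A residue is
assigned the PB whose prototype minimises the RMSDA (root mean square
deviation on angular values) to the observed 8-dihedral window; the two
residues at each chain terminus, and any residue whose window contains an
undefined dihedral, receive the placeholder letter ``Z``.

The prototype table is shipped as packaged TSV data and treated as
configuration: an alternative table can be supplied to every function that
takes an ``alphabet`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

#: the 16 PB letters, in canonical (alphabetical) order
PB_LETTERS: str = "abcdefghijklmnop"

#: placeholder for residues with no assigned / predictable PB
UNASSIGNED: str = "Z"

#: number of dihedral angles in a pentapeptide window
WINDOW_ANGLES: int = 8


def normalize_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = (a + 180.0) % 360.0 - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def angular_difference(a, b):
    """Signed minimal circular difference ``a - b`` in degrees.

    Returns d in (-180, 180] such that a == b + d (mod 360); |d| is the
    minimal separation on the circle.  Accepts scalars or arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("angular_difference requires finite angles")
    return normalize_angle(a - b)


@dataclass(frozen=True)
class PBDefinition:
    """One structural prototype: a PB letter and its 8 standard dihedrals."""

    letter: str
    standard_dihedrals: np.ndarray  # shape (8,), degrees, in (-180, 180]

    def __post_init__(self):
        if self.letter not in PB_LETTERS:
            raise ValueError(f"PB letter must be one of {PB_LETTERS!r}: {self.letter!r}")
        angles = np.asarray(self.standard_dihedrals, dtype=float)
        if angles.shape != (WINDOW_ANGLES,):
            raise ValueError("a PB prototype has exactly 8 dihedral angles")
        object.__setattr__(self, "standard_dihedrals", normalize_angle(angles))


@dataclass(frozen=True)
class DihedralVector:
    """An 8-dihedral pentapeptide window; NaN marks undefined angles."""

    angles: np.ndarray  # shape (8,), degrees; NaN where undefined

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float)
        if angles.shape != (WINDOW_ANGLES,):
            raise ValueError("a dihedral window has exactly 8 angles")
        defined = ~np.isnan(angles)
        out = angles.copy()
        out[defined] = normalize_angle(angles[defined])
        object.__setattr__(self, "angles", out)

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.angles)

    @property
    def is_complete(self) -> bool:
        return bool(self.defined_mask.all())


def load_prototypes(path=None) -> dict[str, PBDefinition]:
    """Load the PB prototype table (packaged canonical table by default).

    The TSV has one row per PB letter and 8 angle columns in window order.
    """
    if path is None:
        source = resources.files("pbkpred.data").joinpath("pb_prototypes.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    defs: dict[str, PBDefinition] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pb\t"):
            continue
        fields = line.split("\t")
        letter = fields[0]
        angles = np.array([float(x) for x in fields[1:9]])
        defs[letter] = PBDefinition(letter, angles)
    if sorted(defs) != list(PB_LETTERS):
        raise ValueError("prototype table must define exactly the letters a-p")
    return defs


_CANONICAL: dict[str, PBDefinition] | None = None


def canonical_alphabet() -> dict[str, PBDefinition]:
    """The packaged canonical 16-PB prototype table (cached)."""
    global _CANONICAL
    if _CANONICAL is None:
        _CANONICAL = load_prototypes()
    return _CANONICAL


def _prototype_matrix(alphabet: Mapping[str, PBDefinition]) -> np.ndarray:
    return np.stack([alphabet[c].standard_dihedrals for c in PB_LETTERS])


def _as_angles(v) -> np.ndarray:
    if isinstance(v, DihedralVector):
        return v.angles
    return DihedralVector(np.asarray(v, dtype=float)).angles


def rmsda(v1, v2) -> float:
    """Root mean square deviation on angular values between two 8-windows.

    Angular differences are wrapped to the minimal circular separation.
    Both windows must be fully defined.
    """
    a1, a2 = _as_angles(v1), _as_angles(v2)
    if np.isnan(a1).any() or np.isnan(a2).any():
        raise ValueError("rmsda requires fully defined dihedral windows")
    d = angular_difference(a1, a2)
    return float(np.sqrt(np.mean(d * d)))


def assign_pb(v, alphabet: Mapping[str, PBDefinition] | None = None) -> str:
    """Assign the PB whose prototype has minimal RMSDA to window ``v``.

    Ties (equal RMSDA, measure-zero in practice) resolve to the
    alphabetically smallest letter.
    """
    angles = _as_angles(v)
    if np.isnan(angles).any():
        raise ValueError("cannot assign a PB to an incomplete dihedral window")
    protos = _prototype_matrix(alphabet or canonical_alphabet())
    d = normalize_angle(angles[None, :] - protos)
    scores = np.sqrt(np.mean(d * d, axis=1))
    return PB_LETTERS[int(np.argmin(scores))]  # argmin -> first = alphabetical


def encode_chain(
    phi: Sequence[float],
    psi: Sequence[float],
    alphabet: Mapping[str, PBDefinition] | None = None,
) -> str:
    """Encode a chain's per-residue phi/psi series as a PB string.

    ``phi[i]``/``psi[i]`` are degrees, NaN where undefined (termini,
    missing atoms, chain breaks).  Residue *i* (0-based, 2 <= i <= L-3)
    is assigned via its 8-angle window; the first two, last two, and any
    residue whose window touches an undefined angle get ``Z``.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be 1-D series of equal length")
    n = len(phi)
    if n < 5:
        warnings.warn(f"chain of length {n} < 5: no PB can be assigned", stacklevel=2)
        return UNASSIGNED * n
    out = [UNASSIGNED] * n
    for i in range(2, n - 2):
        window = np.array(
            [
                psi[i - 2],
                phi[i - 1],
                psi[i - 1],
                phi[i],
                psi[i],
                phi[i + 1],
                psi[i + 1],
                phi[i + 2],
            ]
        )
        if np.isnan(window).any():
            continue
        out[i] = assign_pb(window, alphabet)
    return "".join(out)
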