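"""Backbone geometry: PDB reading, phi/psi dihedrals, and reconstruction.

Only the three backbone atoms N, CA, C per residue are handled.  Dihedrals
are computed internally (no external DSSP-style dependency); definitions
are the standard ones:

    phi(i) = torsion C(i-1)-N(i)-CA(i)-C(i)
    psi(i) = torsion N(i)-CA(i)-C(i)-N(i+1)

A peptide bond with C(i-1)..N(i) distance above 2.5 A is treated as a
chain break, and dihedrals spanning it are undefined (NaN).

``build_backbone`` is the inverse operation used by the synthetic fixture
world: it realises a PB string as 3-D coordinates by sequential
internal-coordinate (NeRF) placement, taking each residue's phi/psi from
the central angles of its PB prototype.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .alphabet import PB_LETTERS, PBDefinition, canonical_alphabet, normalize_angle

log = logging.getLogger(__name__)

#: standard backbone bond lengths, Angstrom
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
#: standard backbone bond angles, degrees
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
#: peptide bond omega (trans)
OMEGA_TRANS = 180.0
#: C(i-1)..N(i) distance above which a chain break is declared, Angstrom
CHAIN_BREAK_CUTOFF = 2.5


@dataclass
class Residue:
    """One residue's backbone atoms; any of N/CA/C may be missing (None)."""

    name: str
    seq_position: int
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None

    @property
    def is_complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None


@dataclass
class BackboneChain:
    """An ordered polypeptide backbone (N/CA/C per residue)."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def parse_structure(
    source,
    model_policy: str = "first",
    altloc_policy: str = "occupancy",
) -> list[BackboneChain]:
    """Parse PDB-format text or a file path into backbone chains.

    Only model 1 is read under the default policy (single-conformation
    encoding); for alternate locations the highest-occupancy conformer is
    kept, ties resolving to altloc 'A' (Biopython's disordered-atom
    selection).  HETATM-only chains are skipped; residues missing any of
    N/CA/C are retained but flagged incomplete so dependent dihedrals
    become undefined.
    """
    if model_policy != "first":
        raise ValueError("only model_policy='first' is supported")
    if altloc_policy != "occupancy":
        raise ValueError("only altloc_policy='occupancy' is supported")
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
        source_id = "<text>"
    else:
        handle = open(source)
        source_id = str(source)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        with handle:
            structure = parser.get_structure("s", handle)
    models = list(structure)
    if not models:
        warnings.warn("no ATOM records found", stacklevel=2)
        return []
    model = models[0]
    chains: list[BackboneChain] = []
    for chain in model:
        residues = []
        for res in chain:
            if res.id[0] != " ":  # HETATM / water
                continue
            r = Residue(name=res.get_resname(), seq_position=res.id[1])
            for attr, atom_name in (("n", "N"), ("ca", "CA"), ("c", "C")):
                if atom_name in res:
                    setattr(r, attr, np.asarray(res[atom_name].get_coord(), dtype=float))
            residues.append(r)
        if residues:
            chains.append(
                BackboneChain(chain_id=chain.id, residues=residues, source_id=source_id)
            )
    if not chains:
        warnings.warn("no polypeptide chains with ATOM records", stacklevel=2)
    return chains


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, in (-180, 180], IUPAC convention.

    Returns NaN for degenerate geometry (coincident consecutive points or
    collinear triples).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9 or np.linalg.norm(b0) < 1e-9 or np.linalg.norm(b2) < 1e-9:
        return float("nan")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        return float("nan")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(normalize_angle(np.degrees(np.arctan2(y, x))))


def phi_psi_series(chain: BackboneChain) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) arrays in degrees; NaN where undefined."""
    n = len(chain)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    res = chain.residues
    for i in range(n):
        if not res[i].is_complete:
            continue
        # linkage to the previous residue, subject to the break criterion
        if i > 0 and res[i - 1].is_complete:
            gap = np.linalg.norm(res[i].n - res[i - 1].c)
            if gap <= CHAIN_BREAK_CUTOFF:
                phi[i] = dihedral(res[i - 1].c, res[i].n, res[i].ca, res[i].c)
        if i + 1 < n and res[i + 1].n is not None:
            gap = np.linalg.norm(res[i + 1].n - res[i].c)
            if gap <= CHAIN_BREAK_CUTOFF:
                psi[i] = dihedral(res[i].n, res[i].ca, res[i].c, res[i + 1].n)
    return phi, psi


def _place_atom(a, b, c, bond_length, bond_angle, torsion) -> np.ndarray:
    """NeRF: place atom d given a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def central_angles(letter: str, alphabet=None) -> tuple[float, float]:
    """The central-residue (phi, psi) pair of a PB prototype."""
    alphabet = alphabet or canonical_alphabet()
    proto = alphabet[letter].standard_dihedrals
    return float(proto[3]), float(proto[4])


def build_backbone(
    pb_string: str,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    alphabet=None,
    residue_names: list[str] | None = None,
    chain_id: str = "A",
) -> BackboneChain:
    """Construct an N/CA/C backbone realising a PB string.

    Residue *i* receives phi/psi equal to the central angles of its PB's
    prototype (plus Gaussian noise of ``noise_sigma`` degrees), the
    standard choice for PB back-mapping since prototypes of adjacent
    overlapping windows agree only approximately.  Placement is sequential
    NeRF with ideal bond lengths/angles and trans peptide bonds.
    Deterministic for a fixed seed.
    """
    if len(pb_string) < 5:
        raise ValueError("a PB string of length >= 5 is required")
    bad = set(pb_string) - set(PB_LETTERS)
    if bad:
        raise ValueError(f"PB string contains letters outside a-p: {sorted(bad)}")
    n_res = len(pb_string)
    rng = np.random.default_rng(seed)
    phis = np.empty(n_res)
    psis = np.empty(n_res)
    for i, letter in enumerate(pb_string):
        phi, psi = central_angles(letter, alphabet)
        phis[i] = phi
        psis[i] = psi
    if noise_sigma > 0:
        phis = phis + rng.normal(0.0, noise_sigma, n_res)
        psis = psis + rng.normal(0.0, noise_sigma, n_res)
    phis[0] = -120.0  # phi(1) has no preceding C; any value, never measured

    names = residue_names or ["ALA"] * n_res
    if len(names) != n_res:
        raise ValueError("residue_names length must match the PB string")

    # seed the first residue in a canonical frame
    coords = [
        np.array([0.0, BOND_N_CA * np.sin(np.radians(ANGLE_N_CA_C)), 0.0]),  # N1
        np.array([0.0, 0.0, 0.0]),  # CA1
        np.array([BOND_CA_C, 0.0, 0.0]),  # C1
    ]
    # atom sequence N,CA,C per residue; torsions: psi places N(i+1),
    # omega places CA(i+1), phi(i+1) places C(i+1)
    for i in range(1, n_res):
        n_new = _place_atom(
            coords[-3], coords[-2], coords[-1], BOND_C_N, ANGLE_CA_C_N, psis[i - 1]
        )
        coords.append(n_new)
        ca_new = _place_atom(
            coords[-3], coords[-2], coords[-1], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS
        )
        coords.append(ca_new)
        c_new = _place_atom(
            coords[-3], coords[-2], coords[-1], BOND_CA_C, ANGLE_N_CA_C, phis[i]
        )
        coords.append(c_new)

    residues = [
        Residue(
            name=names[i],
            seq_position=i + 1,
            n=coords[3 * i],
            ca=coords[3 * i + 1],
            c=coords[3 * i + 2],
        )
        for i in range(n_res)
    ]
    return BackboneChain(chain_id=chain_id, residues=residues, source_id="synthetic")


def write_pdb(chain: BackboneChain, path) -> None:
    """Write a backbone chain as minimal PDB ATOM records."""
    lines = []
    serial = 1
    for res in chain.residues:
        for atom_name, coord in (("N", res.n), ("CA", res.ca), ("C", res.c)):
            if coord is None:
                continue
            # strict PDB columns: name 13-16, resName 18-20, chain 22, seq 23-26
            name_field = (" " + atom_name).ljust(4)
            lines.append(
                f"ATOM  {serial:5d} {name_field} {res.name:<3s} "
                f"{chain.chain_id[:1]}{res.seq_position:4d}    "
                f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom_name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
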