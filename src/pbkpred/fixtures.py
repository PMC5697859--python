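"""Self-contained synthetic test worlds for the whole prediction pipeline.

The generator produces PB strings, backbone structures realising them,
families of homologous chains at controlled sequence identities, and the
matching identity-tier table — everything the knowledge base, predictor
and evaluator consume, with no external data.

PB strings are sampled from a first-order Markov chain whose default
transition weights come from the alphabet itself: a transition x -> y is
allowed when the overlapping parts of the two prototypes' dihedral windows
agree (consecutive windows share six of their eight angles), which mirrors
the fact that most successions of PBs are stereochemically unavailable.
The allowed set is further pruned so that every 5-letter context the chain
can emit is recovered by nearest-prototype assignment with a comfortable
RMSDA margin — making encode(build(s)) == s on interior positions an exact
property at zero noise and a robust one under moderate angular noise.

Homologous chains within a family share the master chain's backbone
coordinates and PB truth while their amino-acid sequences are mutated to
target identities: this isolates the sequence-lookup machinery from
structural divergence (which genuinely confounds even 100%-identity pairs
in real data, but is not what these fixtures test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqUtils import seq3

from .alphabet import PB_LETTERS, canonical_alphabet, encode_chain, normalize_angle
from .pentadb import AA20, THRESHOLDS, TierTable, toy_identity_clusterer
from .structure import BackboneChain, Residue, build_backbone, phi_psi_series, write_pdb

#: RMSDA margin (degrees) required between the true letter and the runner-up
#: for every emittable 5-letter context; generous enough for sigma ~ 5 noise
_CONTEXT_MARGIN = 12.0
#: shift-compatibility cutoff (degrees) for candidate transitions
_SHIFT_CUTOFF = 45.0


def _prototype_arrays():
    alphabet = canonical_alphabet()
    return np.stack([alphabet[c].standard_dihedrals for c in PB_LETTERS])


def _shift_rmsda_matrix() -> np.ndarray:
    """RMSDA between the overlapping 6 angles of consecutive windows x->y."""
    protos = _prototype_arrays()
    out = np.empty((16, 16))
    for i in range(16):
        for j in range(16):
            d = normalize_angle(protos[i, 2:8] - protos[j, 0:6])
            out[i, j] = np.sqrt(np.mean(d * d))
    return out


def _context_window(context: str, centrals: np.ndarray) -> np.ndarray:
    """The 8-angle window measured at the centre of a 5-letter context."""
    p2, p1, c, n1, n2 = (PB_LETTERS.index(x) for x in context)
    phi = centrals[:, 0]
    psi = centrals[:, 1]
    return np.array(
        [psi[p2], phi[p1], psi[p1], phi[c], psi[c], phi[n1], psi[n1], phi[n2]]
    )


def _assignment_margin(window: np.ndarray, center_idx: int) -> float:
    """RMSDA(runner-up) - RMSDA(true centre); negative = misassigned."""
    protos = _prototype_arrays()
    d = normalize_angle(window[None, :] - protos)
    scores = np.sqrt(np.mean(d * d, axis=1))
    own = scores[center_idx]
    others = np.delete(scores, center_idx)
    return float(others.min() - own)


_DEFAULT_WEIGHTS: np.ndarray | None = None


def default_transition_weights() -> np.ndarray:
    """16x16 transition weight matrix for PB-string sampling (cached).

    Built from prototype shift-compatibility and pruned until every
    emittable 5-letter context is recovered by RMSDA assignment with at
    least ``_CONTEXT_MARGIN`` degrees to spare.  Letters left without a
    safe successor are removed from the emittable set (their rows and
    columns are zeroed).
    """
    global _DEFAULT_WEIGHTS
    if _DEFAULT_WEIGHTS is not None:
        return _DEFAULT_WEIGHTS
    shift = _shift_rmsda_matrix()
    allowed = shift < _SHIFT_CUTOFF
    centrals = _prototype_arrays()[:, 3:5]

    for _ in range(64):
        # drop letters that cannot continue or cannot be reached
        changed = True
        while changed:
            changed = False
            for i in range(16):
                if allowed[i].any() and not allowed[:, i].any() and not allowed[i, i]:
                    pass  # unreachable start letters are still emittable as starts
                if allowed[:, i].any() and not allowed[i].any():
                    allowed[:, i] = False
                    changed = True
        # check every 5-letter path through the allowed graph
        worst_edge = None
        worst_excess = 0.0
        edges = [(i, j) for i in range(16) for j in range(16) if allowed[i, j]]
        succ = {i: [j for j in range(16) if allowed[i, j]] for i in range(16)}
        bad_found = False
        for a, b in edges:
            for c in succ[b]:
                for d in succ[c]:
                    for e in succ[d]:
                        context = "".join(PB_LETTERS[k] for k in (a, b, c, d, e))
                        margin = _assignment_margin(_context_window(context, centrals), c)
                        if margin < _CONTEXT_MARGIN:
                            bad_found = True
                            path_edges = [(a, b), (b, c), (c, d), (d, e)]
                            for ei, ej in path_edges:
                                if shift[ei, ej] > worst_excess:
                                    worst_excess = shift[ei, ej]
                                    worst_edge = (ei, ej)
        if not bad_found:
            break
        allowed[worst_edge] = False
    weights = allowed.astype(float)
    _DEFAULT_WEIGHTS = weights
    return weights


def sample_pb_string(
    length: int,
    transition_weights: np.ndarray | None = None,
    seed: int | None = None,
    start: str | None = None,
) -> str:
    """First-order Markov sample of a PB string.

    Zero-weight transitions are never emitted; rows must not be all-zero
    for any reachable letter.  Deterministic per seed.
    """
    weights = (
        np.asarray(transition_weights, dtype=float)
        if transition_weights is not None
        else default_transition_weights()
    )
    if weights.shape != (16, 16) or (weights < 0).any():
        raise ValueError("transition weights must be a non-negative 16x16 matrix")
    rng = np.random.default_rng(seed)
    emittable = [i for i in range(16) if weights[i].sum() > 0]
    if not emittable:
        raise ValueError("no PB letter has a usable transition row")
    if start is not None:
        state = PB_LETTERS.index(start)
    else:
        state = int(rng.choice(emittable))
    letters = [state]
    for _ in range(length - 1):
        row = weights[state]
        total = row.sum()
        if total == 0:
            raise ValueError(
                f"all-zero transition row for letter {PB_LETTERS[state]!r}"
            )
        state = int(rng.choice(16, p=row / total))
        letters.append(state)
    return "".join(PB_LETTERS[i] for i in letters)


def random_aa_sequence(length: int, seed: int | None = None) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA20), size=length))


def mutate_sequence(aa_seq: str, target_identity: float, seed: int | None = None) -> str:
    """Substitute positions to reach a target percent identity (+-1 position).

    Exactly round(L * (1 - identity/100)) deterministic substitutions, each
    to a different residue, so the realized ungapped identity matches the
    target to within one position.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    n_sub = round(len(aa_seq) * (1.0 - target_identity / 100.0))
    if n_sub == 0:
        return aa_seq
    positions = rng.choice(len(aa_seq), size=n_sub, replace=False)
    out = list(aa_seq)
    for p in positions:
        choices = [c for c in AA20 if c != out[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


@dataclass
class FixtureSpec:
    """A stated synthetic world: family layout, identities, noise, seed."""

    n_families: int = 3
    chains_per_family: int = 3
    chain_length: int = 60
    identity_schedule: tuple[float, ...] = (100.0, 70.0)  # homologues per family
    dihedral_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.chain_length < 5:
            raise ValueError("chains must be at least 5 residues long")
        if len(self.identity_schedule) != self.chains_per_family - 1:
            raise ValueError(
                "identity_schedule must list one identity per non-master chain"
            )
        for ident in self.identity_schedule:
            if not 0 < ident <= 100:
                raise ValueError("identities must be in (0, 100]")


@dataclass
class FixtureChain:
    chain_id: str
    family: int
    aa_seq: str
    pb_truth: str
    backbone: BackboneChain


@dataclass
class Fixture:
    spec: FixtureSpec
    chains: list[FixtureChain] = field(default_factory=list)
    tier_table: TierTable | None = None

    def chain(self, chain_id: str) -> FixtureChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def db_triples(self, exclude: set[str] = frozenset()):
        return [
            (c.chain_id, c.aa_seq, c.pb_truth)
            for c in self.chains
            if c.chain_id not in exclude
        ]


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a mutually consistent world of chains, structures and tiers.

    Per family: one master PB string realised as a backbone; homologues
    share the master's coordinates and PB truth while their sequences are
    mutated to the identities in the schedule.  The tier table is measured
    by the toy clusterer on the generated sequences, not asserted.
    """
    rng = np.random.default_rng(spec.seed)
    chains: list[FixtureChain] = []
    for fam in range(spec.n_families):
        pb_seed = int(rng.integers(2**31 - 1))
        aa_seed = int(rng.integers(2**31 - 1))
        noise_seed = int(rng.integers(2**31 - 1))
        pb_string = sample_pb_string(spec.chain_length, seed=pb_seed)
        master_aa = random_aa_sequence(spec.chain_length, seed=aa_seed)
        backbone = build_backbone(
            pb_string,
            noise_sigma=spec.dihedral_noise_sigma,
            seed=noise_seed,
            chain_id="A",
        )
        phi, psi = phi_psi_series(backbone)
        pb_truth = encode_chain(phi, psi)
        members = [master_aa] + [
            mutate_sequence(master_aa, ident, seed=int(rng.integers(2**31 - 1)))
            for ident in spec.identity_schedule
        ]
        for k, aa_seq in enumerate(members):
            chains.append(
                FixtureChain(
                    chain_id=f"F{fam}C{k}",
                    family=fam,
                    aa_seq=aa_seq,
                    pb_truth=pb_truth,
                    backbone=backbone,
                )
            )
    tier_table = toy_identity_clusterer([(c.chain_id, c.aa_seq) for c in chains])
    return Fixture(spec=spec, chains=chains, tier_table=tier_table)


def write_fixture(fixture: Fixture, out_dir) -> dict[str, Path]:
    """Write a fixture as PDB + FASTA (aa and PB) + tier TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structures = out / "structures"
    structures.mkdir(exist_ok=True)
    for chain in fixture.chains:
        # homologues share coordinates but each PDB carries its own sequence
        residues = [
            Residue(
                name=seq3(aa).upper(),
                seq_position=r.seq_position,
                n=r.n,
                ca=r.ca,
                c=r.c,
            )
            for aa, r in zip(chain.aa_seq, chain.backbone.residues)
        ]
        bb = BackboneChain(chain_id="A", residues=residues, source_id=chain.chain_id)
        write_pdb(bb, structures / f"{chain.chain_id}.pdb")
    aa_path = out / "sequences.fasta"
    with open(aa_path, "w") as fh:
        for chain in fixture.chains:
            fh.write(f">{chain.chain_id}\n{chain.aa_seq}\n")
    pb_path = out / "pb_truth.fasta"
    with open(pb_path, "w") as fh:
        for chain in fixture.chains:
            fh.write(f">{chain.chain_id} alphabet=PB\n{chain.pb_truth}\n")
    tiers_path = out / "tiers.tsv"
    fixture.tier_table.to_tsv(tiers_path)
    spec_path = out / "spec.json"
    with open(spec_path, "w") as fh:
        json.dump(
            {
                "n_families": fixture.spec.n_families,
                "chains_per_family": fixture.spec.chains_per_family,
                "chain_length": fixture.spec.chain_length,
                "identity_schedule": list(fixture.spec.identity_schedule),
                "dihedral_noise_sigma": fixture.spec.dihedral_noise_sigma,
                "seed": fixture.spec.seed,
            },
            fh,
            indent=2,
        )
    return {
        "structures": structures,
        "aa_fasta": aa_path,
        "pb_fasta": pb_path,
        "tiers": tiers_path,
        "spec": spec_path,
    }
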