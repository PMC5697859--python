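"""Pentapeptide knowledge base with homologue-tier filtering.

Every overlapping amino-acid 5-mer of every chain whose central residue has
a defined PB becomes one record (5-mer, central PB, source chain, position).
Records are held in an embedded SQLite store indexed for exact 5-mer and
4-mer-prefix (wildcard fifth position) lookup.

Each source chain carries cluster memberships at the identity thresholds
30, 40, 50, 70, 90, 95 and 100%: two chains co-clustered at threshold *t*
share >= t% sequence identity (single linkage).  Query-time accessibility
predicates built from these memberships implement both the classic
"< t% identity only" filtering and the closest-first noise-filtering
ladder, always excluding the query chain itself.
"""

from __future__ import annotations

import sqlite3
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .alphabet import PB_LETTERS, UNASSIGNED

#: identity thresholds (percent) at which chain clusters are recorded
THRESHOLDS: tuple[int, ...] = (30, 40, 50, 70, 90, 95, 100)
#: sentinel admitting every chain except the query itself
FULL = "full"

#: the 20 standard amino acids; nonstandard residues map to 'X'
AA20 = "ACDEFGHIKLMNPQRSTVWY"

ChainPredicate = Callable[[str], bool]


@dataclass(frozen=True)
class PentapeptideRecord:
    aa5: str
    central_pb: str
    source_chain: str
    position: int  # 1-based index of the 5-mer's first residue


@dataclass
class CandidateProfile:
    """Per query position: the 'list of all possible PBs' with S1 counts."""

    query_position: int  # 1-based index of the window's first residue
    counts: dict[str, int] = field(default_factory=dict)
    match_kind: str = "none"  # exact-pentapeptide | wildcard-tetrapeptide | none
    tier_used: int | str | None = None

    @property
    def is_empty(self) -> bool:
        return not self.counts

    def total(self) -> int:
        return sum(self.counts.values())

    def candidates(self) -> list[str]:
        return sorted(self.counts)


class TierTable:
    """Per-chain cluster membership at each identity threshold."""

    def __init__(self, rows: Mapping[str, Mapping[int, str]] | None = None):
        # rows: chain_id -> {threshold: cluster_id}
        self.rows: dict[str, dict[int, str]] = {
            c: dict(m) for c, m in (rows or {}).items()
        }

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.rows

    def chains(self) -> list[str]:
        return sorted(self.rows)

    def add_chain(self, chain_id: str, clusters: Mapping[int, str]) -> None:
        missing = set(THRESHOLDS) - set(clusters)
        if missing:
            raise ValueError(f"chain {chain_id}: missing thresholds {sorted(missing)}")
        self.rows[chain_id] = {t: clusters[t] for t in THRESHOLDS}

    def co_clustered(self, a: str, b: str, threshold: int) -> bool:
        """True if chains a and b share a cluster at the given threshold."""
        if threshold not in THRESHOLDS:
            raise ValueError(f"unknown identity threshold {threshold!r}")
        return self.rows[a][threshold] == self.rows[b][threshold]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain_id\t" + "\t".join(f"cluster{t}" for t in THRESHOLDS) + "\n")
            for chain in self.chains():
                row = self.rows[chain]
                fh.write(chain + "\t" + "\t".join(row[t] for t in THRESHOLDS) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "TierTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["chain_id"] + [f"cluster{t}" for t in THRESHOLDS]
            if header != expected:
                raise ValueError(f"bad tier table header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                table.add_chain(fields[0], dict(zip(THRESHOLDS, fields[1:])))
        return table


def tier_predicate(
    tier_table: TierTable, query_chain: str, max_identity_threshold
) -> ChainPredicate:
    """Accessibility predicate for the classic (without noise filtering) scheme.

    ``FULL`` admits every chain except the query itself; a numeric threshold
    *t* additionally excludes every chain co-clustered with the query at *t*
    (i.e. admits only chains sharing < t% identity with the query).
    """
    if max_identity_threshold == FULL:
        return lambda chain: chain != query_chain
    if max_identity_threshold not in THRESHOLDS:
        raise ValueError(f"unknown identity threshold {max_identity_threshold!r}")
    t = max_identity_threshold

    def predicate(chain: str) -> bool:
        return chain != query_chain and not tier_table.co_clustered(
            chain, query_chain, t
        )

    return predicate


def noise_filter_ladder(
    tier_table: TierTable, query_chain: str, start
) -> list[ChainPredicate]:
    """Ordered closest-first accessibility rungs for the noise-filtering scheme.

    ``start=100`` (the best-performing setup) begins with exact-sequence
    homologues (co-clustered at 100%) and widens band by band down to the
    full database.  ``start=('below', t)`` caps accessibility at < t%
    identity — the outer set of the classic scheme at *t* — and still walks
    it closest band first; with t = 30 a single rung remains, making that
    ladder identical to the classic scheme at < 30%.
    """
    if start == FULL or start == 100:
        cap = None
        floors = list(reversed(THRESHOLDS))  # 100, 95, ..., 30
    else:
        try:
            tag, cap = start
        except (TypeError, ValueError):
            raise ValueError(f"start must be 100, 'full', or ('below', t): {start!r}")
        if tag != "below" or cap not in THRESHOLDS:
            raise ValueError(f"start must be 100, 'full', or ('below', t): {start!r}")
        floors = [t for t in reversed(THRESHOLDS) if t < cap]

    def within_cap(chain: str) -> bool:
        if chain == query_chain:
            return False
        if cap is None:
            return True
        return not tier_table.co_clustered(chain, query_chain, cap)

    rungs: list[ChainPredicate] = []
    for floor in floors:
        def rung(chain: str, _floor=floor) -> bool:
            return within_cap(chain) and tier_table.co_clustered(
                chain, query_chain, _floor
            )

        rungs.append(rung)
    rungs.append(within_cap)  # final rung: the whole capped set
    return rungs


def sanitize_aa(seq: str) -> str:
    """Uppercase and map nonstandard residues to 'X'."""
    return "".join(c if c in AA20 else "X" for c in seq.upper())


class PentaDB:
    """Embedded pentapeptide knowledge base (SQLite-backed)."""

    _SCHEMA = """
    CREATE TABLE IF NOT EXISTS records (
        aa5 TEXT NOT NULL,
        prefix4 TEXT NOT NULL,
        pb TEXT NOT NULL,
        chain TEXT NOT NULL,
        pos INTEGER NOT NULL
    );
    CREATE INDEX IF NOT EXISTS idx_aa5 ON records (aa5);
    CREATE INDEX IF NOT EXISTS idx_prefix4 ON records (prefix4);
    CREATE TABLE IF NOT EXISTS chains (chain TEXT PRIMARY KEY, length INTEGER);
    """

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(self._SCHEMA)

    def close(self) -> None:
        self.conn.close()

    # -- construction ------------------------------------------------------

    def add_chain(self, chain_id: str, aa_seq: str, pb_seq: str) -> int:
        """Insert all 5-mers of one chain; returns the number of records."""
        if len(aa_seq) != len(pb_seq):
            raise ValueError(
                f"chain {chain_id}: sequence length {len(aa_seq)} != "
                f"PB string length {len(pb_seq)}"
            )
        aa = sanitize_aa(aa_seq)
        rows = []
        for start in range(len(aa) - 4):
            central = pb_seq[start + 2]
            if central == UNASSIGNED:
                continue
            if central not in PB_LETTERS:
                raise ValueError(f"invalid PB letter {central!r} in chain {chain_id}")
            aa5 = aa[start : start + 5]
            rows.append((aa5, aa5[:4], central, chain_id, start + 1))
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO chains VALUES (?, ?)", (chain_id, len(aa))
            )
            self.conn.executemany("INSERT INTO records VALUES (?,?,?,?,?)", rows)
        return len(rows)

    # -- queries -----------------------------------------------------------

    def _profile(self, rows, position: int, kind: str, predicate) -> CandidateProfile:
        counts = Counter(pb for pb, chain in rows if predicate(chain))
        if not counts:
            return CandidateProfile(position, {}, "none")
        return CandidateProfile(position, dict(counts), kind)

    def query_exact(
        self, aa5: str, predicate: ChainPredicate, position: int = 0
    ) -> CandidateProfile:
        """S1 counts over central PBs of records matching the 5-mer exactly."""
        if len(aa5) != 5:
            raise ValueError("query must be a pentapeptide")
        rows = self.conn.execute(
            "SELECT pb, chain FROM records WHERE aa5 = ?", (sanitize_aa(aa5),)
        ).fetchall()
        return self._profile(rows, position, "exact-pentapeptide", predicate)

    def query_wildcard(
        self, aa5: str, predicate: ChainPredicate, position: int = 0
    ) -> CandidateProfile:
        """Fallback: match the first four residues with a wildcard fifth.

        Stored 5-mers containing 'X' never satisfy a wildcard query unless
        the query prefix itself carries the 'X'.
        """
        if len(aa5) != 5:
            raise ValueError("query must be a pentapeptide")
        prefix = sanitize_aa(aa5)[:4]
        rows = self.conn.execute(
            "SELECT pb, chain FROM records WHERE prefix4 = ?", (prefix,)
        ).fetchall()
        return self._profile(rows, position, "wildcard-tetrapeptide", predicate)

    # -- statistics --------------------------------------------------------

    def stats(self, predicate: ChainPredicate | None = None) -> dict:
        """Total / unique pentapeptide counts and sequence-space coverage."""
        if predicate is None:
            rows = self.conn.execute("SELECT aa5, COUNT(*) FROM records GROUP BY aa5")
            pairs = rows.fetchall()
        else:
            raw = self.conn.execute("SELECT aa5, chain FROM records").fetchall()
            counter = Counter(aa5 for aa5, chain in raw if predicate(chain))
            pairs = list(counter.items())
        total = sum(c for _, c in pairs)
        unique = len(pairs)
        space = pentapeptide_space_size()
        return {
            "total_pentapeptides": total,
            "unique_pentapeptides": unique,
            "possible_pentapeptides": space,
            "fraction_of_sequence_space": unique / space,
            "n_chains": self.conn.execute("SELECT COUNT(*) FROM chains").fetchone()[0],
        }


def pentapeptide_space_size(n_amino_acids: int = 20, k: int = 5) -> int:
    """Number of possible amino-acid k-mers (20^5 = 3.2 million pentapeptides)."""
    return n_amino_acids**k


def build_db(
    chains: Iterable[tuple[str, str, str]],
    tier_table: TierTable,
    store_path=":memory:",
) -> PentaDB:
    """Build a PentaDB from (chain_id, aa_seq, pb_seq) triples.

    Every chain must have a row in the tier table so that identity
    filtering stays well-defined.
    """
    db = PentaDB(store_path)
    for chain_id, aa_seq, pb_seq in chains:
        if chain_id not in tier_table:
            raise ValueError(f"chain {chain_id!r} is absent from the tier table")
        db.add_chain(chain_id, aa_seq, pb_seq)
    return db


# -- toy identity clustering (BLASTClust stand-in for fixture-sized input) --


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity (identities / alignment length)."""
    from Bio import Align

    if not seq_a or not seq_b:
        return 0.0
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / length if length else 0.0


def toy_identity_clusterer(
    sequences: Sequence[tuple[str, str]],
    thresholds: Sequence[int] = THRESHOLDS,
) -> TierTable:
    """Greedy single-linkage clustering on global pairwise percent identity.

    ``sequences`` is an ordered list of (chain_id, aa_seq).  Deterministic
    given input order; cluster labels are derived from the smallest member
    index.  Intended for fixture-scale input only (O(n^2) alignments).
    """
    ids = [cid for cid, _ in sequences]
    n = len(ids)
    identity = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(sequences[i][1], sequences[j][1])
            identity[i][j] = identity[j][i] = pid

    table = TierTable()
    assignments: dict[str, dict[int, str]] = {cid: {} for cid in ids}
    for t in thresholds:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if identity[i][j] >= t:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        for i in range(n):
            assignments[ids[i]][t] = f"t{t}_{find(i)}"
    for cid in ids:
        table.add_chain(cid, assignments[cid])
    return table
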