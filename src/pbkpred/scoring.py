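"""Tri-PB / penta-PB motif frequency tables and the PB-sequence accuracy score.

Runs of 3 or 5 consecutive PBs (tri-PB / penta-PB motifs) are highly
non-uniform in real structures: many combinations are stereochemically
disallowed and never observed.  A normalized frequency table over such
motifs therefore carries a strong plausibility signal.

Two normalizations are supported:

* ``freq``  — plain frequency: count(motif) / total motif count; entries
  sum to one.
* ``odds``  — marginal odds: plain frequency divided by the product of the
  single-PB marginal frequencies of the motif's letters.  Odds exceed 1
  for motifs enriched over an independence baseline, which is what lets
  the accuracy score of a plausible sequence come out positive.

The accuracy score A of a PB sequence of length l sums log10 of the
normalized frequency of each of its l-4 overlapping penta-PB windows and
divides by l; a window whose motif was never observed contributes a flat
penalty of -5 instead of a logarithm.  The score self-estimates prediction
quality: implausible PB strings hit unobserved or rare motifs and score
low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .alphabet import PB_LETTERS, UNASSIGNED

#: penalty replacing log10(N) for a never-observed penta-PB motif
DEFAULT_PENALTY = -5.0


@dataclass
class FrequencyTable:
    """Normalized frequencies of PB motifs of a fixed order (3 or 5)."""

    order: int
    normalization_mode: str  # "freq" | "odds"
    entries: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    total_motifs_observed: int = 0

    def __post_init__(self):
        if self.order not in (3, 5):
            raise ValueError("motif order must be 3 or 5")
        if self.normalization_mode not in ("freq", "odds"):
            raise ValueError(f"unknown normalization {self.normalization_mode!r}")

    def get(self, motif: str) -> float:
        """Normalized frequency of a motif; unobserved motifs are 0."""
        if len(motif) != self.order:
            raise ValueError(f"motif {motif!r} does not have order {self.order}")
        return self.entries.get(motif, 0.0)

    def __contains__(self, motif: str) -> bool:
        return motif in self.entries

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# order={self.order} mode={self.normalization_mode} "
                f"total={self.total_motifs_observed}\n"
            )
            fh.write("motif\tcount\tnormalized_frequency\n")
            for motif in sorted(self.entries):
                fh.write(
                    f"{motif}\t{self.counts.get(motif, 0)}\t"
                    f"{self.entries[motif]:.12g}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#"):
                raise ValueError("missing frequency-table metadata header")
            meta = dict(kv.split("=") for kv in header[1:].split())
            fh.readline()  # column names
            entries, counts = {}, {}
            for line in fh:
                if not line.strip():
                    continue
                motif, count, freq = line.rstrip("\n").split("\t")
                entries[motif] = float(freq)
                counts[motif] = int(count)
        return cls(
            order=int(meta["order"]),
            normalization_mode=meta["mode"],
            entries=entries,
            counts=counts,
            total_motifs_observed=int(meta["total"]),
        )


def _iter_motifs(pb_sequence: str, order: int):
    for start in range(len(pb_sequence) - order + 1):
        motif = pb_sequence[start : start + order]
        if UNASSIGNED not in motif:
            yield motif


def build_table(
    pb_corpus: list[str], order: int, mode: str = "odds"
) -> FrequencyTable:
    """Build a motif frequency table from a corpus of PB strings.

    Windows containing ``Z`` are skipped.  In ``odds`` mode the marginal
    single-PB frequencies are estimated from the same corpus (Z excluded).
    """
    if order not in (3, 5):
        raise ValueError("motif order must be 3 or 5")
    if not pb_corpus:
        raise ValueError("the PB corpus must be non-empty")
    counts: dict[str, int] = {}
    letter_counts = {c: 0 for c in PB_LETTERS}
    for seq in pb_corpus:
        for motif in _iter_motifs(seq, order):
            counts[motif] = counts.get(motif, 0) + 1
        for c in seq:
            if c in letter_counts:
                letter_counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        return FrequencyTable(order, mode, {}, {}, 0)
    n_letters = sum(letter_counts.values())
    marginals = {c: letter_counts[c] / n_letters for c in PB_LETTERS}
    entries: dict[str, float] = {}
    for motif, count in counts.items():
        freq = count / total
        if mode == "freq":
            entries[motif] = freq
        else:
            baseline = math.prod(marginals[c] for c in motif)
            entries[motif] = freq / baseline if baseline > 0 else 0.0
    return FrequencyTable(order, mode, entries, counts, total)


@dataclass(frozen=True)
class AccuracyScore:
    """The length-normalized log-plausibility A of a PB sequence."""

    value: float
    n_windows: int  # scored-length minus 4
    n_penalized: int  # windows whose penta-PB motif was never observed
    n_skipped: int = 0  # interior windows containing Z, not scored


def accuracy_score(
    pb_sequence: str,
    penta_table: FrequencyTable,
    penalty: float = DEFAULT_PENALTY,
    log_base: float = 10.0,
) -> AccuracyScore:
    """Score a PB sequence: A = [sum over windows of log(N_i) or penalty] / l.

    ``l`` is the length of the PB sequence after trimming terminal Z runs
    (prediction always leaves two Z at each end).  Each of the l-4
    overlapping penta-PB windows contributes log(N_i) in the requested
    base, or the flat ``penalty`` when its motif is absent from the table;
    interior windows containing Z are skipped and reported separately.
    """
    if penta_table.order != 5:
        raise ValueError("the accuracy score requires a penta-PB table")
    trimmed = pb_sequence.strip(UNASSIGNED)
    l = len(trimmed)
    if l < 5:
        raise ValueError("fewer than one scorable penta-PB window")
    log_div = math.log(log_base)
    total = 0.0
    n_penalized = 0
    n_skipped = 0
    n_windows = l - 4
    for start in range(n_windows):
        motif = trimmed[start : start + 5]
        if UNASSIGNED in motif:
            n_skipped += 1
            continue
        freq = penta_table.get(motif)
        if freq > 0.0:
            total += math.log(freq) / log_div
        else:
            total += penalty
            n_penalized += 1
    return AccuracyScore(
        value=total / l,
        n_windows=n_windows,
        n_penalized=n_penalized,
        n_skipped=n_skipped,
    )


def motif_coverage(table: FrequencyTable) -> tuple[int, float]:
    """Observed motif count and its fraction of the 16^order motif space."""
    possible = motif_space_size(table.order)
    return len(table.entries), len(table.entries) / possible


def motif_space_size(order: int) -> int:
    """Number of possible PB motifs of a given order (16^3 = 4096, 16^5 = 1048576)."""
    return len(PB_LETTERS) ** order
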