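"""Evaluation of predicted PB sequences against structure-derived truth.

Q16 is the percentage of residues whose predicted PB (one of 16) matches
the PB encoded from the known structure.  Positions carrying ``Z`` in
either sequence (termini, chain breaks, no-hit windows) are excluded from
both numerator and denominator by default; the stricter denominator that
counts unpredicted positions as errors is also reported where relevant.

Per-PB statistics binarize the 16-class confusion matrix one-vs-rest:
sensitivity, specificity and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the conventional value 0 when the denominator vanishes.

Because some PBs are nearly interchangeable (notably c and d, which the
predictor frequently confuses), a relaxed accuracy may treat co-members of
user-supplied equivalence sets as correct.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alphabet import PB_LETTERS, UNASSIGNED
from .pentadb import CandidateProfile

#: the only equivalence hard-wired by default: the c/d strand-cap pair
DEFAULT_EQUIVALENCE_SETS: tuple[frozenset, ...] = (frozenset({"c", "d"}),)

_INDEX = {c: i for i, c in enumerate(PB_LETTERS)}


@dataclass
class ConfusionMatrix16:
    """16x16 confusion counts; rows = true PB, columns = predicted PB."""

    counts: np.ndarray  # (16, 16) int
    n_excluded: int  # positions with Z in either sequence

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("true\\pred\t" + "\t".join(PB_LETTERS) + "\n")
            for i, letter in enumerate(PB_LETTERS):
                row = "\t".join(str(int(x)) for x in self.counts[i])
                fh.write(f"{letter}\t{row}\n")


def _check_lengths(true_pb: str, pred_pb: str) -> None:
    if len(true_pb) != len(pred_pb):
        raise ValueError(
            f"sequence length mismatch: {len(true_pb)} vs {len(pred_pb)}"
        )


def _joint_positions(true_pb: str, pred_pb: str):
    for t, p in zip(true_pb, pred_pb):
        if t != UNASSIGNED and p != UNASSIGNED:
            yield t, p


def q16_accuracy(
    true_pb: str,
    pred_pb: str,
    count_ties_as_correct: bool = False,
    tie_sets: list[list[str]] | None = None,
) -> float:
    """Percentage of jointly defined positions predicted exactly right.

    With ``count_ties_as_correct`` a position whose emitted letter was an
    arbitrary pick among equally scored candidates (``tie_sets``, aligned
    with the full sequence) counts as correct if any tied letter matches.
    """
    _check_lengths(true_pb, pred_pb)
    n = 0
    hits = 0
    for i, (t, p) in enumerate(zip(true_pb, pred_pb)):
        if t == UNASSIGNED or p == UNASSIGNED:
            continue
        n += 1
        if t == p:
            hits += 1
        elif count_ties_as_correct and tie_sets and t in (tie_sets[i] or []):
            hits += 1
    return 100.0 * hits / n if n else 0.0


def confusion(true_pb: str, pred_pb: str) -> ConfusionMatrix16:
    """Accumulate the 16x16 confusion matrix over jointly defined positions."""
    _check_lengths(true_pb, pred_pb)
    counts = np.zeros((16, 16), dtype=int)
    excluded = 0
    for t, p in zip(true_pb, pred_pb):
        if t == UNASSIGNED or p == UNASSIGNED:
            excluded += 1
            continue
        counts[_INDEX[t], _INDEX[p]] += 1
    return ConfusionMatrix16(counts=counts, n_excluded=excluded)


def merge_confusions(matrices: list[ConfusionMatrix16]) -> ConfusionMatrix16:
    return ConfusionMatrix16(
        counts=sum((m.counts for m in matrices), np.zeros((16, 16), dtype=int)),
        n_excluded=sum(m.n_excluded for m in matrices),
    )


@dataclass(frozen=True)
class PerPBStats:
    pb: str
    accuracy: float  # per-class recall (the "PB-wise prediction rate")
    sensitivity: float
    specificity: float
    mcc: float
    support: int  # true occurrences of this PB


def per_pb_stats(cm: ConfusionMatrix16, pb: str) -> PerPBStats:
    """One-vs-rest sensitivity, specificity and MCC for a single PB."""
    if cm.total == 0:
        raise ValueError("cannot compute per-PB statistics on an empty matrix")
    i = _INDEX[pb]
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom > 0 else 0.0
    return PerPBStats(
        pb=pb,
        accuracy=100.0 * sens,
        sensitivity=sens,
        specificity=spec,
        mcc=mcc,
        support=tp + fn,
    )


def _merge_overlapping(sets) -> list[frozenset]:
    merged: list[set] = []
    overlap = False
    for s in sets:
        s = set(s)
        hit = [m for m in merged if m & s]
        for m in hit:
            merged.remove(m)
            s |= m
            overlap = True
        merged.append(s)
    if overlap:
        warnings.warn("overlapping equivalence sets were merged", stacklevel=3)
    return [frozenset(s) for s in merged]


def relaxed_accuracy(
    true_pb: str,
    pred_pb: str,
    equivalence_sets=DEFAULT_EQUIVALENCE_SETS,
) -> float:
    """Q16 under PB equivalence: co-members of any set count as correct."""
    _check_lengths(true_pb, pred_pb)
    sets = _merge_overlapping(equivalence_sets or [])
    n = 0
    hits = 0
    for t, p in _joint_positions(true_pb, pred_pb):
        n += 1
        if t == p or any(t in s and p in s for s in sets):
            hits += 1
    return 100.0 * hits / n if n else 0.0


def candidate_coverage(true_pb: str, profiles: list[CandidateProfile]) -> float:
    """Percentage of positions whose true PB appears in the candidate list.

    This is the ceiling of the knowledge-based approach: no selection rule
    can beat the rate at which the correct PB is present among candidates.
    ``profiles`` are aligned to windows 1..L-4; window at position p covers
    the central residue p+2.  The denominator counts jointly defined
    positions — true PB assigned *and* a non-empty candidate list — which
    is exactly the set of positions any prediction built from the same
    profiles can score on, so coverage >= Q16 holds by construction.
    """
    if len(profiles) != max(len(true_pb) - 4, 0):
        raise ValueError("profiles are not aligned with the true PB sequence")
    n = 0
    hits = 0
    for i, profile in enumerate(profiles):
        t = true_pb[i + 2]
        if t == UNASSIGNED or profile.is_empty:
            continue
        n += 1
        if t in profile.counts:
            hits += 1
    return 100.0 * hits / n if n else 0.0


def evaluation_report(true_pb: str, pred_pb: str) -> dict:
    """Bundle Q16 (both denominators), relaxed accuracy and per-PB stats."""
    cm = confusion(true_pb, pred_pb)
    defined_true = sum(1 for t in true_pb if t != UNASSIGNED)
    strict_denominator = (
        100.0 * np.trace(cm.counts) / defined_true if defined_true else 0.0
    )
    per_pb = {}
    if cm.total:
        for pb in PB_LETTERS:
            stats = per_pb_stats(cm, pb)
            per_pb[pb] = {
                "frequency": stats.support / cm.total,
                "accuracy": stats.accuracy,
                "sensitivity": stats.sensitivity,
                "specificity": stats.specificity,
                "mcc": stats.mcc,
            }
    return {
        "q16": q16_accuracy(true_pb, pred_pb),
        "q16_all_positions": strict_denominator,
        "relaxed_q16": relaxed_accuracy(true_pb, pred_pb),
        "n_positions": cm.total,
        "n_excluded": cm.n_excluded,
        "per_pb": per_pb,
    }
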