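"""PB sequence prediction from pentapeptide knowledge-base lookups.

For every overlapping pentapeptide of a query sequence the knowledge base
returns a candidate profile: the "list of all possible PBs" with raw hit
counts (S1 scores).  Two selection rules turn profiles into a prediction:

* **majority rule** — per window, the candidate with the highest S1 count;
* **hybrid** — per window, the candidate maximising S1 x S2, where the S2
  score of candidate *y* sums the tri-PB odds of every motif *xyz* formed
  with candidates *x* of the preceding and *z* of the succeeding window.

Lookups run under either the classic scheme (one accessibility predicate,
typically "chains below t% identity to the query") or the noise-filtering
scheme, which walks a closest-first ladder of predicates per window and
keeps the first rung producing an exact hit.  The wildcard (first four
residues, any fifth) fallback is consulted only after exact lookup fails
on every rung.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import PB_LETTERS, UNASSIGNED
from .pentadb import CandidateProfile, ChainPredicate, PentaDB
from .scoring import FrequencyTable


@dataclass
class PositionResult:
    profile: CandidateProfile
    s2_scores: dict[str, float] = field(default_factory=dict)
    chosen: str = UNASSIGNED
    tied: list[str] = field(default_factory=list)
    tier_used: int | str | None = None


@dataclass
class PredictionResult:
    pb_sequence: str
    per_position: list[PositionResult]
    method: str  # majority | hybrid
    scheme: str  # classic | noise-filter

    def __post_init__(self):
        assert len(self.pb_sequence) == len(self.per_position) + 4


def collect_profiles(
    query_seq: str, db: PentaDB, predicate: ChainPredicate
) -> list[CandidateProfile]:
    """One candidate profile per sliding window (positions 1..L-4).

    Exact pentapeptide lookup first; the wildcard tetrapeptide fallback is
    consulted only on an empty exact result.
    """
    if len(query_seq) < 5:
        raise ValueError("query must be at least 5 residues long")
    profiles = []
    for start in range(len(query_seq) - 4):
        aa5 = query_seq[start : start + 5]
        profile = db.query_exact(aa5, predicate, position=start + 1)
        if profile.is_empty:
            profile = db.query_wildcard(aa5, predicate, position=start + 1)
        profiles.append(profile)
    return profiles


def _argmax_letters(scores: dict[str, float]) -> list[str]:
    best = max(scores.values())
    return sorted(k for k, v in scores.items() if v == best)


def _assemble(per_position: list[PositionResult], method: str, scheme: str):
    # window at 1-based position p predicts the central residue p+2;
    # two flanking residues at each terminus are never predicted
    letters = [UNASSIGNED] * (len(per_position) + 4)
    for i, pos in enumerate(per_position):
        letters[i + 2] = pos.chosen
    return PredictionResult("".join(letters), per_position, method, scheme)


def predict_majority(
    profiles: list[CandidateProfile], scheme: str = "classic"
) -> PredictionResult:
    """Majority rule: per window, the PB with the highest S1 count.

    Equal top counts set the tie flag and record every tied letter; the
    emitted string carries the alphabetically smallest (a single string is
    needed downstream even when several PBs are equally supported).
    """
    per_position = []
    for profile in profiles:
        pos = PositionResult(profile=profile, tier_used=profile.tier_used)
        if not profile.is_empty:
            tied = _argmax_letters(profile.counts)
            pos.chosen = tied[0]
            pos.tied = tied if len(tied) > 1 else []
        per_position.append(pos)
    return _assemble(per_position, "majority", scheme)


def s2_scores(
    profile_prev: CandidateProfile | None,
    profile_self: CandidateProfile,
    profile_next: CandidateProfile | None,
    tripb_table: FrequencyTable,
    terminal_policy: str = "full-alphabet",
) -> dict[str, float]:
    """Contextual S2 score of each candidate central PB.

    S2(y) = sum over x in candidates(prev), z in candidates(next) of the
    tri-PB odds of motif xyz; unobserved motifs contribute zero.  A missing
    or empty neighbour contributes the full 16-letter alphabet under the
    default policy ('skip' instead makes that side a single wildcard pass
    using marginal behaviour is deliberately not offered: pure-S1 handling
    lives at the predictor level).
    """
    if tripb_table.order != 3:
        raise ValueError("S2 requires a tri-PB frequency table")
    if terminal_policy not in ("full-alphabet", "none"):
        raise ValueError(f"unknown terminal policy {terminal_policy!r}")

    def neighbour_candidates(profile):
        if profile is None or profile.is_empty:
            if terminal_policy == "none":
                return None
            return list(PB_LETTERS)
        return profile.candidates()

    prev_cands = neighbour_candidates(profile_prev)
    next_cands = neighbour_candidates(profile_next)
    scores: dict[str, float] = {}
    for y in profile_self.candidates():
        if prev_cands is None or next_cands is None:
            scores[y] = 1.0  # neighbourless under 'none' policy: S2 neutral
            continue
        total = 0.0
        for x in prev_cands:
            for z in next_cands:
                total += tripb_table.get(x + y + z)
        scores[y] = total
    return scores


def predict_hybrid(
    profiles: list[CandidateProfile],
    tripb_table: FrequencyTable,
    scheme: str = "classic",
    terminal_policy: str = "full-alphabet",
) -> PredictionResult:
    """Hybrid method: per window, argmax over candidates of S1(y) * S2(y).

    When every candidate's product is zero (all context tri-PBs unobserved)
    the window falls back to the S1 majority choice rather than emitting an
    arbitrary letter.  Ties behave as in the majority rule.
    """
    per_position = []
    n = len(profiles)
    for i, profile in enumerate(profiles):
        pos = PositionResult(profile=profile, tier_used=profile.tier_used)
        if not profile.is_empty:
            prev_p = profiles[i - 1] if i > 0 else None
            next_p = profiles[i + 1] if i + 1 < n else None
            s2 = s2_scores(prev_p, profile, next_p, tripb_table, terminal_policy)
            pos.s2_scores = s2
            products = {y: profile.counts[y] * s2[y] for y in profile.counts}
            if max(products.values()) == 0.0:
                products = dict(profile.counts)  # S1 fallback
            tied = _argmax_letters(products)
            pos.chosen = tied[0]
            pos.tied = tied if len(tied) > 1 else []
        per_position.append(pos)
    return _assemble(per_position, "hybrid", scheme)


def collect_profiles_noise_filtering(
    query_seq: str, db: PentaDB, tier_ladder: list[ChainPredicate]
) -> list[CandidateProfile]:
    """Per-window closest-first ladder walk over accessibility rungs.

    For each window the first rung yielding a non-empty exact profile
    supplies that window's candidates (tier_used records the rung index).
    Only when the entire ladder yields no exact hit is the wildcard
    fallback consulted, again closest rung first.
    """
    if not tier_ladder:
        raise ValueError("the tier ladder must contain at least one rung")
    if len(query_seq) < 5:
        raise ValueError("query must be at least 5 residues long")
    profiles = []
    for start in range(len(query_seq) - 4):
        aa5 = query_seq[start : start + 5]
        profile = None
        for rung_idx, predicate in enumerate(tier_ladder):
            candidate = db.query_exact(aa5, predicate, position=start + 1)
            if not candidate.is_empty:
                candidate.tier_used = rung_idx
                profile = candidate
                break
        if profile is None:
            for rung_idx, predicate in enumerate(tier_ladder):
                candidate = db.query_wildcard(aa5, predicate, position=start + 1)
                if not candidate.is_empty:
                    candidate.tier_used = rung_idx
                    profile = candidate
                    break
        if profile is None:
            profile = CandidateProfile(start + 1, {}, "none")
        profiles.append(profile)
    return profiles


def predict_with_noise_filtering(
    query_seq: str,
    db: PentaDB,
    tier_ladder: list[ChainPredicate],
    method: str = "hybrid",
    tripb_table: FrequencyTable | None = None,
) -> PredictionResult:
    """Noise-filtering scheme: ladder per window, then the chosen method."""
    profiles = collect_profiles_noise_filtering(query_seq, db, tier_ladder)
    if method == "majority":
        return predict_majority(profiles, scheme="noise-filter")
    if method == "hybrid":
        if tripb_table is None:
            raise ValueError("the hybrid method requires a tri-PB table")
        return predict_hybrid(profiles, tripb_table, scheme="noise-filter")
    raise ValueError(f"unknown method {method!r}")
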