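# pbkpred

Knowledge-based prediction of protein local backbone conformation as a
sequence of **Protein Blocks** (PBs), with a self-estimating accuracy score.

## The problem

Protein Blocks are a structural alphabet: 16 canonical five-residue backbone
conformations, labelled `a`–`p`, each defined by a prototype vector of eight
dihedral angles (ψ<sub>i−2</sub>, φ<sub>i−1</sub>, ψ<sub>i−1</sub>, φ<sub>i</sub>,
ψ<sub>i</sub>, φ<sub>i+1</sub>, ψ<sub>i+1</sub>, φ<sub>i+2</sub>). PBs *m* and
*d* correspond roughly to α-helix and β-strand cores. Encoding a structure as
a PB string gives a one-dimensional description of local backbone geometry that
is far finer than three-state secondary structure.

`pbkpred` predicts the PB string of a protein **from its amino-acid sequence
alone**, by looking every overlapping pentapeptide up in a knowledge base of
5-mer fragments extracted from known structures. It is aimed at structural
bioinformaticians who need local-structure hypotheses for sequences without
solved structures — including sequences with no detectable homologues.

## The method

1. **Knowledge base.** Every overlapping 5-mer of every known chain is stored
   with the PB of its central residue and the source chain's sequence-identity
   cluster memberships at thresholds {30, 40, 50, 70, 90, 95, 100}%.
2. **Lookup.** For each query window, exact 5-mer lookup returns the *list of
   all possible PBs* with raw hit counts (**S1** scores); if the 5-mer is
   unknown, a tetrapeptide-with-wildcard-fifth-position fallback is tried.
   The query's own chain is always excluded.
3. **Selection.** The *majority rule* picks argmax S1. The *hybrid method*
   picks argmax S1×S2, where **S2**(y) sums the odds of every tri-PB motif
   x·y·z formed with the neighbouring windows' candidates, from a normalized
   tri-PB frequency table — a context term that suppresses locally
   implausible choices.
4. **Noise filtering.** Instead of querying the whole database at once, a
   per-window ladder consults the closest sequence-identity tier first and
   widens only on a miss, so fragments from close homologues are preferred
   when they exist.
5. **Accuracy score.** A predicted PB string of length *l* is scored
   A = Σ<sub>i=1..l−4</sub> log₁₀ N<sub>i</sub> / l over its penta-PB windows,
   where N<sub>i</sub> is the motif's normalized frequency and a never-observed
   motif contributes a flat −5 penalty. Implausible predictions hit rare or
   forbidden motifs and score low, so A estimates prediction quality without
   knowing the answer.

Evaluation utilities provide Q16 (16-state accuracy), per-PB
sensitivity/specificity/MCC from the 16×16 confusion matrix, and a relaxed
accuracy treating near-interchangeable PBs (by default *c*/*d*) as equivalent.

Everything is testable offline: a fixture generator samples PB strings from a
prototype-compatible Markov chain, realises them as backbones by
internal-coordinate (NeRF) placement, and derives homologue families with
controlled identities plus the matching tier table.

## Worked example

```python
from pbkpred import (
    FixtureSpec, make_fixture, build_db, build_table,
    noise_filter_ladder, predict_with_noise_filtering,
    q16_accuracy, accuracy_score,
)

world = make_fixture(FixtureSpec(n_families=3, chains_per_family=3,
                                 identity_schedule=(100.0, 70.0),
                                 chain_length=60, seed=42))
query = world.chain("F0C0")
db = build_db(world.db_triples(exclude={"F0C0"}), world.tier_table)
corpus = [c.pb_truth for c in world.chains if c.chain_id != "F0C0"]
tripb = build_table(corpus, 3, "odds")
pentapb = build_table(corpus, 5, "odds")

ladder = noise_filter_ladder(world.tier_table, "F0C0", 100)
result = predict_with_noise_filtering(query.aa_seq, db, ladder, "hybrid", tripb)

print("query     :", query.aa_seq)
print("true PBs  :", query.pb_truth)
print("predicted :", result.pb_sequence)
print(f"Q16       : {q16_accuracy(query.pb_truth, result.pb_sequence):.1f}%")
print(f"score A   : {accuracy_score(result.pb_sequence, pentapb).value:+.2f}")
```

prints

```
query     : THHPWVYCYNTCQVHACHAFRIKVRTCLSLDFWHVDTIWLCLLPSQPANHRRSNPMQGVG
true PBs  : ZZklnopacfklmnopafklnopacddddfklnopafklnopafklmnopafklmmmnZZ
predicted : ZZklnopacfklmnopafklnopacddddfklnopafklnopafklmnopafklmmmnZZ
Q16       : 100.0%
score A   : +3.34
```

The held-out chain has an identical-sequence homologue in the database, so the
closest-first ladder recovers the true PB at every interior position (the two
residues at each terminus have no complete dihedral window and stay `Z`), and
the high accuracy score (+3.34, well above +1) correctly flags the prediction
as trustworthy. Restricting the database to chains below 30% identity
(`tier_predicate(world.tier_table, "F0C0", 30)`) collapses Q16 — the expected
behaviour in the twilight zone.

The same pipeline is scriptable from the shell:

```bash
pbkpred make-fixture --seed 4 --out world/
pbkpred build-db --structures world/structures --tiers world/tiers.tsv --out penta.db
pbkpred build-tables --pb-corpus world/pb_truth.fasta --order 3 --out tripb.tsv
pbkpred predict --db penta.db --tiers world/tiers.tsv --fasta world/sequences.fasta \
    --method hybrid --scheme noise-filter --start 100 --tripb tripb.tsv \
    --out pred.fasta --report report.json
pbkpred evaluate --true world/pb_truth.fasta --pred pred.fasta
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a synthetic world from the seed, builds the knowledge base and
motif tables from scratch, predicts held-out chains under both the
closest-homologue-first and the below-30%-identity conditions, and prints the
resulting mean Q16, relaxed accuracy and accuracy scores.
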