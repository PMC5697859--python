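# Methods

This note documents the models, conventions and design choices behind
`pbkpred`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what a passing test
does and does not establish.

## The Protein Blocks alphabet and RMSDA assignment

The 16 PB prototypes (letters `a`–`p`, eight dihedral angles each) are the
canonical published table (de Brevern, Etchebest & Hazout, 2000, *Proteins*
41:271–287), shipped as `pbkpred/data/pb_prototypes.tsv`. The package treats
the table as configuration: every assignment function accepts an alternative
`alphabet`, and the TSV format (letter + 8 angle columns, degrees) is the
interchange format. Re-deriving the prototypes by unsupervised learning is
out of scope.

A residue's window is (ψ<sub>i−2</sub>, φ<sub>i−1</sub>, ψ<sub>i−1</sub>,
φ<sub>i</sub>, ψ<sub>i</sub>, φ<sub>i+1</sub>, ψ<sub>i+1</sub>, φ<sub>i+2</sub>).
Dissimilarity is RMSDA, the root mean square of the eight wrapped angular
differences; the PB with minimal RMSDA is assigned. Conventions:

* angles are normalized to (−180°, 180°] at ingestion; the half-turn maps to
  +180;
* RMSDA ties (measure-zero in practice) resolve to the alphabetically
  smallest letter, for reproducibility;
* the first two and last two residues, and any residue whose window touches
  an undefined dihedral, receive `Z`. `Z` positions are excluded from all
  accuracy denominators.

## Structure handling

PDB files are read through Biopython. Policies where multiple conformations
exist: first model only (single-conformation encoding); highest-occupancy
altloc, ties to `A`. Residues missing any of N/CA/C are kept but flagged, so
dihedrals depending on them become undefined rather than wrong. A
C(i−1)–N(i) distance above 2.5 Å (a generous upper bound for a peptide bond)
is treated as a chain break. φ/ψ are computed internally with the standard
IUPAC sign convention (verified against an independent geometry library);
no external assignment program is needed.

`build_backbone` inverts encoding for fixtures: sequential NeRF placement
with ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.0°,
CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°). Each residue takes the **central**
(φ, ψ) pair of its PB's prototype — the standard choice for PB back-mapping,
since prototypes of adjacent overlapping windows agree only approximately
and no exact reconstruction exists. Optional Gaussian noise of stated σ is
added per angle, deterministically per seed.

## The pentapeptide knowledge base

One record per overlapping 5-mer whose central residue has a defined PB:
(5-mer, central PB, source chain, position). Storage is a single-file SQLite
database indexed on the 5-mer and on its 4-mer prefix; an embedded store has
the same query contract as a database server without the deployment.
Nonstandard residues map to `X`; `X`-containing 5-mers are stored and can be
matched, but never masquerade as standard residues.

The wildcard fallback fixes the wildcard at position 5 (matching the first
four residues exactly); the position of the wildcard does not matter
empirically, so only one is implemented.

### Identity tiers

Each source chain carries cluster memberships at thresholds
{30, 40, 50, 70, 90, 95, 100}%. Two chains co-clustered at threshold *t*
share ≥ t% identity under single linkage, so memberships are nested: a
cluster at a lower threshold is coarser. "Accessible below *t*%" is encoded
as "not co-clustered with the query at *t*"; the query chain itself is
always excluded. Consequently the accessible set grows monotonically as the
cut-off loosens — candidate lists can only gain entries, which the tests
assert.

The bundled clusterer is a deliberate toy (greedy single-linkage on global
pairwise percent identity, identities / alignment length, via Biopython's
`PairwiseAligner`), adequate for fixture-scale input; production cluster
memberships are an input (TSV), not something this package recomputes.

### The noise-filtering ladder

The with-noise-filtering scheme walks, **per window**, an ordered ladder of
accessibility predicates from the closest identity band outward; the first
rung with a non-empty exact hit supplies that window's candidates. The
wildcard fallback is consulted only after the entire ladder misses, again
closest rung first — exact information from a distant homologue is preferred
over wildcard guesses from a close one; the original ordering of wildcard vs
tier is not documented anywhere, so this is this package's declared choice.

A ladder may start at the exact-duplicate band (co-clustered at 100%) and
widen to the full database, or be capped below a threshold *t* and widen
within the cap. The capped ladder starting below 30% has a single rung and
is therefore *identical* to the classic scheme at <30% — an identity the
acceptance suite tests.

## Selection rules

* **Majority rule**: argmax of S1 (raw hit counts). Equal top counts set a
  tie flag and record all tied letters; the emitted string carries the
  alphabetically smallest, because downstream formats need one letter per
  position. Evaluation can optionally count a tie as correct when any tied
  letter matches (off by default).
* **Hybrid**: argmax of S1(y)·S2(y), with S2(y) = Σ<sub>x,z</sub>
  odds(x·y·z) over the neighbouring windows' candidate sets. A missing or
  empty neighbour contributes the full 16-letter alphabet (the alternative,
  neutral S2 at termini, is available via `terminal_policy="none"`).
  Unobserved tri-PBs contribute zero; when *every* candidate's product is
  zero the window falls back to the S1 majority rather than emitting an
  arbitrary or empty answer. With a constant tri-PB table the hybrid reduces
  exactly to the majority rule (tested).

## Motif tables and the accuracy score

Tables over tri-PB or penta-PB motifs skip any window containing `Z`. Two
normalizations:

* `freq` — plain frequencies summing to 1;
* `odds` (default) — frequency divided by the product of single-PB marginal
  frequencies from the same corpus.

The accuracy score is A = [Σ log₁₀ N<sub>i</sub>] / l over the l−4 penta-PB
windows of the Z-trimmed sequence, with a flat −5 penalty replacing the
logarithm for never-observed motifs. The log base (10) and the odds
normalization are declared package choices, not published values: the
original normalization is not specified in the available text, and plain
frequencies (always ≤ 1) could never produce the positive scores that
characterize plausible sequences. Under odds normalization, enriched motifs
score above zero and realistic sequences land in roughly the +1…+3 range,
as in the worked example. Both knobs (`log_base`, `mode`) are configurable;
the penalty is a parameter too.

## Evaluation

Q16 excludes `Z` in either sequence from numerator and denominator; the
stricter all-defined-truth denominator is also reported
(`q16_all_positions`). Per-PB statistics binarize the 16×16 confusion
matrix one-vs-rest; MCC uses the conventional value 0 on a vanishing
denominator (verified against scikit-learn on random matrices). High
specificity values are expected from the binary nature of that test.
Relaxed accuracy treats co-members of equivalence sets as correct; only
{c, d} is default — these two strand-flanking PBs are structurally close
and are the dominant confusion in practice — richer substitution-derived
sets are user-suppliable. `candidate_coverage` computes the ceiling of any
selection rule over the positions where the truth is defined *and*
candidates exist, the same denominator any prediction from those profiles is
scored on, making coverage ≥ Q16 a theorem rather than a tendency.

## The synthetic world

The fixture generator emulates exactly what the pipeline consumes:

* **PB strings** from a first-order Markov chain. Default transition
  weights are derived from the alphabet itself: transition x→y is a
  candidate when the six overlapping angles of consecutive prototype
  windows agree within 45° RMSDA, and the candidate set is pruned until
  every emittable 5-letter context is re-assigned to its centre with ≥ 12°
  RMSDA margin. Letters `b`, `g`, `j` have no safe continuation under this
  criterion and drop out of the emittable set. The margin makes
  encode∘build an exact identity at σ = 0 and a robust one at σ = 5°.
* **Backbones** via `build_backbone`; **truth** via re-encoding the built
  coordinates (never asserted, always measured).
* **Homologue families**: per family one master chain; homologues share the
  master's coordinates and PB truth while their sequences are mutated to
  scheduled identities (exactly round(L·(1−id/100)) substitutions). Sharing
  coordinates isolates the sequence-lookup machinery from structural
  divergence — which in real data confounds even 100%-identity pairs (rigid
  body motions, conformational change). The tier table is *measured* by the
  toy clusterer on the generated sequences.

Defaults (3 families × 3 chains of 60 residues, identities 100% and 70%,
σ = 0) give each query both an exact duplicate and a mid-identity relative,
the two regimes the querying schemes distinguish.

What a green end-to-end test establishes: the lookup, tier, selection and
scoring machinery compose correctly, recover a held-out chain through an
identical-sequence homologue, and degrade when only twilight-zone chains
are accessible. What it does not establish: real-PDB accuracy levels —
fixture chains are short, sequence–structure coupling is artificial, and
the full-database experiments require external structure data at a scale
out of this package's scope.

## Numerical choices and degenerate inputs

* Angle wrap: (−180, 180], half-turn → +180; `argmin` over the
  alphabetically ordered prototypes implements the tie rule.
* Degenerate torsion geometry (coincident/collinear points) yields NaN, not
  an exception; NaN propagates to `Z`.
* Chains shorter than 5 residues encode as all-`Z` with a warning; queries
  shorter than 5 are an error.
* All stochastic components take explicit seeds; fixture generation is
  byte-reproducible per seed.

## Known limitations

* The toy clusterer is O(n²) in alignments and is not BLASTClust; tier
  tables for real data should come from an external clustering run.
* mmCIF, side chains, occupancy-weighted ensembles and structure validation
  are out of scope.
* The accuracy-score normalization and log base are package choices (see
  above); scores are comparable within one table, not across normalization
  modes.
* `b`, `g`, `j` never appear in default synthetic worlds, so fixture-based
  tests exercise 13 of 16 letters end-to-end (all 16 are covered by unit
  tests at the assignment and evaluation level).
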