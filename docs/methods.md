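# Methods

This note documents the models and procedures implemented in `srnakit`,
the parameters that matter, the design choices made where several
reasonable options existed, and what the synthetic benchmarks do and do
not demonstrate.

## Quality model and read cleaning

Per-base qualities are interpreted through the Solexa odds transform:
a quality score `sQ` (dimensionless, 0–41) corresponds to an error
probability `E = Y/(1+Y)` with `Y = 10^(−sQ/10)`, equivalently
`sQ = −10·log10(E/(1−E))`. Unlike the plain Phred mapping, `sQ = 0`
means `E = 0.5`, and `E` is bounded by 0.5 for non-negative scores. The
functions are exact inverses (round-trip verified to 1e-9 over the
integer score range).

Cleaning applies four rules per read, in a fixed order, and tallies each
read under the first rule it fails so that
`reads in = reads kept + Σ rejections` holds exactly:

1. **Quality floor** (`quality_floor`, default sQ = 20): the mean
   per-base error probability must not exceed `quality_to_error(20)`
   ≈ 0.0099. The floor is applied to the mean error, not a per-base
   count, because a single bad cycle should not discard an otherwise
   confident read.
2. **Adapter clipping**: the 3′ adapter is removed when the full adapter
   — or, failing that, any adapter prefix of at least 6 nt — is an exact
   suffix of the read. Exact suffix matching keeps the step
   deterministic and is adequate at the error rates the quality floor
   admits; reads without a recognizable adapter are kept unclipped.
3. **Poly-A** (≥ 80% A after clipping): removes oligo-dA artifacts.
4. **Length bounds** (18–30 nt): below 18 nt, mapping and miRNA
   assignment are not meaningful; 30 nt is the upper bound of the
   size-selected fraction in a typical small-RNA library prep.

Clean reads are collapsed to unique tags with per-library counts
(sequences stored as RNA, T→U), sorted by total count then sequence, so
all downstream results are independent of read order.

## Annotation and genome mapping

Contaminant annotation is exact substring matching of each tag against
reference sets, in the priority order rRNA > tRNA > snRNA > snoRNA >
repeat > mRNA fragment; a tag matching several classes keeps the
highest-priority one. Substring matching replaces a heuristic BLAST
search: at tag lengths of 18–30 nt an exact hit is the relevant signal,
and the step becomes deterministic and database-free.

Genome mapping reports **all** occurrences of a tag on both strands
with at most one substitution and no indels. The index stores all
genomic 9-mers; since two disjoint 9-mer seeds fit inside the first
18 nt of any tag, a single substitution can destroy at most one seed,
so seeding on both and verifying by Hamming distance cannot miss a hit
(pigeonhole argument). The mapper is tested for exact agreement with a
naive sliding-window scan on a >100 kb genome. The one-mismatch
tolerance is applied over the whole tag, a stricter reading than
seed-restricted mismatch rules used by some short-read aligners.

## Conserved miRNAs, families, arm pairs

A tag is assigned to the mature reference with the fewest substitutions
(≤ 2, configurable) over a 5′-anchored comparison of the overlapping
prefix, which lets tags run short or long at the 3′ end — where
essentially all length variation occurs — without penalty. Ties break by
(fewest mismatches, longest overlap, lexicographically smallest id);
each tag counts toward at most one miRNA. A minimum overlap of 16 nt
prevents spurious assignments of short tags.

Families are equivalence classes of the seed (positions 2–8 from the 5′
end). With synthetic references there is no curated nomenclature to
inherit, and seed identity is the property that matters functionally.

A miRNA:miRNA* pair is emitted when both arms of one precursor carry
assigned expression; the pair reports each arm's own counts without
re-aggregation.

## Novel miRNA prediction

Unexplained tags that map to the genome are clustered by shared 5′ end
(within 4 nt): homogeneous 5′ ends across supporting reads are the
signature of Dicer processing, and the cluster's most abundant tag
becomes the candidate mature. For each cluster a window with 20 nt
(`flank_proximal`) on one side and 160 nt (`flank_distal`) on the other
is excised in both orientations and folded. Because long windows over
random sequence fold into branched structures, the stem-loop
substructure that the candidate pairs across is then cut out (walking
outward from the terminal loop through enclosing pairs) and re-folded.
A candidate is reported when the re-folded hairpin has

* exactly one terminal loop,
* the mature entirely within one arm — candidates spanning the loop are
  rejected; an intrusion of up to 4 nt into the loop is tolerated
  because predicted loop boundaries wobble and genuine Dicer products
  sit flush against the loop,
* at least 14 of the mature's bases paired, and
* MFE ≤ −18 kcal/mol (ceiling calibrated for the thermodynamic engine).

The default fold engine is ViennaRNA's MFE folder. A bundled
Nussinov-style folder (pair energies GC −3, AU −2, GU −1 kcal/mol,
hairpin loops ≥ 3 nt) provides a dependency-free fallback; its energies
are not on the thermodynamic scale, and candidate sets under the two
engines can differ, so tests pin the engine explicitly.

## isomiR classification and seed edits

Each assigned tag is aligned 5′-anchored to its mature within the
precursor; 5′ shifts of 0–4 nt are scored over the first 10 bases and
the best (smallest) shift wins. Classes: `trim5`, `trim3`,
`ext3_templated` (3′ extension matching the precursor downstream of the
mature), `add3_nontemplated` (extension bases that do not match the
precursor — predominantly U and A in real data), `substitution`
(internal mismatches, recorded 1-based on the mature), and `canonical`
(none of the above; exclusive by construction). A mixed extension
(templated bases then non-templated ones) carries both 3′-extension
classes.

Seed-edit calls scan tags that failed conserved assignment: a call
requires **exactly one** mismatch over the 5′-anchored overlap with some
mature, located at positions 2–8. Tags with two or more mismatches are
never called. Because the conserved step runs first with a 2-mismatch
tolerance, a 1-mismatch-in-seed tag reaching the seed-edit scanner must
have failed assignment; in end-to-end runs most seed-edited reads are
therefore absorbed as conserved isomiRs with a seed-position
substitution, and the dedicated detector is the module to use when seed
editing is the object of study (run it after exact-match assignment).
The substitution spectrum (12 directed types, read-count weighted,
reported per condition and pooled) pools isomiR substitutions and
seed-edit calls, so planted substitution events are recovered either
way. The seed-position histogram reports all of 2–8; positions 2–4 are
searched, not excluded, so an absence of calls there is a finding.

## Differential expression

Counts are normalized per million clean reads; an observed zero is
floored at 0.01 normalized units so fold-changes stay finite, and
miRNAs below 1 normalized unit in both libraries are removed before
testing (at that depth the test has no power and the 0.01 floor would
dominate the fold-change).

The exact test conditions on the count `x` in library A and asks how
surprising the count `y` in library B is under equal relative
abundance:

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) )

with `N1`, `N2` the library sizes in clean reads. The formula's `x`,
`y` are raw integer counts — the factorial form requires integers, and
the library sizes carry the normalization. Point masses are evaluated
in log-gamma space (factorials overflow doubles near x+y ≈ 170); the
lower tail `P(Y ≤ y)` is the CDF of a negative binomial with `x+1`
successes at probability `N1/(N1+N2)` and is computed through the
regularized incomplete beta function, accurate to machine precision
even when the tail has ~1e5 terms.

The two-sided p-value is `min(1, 2·min(P(Y ≤ y), P(Y ≥ y+1)))`.
Splitting the observed point mass between the tails this way makes the
p-value *exactly* symmetric under swapping the libraries, via the
identity `P(Y ≤ y | x, N1, N2) = P(X ≥ x+1 | y, N2, N1)`; doubling two
inclusive tails instead breaks symmetry at small counts by up to the
point mass. Calibration was checked by simulation: on null libraries of
200 miRNAs at 1e5 reads the pooled rejection rate at α = 0.05 is ≈ 0.05.

A miRNA is called differential when |log2(NE_A/NE_B)| ≥ 1 (at least
2-fold) **and** p < 0.05. No multiple-testing correction enters the
primary call — with a single library per condition the test is a
screening tool — but a Benjamini–Hochberg `q` column is emitted for
readers who want it. The `2^−ΔΔCt` helper converts stem-loop qPCR Ct
values (normalized to a reference RNA, relative to a calibrator ΔCt)
into relative expression.

## Target prediction

A miRNA is aligned to a candidate site antiparallel and ungapped; each
miRNA position is Watson-Crick paired, G:U paired, or mismatched. G:U
wobbles are *pairs* for run/adjacency purposes but cost 0.5 mismatch
units in the counting criteria — the accounting that makes "no more
than four mismatches with G-U counting half" coherent. The six filters
(≤ 4 units total; no run of > 2 mismatches; no adjacent mismatches in
positions 2–12; no mismatch at 10–11; ≤ 2.5 units in 1–12; MFE
criterion) are evaluated independently and reported per criterion with
the quantities they threshold.

The MFE criterion reads "at least 75% of the perfect-complement MFE" as
favorability: `duplex_mfe ≤ 0.75 × perfect_mfe`, both negative — the
only physically sensible reading, since a duplex cannot be *more*
negative than required by being closer to zero. The default energy
engine is ViennaRNA's two-sequence hybridization; the bundled additive
model (WC −2.0, G:U −1.0 kcal/mol per pair, +3.0 per mismatch run) is
deterministic and engine-pinned in tests.

Transcripts are scanned at stride 1 with windows of the miRNA's length
anywhere on the transcript (sites in 5′ UTRs and coding sequence are
reported, not just 3′ UTRs); overlapping passing windows merge to the
lowest-MFE site, leftmost on ties; transcripts are capped at 100,000 nt.

## The simulator

The generator emulates the statistical structure the analysis assumes:

* mature lengths 20–24 nt peaked at 22 (so the read-length mode falls
  in 21–23), ~50% starting with U;
* hairpin precursors: the mature in one arm, the star arm its reverse
  complement with 8% substitutions, an unpairable-biased loop of
  9–12 nt, short flanks; every precursor (and contaminant) inserted
  verbatim into a random genome at recorded coordinates;
* baseline abundances log-normal (σ = 1.5), giving the several-orders-
  of-magnitude dynamic range real libraries show; library counts
  multinomial at the configured depth, with condition-B weights scaled
  by `2^(planted log2FC)`; an optional gamma-mixing knob adds
  negative-binomial overdispersion (default off — one pooled library
  per condition has no replicate structure to estimate dispersion from);
* star arms expressed at 20% of their guide by default, so arm pairing
  is exercised;
* isomiR reads at configured rates (3′ trim of 1–2 nt; templated 3′
  extension; non-templated 3′ addition, U with probability 0.6 else A;
  internal substitutions at positions ≥ 9 drawn from a 12-type spectrum
  whose four dominant rates default to G→U 0.159, U→C 0.121, G→A 0.112,
  A→G 0.112, the remainder uniform); seed-edit reads only at configured
  positions within 2–8 (default 5–8, where such edits concentrate);
* a 12-nt constant 3′ adapter on every read; 5% contaminant fragments,
  1% poly-A junk, 5% of reads with qualities that fail the default
  floor.

Every simulated read appears in the truth table (provenance counts sum
to the depth exactly), and planted seed-edit and substitution events are
recorded per type, so recovery can be asserted as equality rather than
correlation.

**What passing these benchmarks does not show.** The simulator draws
bases uniformly, has no sequence-composition bias, no per-cycle error
profile, no PCR duplication structure, no tissue mixture, and its
precursors are cleaner hairpins than genomic ones; contaminants are
random sequences rather than real ncRNA families. Recovery rates on
simulated data are therefore upper bounds on real-data behavior, and
the type-I/power numbers certify the statistics, not the biology.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations sized to make
their assertions sharp but cheap: 200-miRNA count tables at 1e5 reads
per library (50 null replicates for calibration, 20 for power),
read-level libraries of 1e4–1.5e5 reads over 12–40 miRNAs, a ~115 kb
genome for mapping-oracle equality, and 30 precursors for novel-miRNA
recovery. Tolerances: 1e-12 for exact-test identities against direct
factorial evaluation, 1e-9 for tail normalization, exact equality for
read accounting, mapping and filter-oracle agreement. Ties everywhere
break deterministically (lexicographic ids, leftmost positions), and
the whole pipeline is a pure function of (inputs, config, seed) — two
runs produce byte-identical reports.

## Known limitations

* One library per condition: no replicate-aware dispersion modeling; the
  exact test treats sampling as the only noise source.
* Seed-edit calls and sequencing errors are not statistically
  distinguished; a 1-mismatch call is a candidate edit, not a verdict.
* Novel prediction requires the mature to map within a foldable genomic
  window; miRNAs at contig edges or with long-range structure are
  missed.
* Exact-substring contaminant annotation cannot catch diverged ncRNA
  fragments a profile-based search would.
* The additive duplex energy model is a coarse stand-in for
  nearest-neighbor thermodynamics; conclusions that hinge on energies
  should use the ViennaRNA engine.
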