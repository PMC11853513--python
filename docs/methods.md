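# Methods

## The model

A UMI design is an ordered list of allowed-nucleotide sets, one per
position, written as an IUPAC string (`N` = {A,C,G,T}, `S` = {C,G},
`W` = {A,T}, a literal base fixes the position; the full 15-code table is
supported). Three quantities summarise a design:

* **Diversity** `D = ∏ᵢ kᵢ`, the number of distinct sequences it can emit
  (`kᵢ` = size of the allowed set at position i). Computed in exact
  arbitrary-precision integer arithmetic — `4^12 = 16,777,216` for the
  unstructured reference, and patterns much longer than 12 nt must not
  overflow silently.
* **Collision risk**: labeling `n` molecules uniformly from `D` sequences
  is the birthday problem. `P(any collision) = 1 − ∏_{i=1}^{n−1}(1 − i/D)`,
  evaluated as `−expm1(Σ log1p(−i/D))` for stability; the expected number
  of colliding pairs is `C(n,2)/D`. The common exponential approximation
  `1 − exp(−C(n,2)/D)` is exposed separately as a cross-check only.
* **Worst homopolymer run**: the maximum, over emittable sequences, of the
  longest run of a given base — greedy over positions whose set contains
  the base. Adenine-structured designs deliberately accept long worst-case
  poly-A (a fully randomized neighbourhood can always draw A); the figure
  of merit is the trade against cross-hybridization, not the worst case
  alone.

## UMI–UMI interaction rule

Two UMIs are said to interact when they can form an ungapped antiparallel
Watson–Crick duplex with at least `min_run` (default 6) consecutive base
pairs of which at least `min_gc_pairs` (default 3) are G–C. Because every
window of length ≥ `min_run` inside a complementary stretch has at most
the stretch's total G–C count, the rule reduces to: *some maximal
complementary stretch has length ≥ min_run and total G–C pairs ≥
min_gc_pairs*. Two equivalent implementations exist and are held equal in
tests:

* `interacts()` scans every relative offset of `a` against
  `reverse_complement(b)` and tallies maximal match runs — used for single
  pairs, returns the best run's length/G–C count/offset;
* the population simulator intersects *qualifying substring* sets: a pair
  interacts iff a substring of `a` with length ≥ `min_run` and ≥
  `min_gc_pairs` G/C bases equals such a substring of
  `reverse_complement(b)` (the shared substring *is* the duplex; G/C
  content is invariant under reverse complement). Set intersection makes
  the all-pairs scan tractable at n = 10,000 (≈ 5·10⁷ pairs).

G·T wobble pairs are not counted by default (the rule is phrased in terms
of Watson–Crick and G–C pairing); `allow_wobble=True` counts them as
paired, never as G–C, and routes through the pairwise scanner. A UMI is
never compared with itself, and duplicate sampled sequences are kept as
distinct individuals, as in real labeling; sequences shorter than
`min_run` warn and return false rather than raising.

The simulation defaults to 10,000 UMIs per design (the scale at which
designs are screened); examples and tests use 200–2,000 for speed, which
already separates designs by several standard errors.

## Library simulator

The generator emulates a two-step barcoding/adapter PCR workflow at the
level that matters for consensus calling:

* **Labels per molecule** ~ zero-truncated Poisson, rate calibrated by
  Brent root-finding so the truncated mean equals
  `umis_per_molecule_mean` (default **2.0**: each double-stranded molecule
  yields on average two distinct UMI labels after barcoding PCR and
  dilution). Zero labels would mean the molecule was never observed, hence
  truncation.
* **Family size** (reads per label) ~ discretised log-normal, default
  μ = 3.0, σ = 0.8 (median ≈ 20 reads, P(size < 3) ≈ 0.4%), chosen so the
  standard family-size cutoff ≥ 3 keeps ≳ 99% of families at default
  depth. `("constant", k)` is available for analytic tests. The law is a
  synthetic convention: real amplification branching is not modeled.
* **Polymerase errors**: each labeled template suffers per-base
  substitution with `polymerase_error_rate` *once*; every read of the
  family inherits them. This first-cycle approximation captures exactly
  what UMI consensus cannot correct; per-cycle branching is out of scope.
* **Sequencer errors**: per-read, per-base substitutions at
  `seq_error_rate` applied to the insert. The UMI and spacer are read out
  error-free — for 12–14-nt UMIs the error mass is small, and its
  first-order effect (rare spurious singleton families) is precisely what
  the family-size cutoff removes; modeling it as its own channel is
  deliberately omitted.
* **Variants**: each spiked variant is carried by a molecule with
  independent probability `fraction`; realized counts are recorded in the
  truth table.
* **Off-target reads**: uniform random sequence behind a valid UMI+spacer
  prefix; the count is drawn `Binomial(n_on_target, f/(1−f))` so the
  expected off-target *fraction* of the final library equals `f`.
* **Layout**: `UMI + spacer (default CTAG) + insert`, forward orientation,
  single-end, constant high base quality (the collapse pipeline ignores
  qualities). One seeded generator drives every draw, so a config is
  byte-reproducible.

`genome_equivalents(ng)` converts DNA mass to template molecules at 310
molecules/ng (single-locus amplifiable genome equivalents).

## Collapse pipeline

1. **Extraction**: first `umi_len` bases = UMI; the following spacer must
   match within `max_spacer_mismatch` (default 1) substitutions; failures
   are counted, not fatal.
2. **Target assignment**: a k-mer index (default k = 15) replaces genome
   alignment at desk scale. An insert is assigned to the unique amplicon
   holding the plurality of its k-mers, requiring ≥ 50% of insert k-mers
   matched; ties and sub-threshold hits are `UNASSIGNED`. A single
   substitution destroys at most k k-mers of a ~100-nt insert, so true
   reads survive; random sequence matches a 15-mer with probability
   ≈ 4⁻¹⁵ per position and is reliably unassigned. Panels whose amplicons
   share ≥ 50% of k-mers are refused at load.
3. **Clustering**: families are keyed by (UMI, target) — the same UMI on
   two targets labels two molecules. Default is exact UMI matching;
   `merge_distance=1` enables directional merging (a family is absorbed by
   a same-target family within Hamming distance 1 that is ≥ 2× its
   pre-merge size, largest absorber wins, chains resolve to the final
   absorber).
4. **Consensus**: per-position majority over the family's inserts
   (clipped/padded to the amplicon length). Ties go to the reference base
   when it is among the tied alleles, else `N` — conservative against
   false positives. Families below `min_family_size` (default 3) are
   dropped and counted.
5. **Statistics**:
   * molecules per target = consensus reads / 2 (each molecule yields ~2
     labels); fractional value and integer floor are both reported;
   * background error rate = Σ non-reference A/C/G/T alleles / Σ coverage
     over consensus pileups, *excluding* known-SNP and monitored-mutation
     positions; `N` consensus calls stay in coverage but are never counted
     as non-reference (an ambiguity is not an allele);
   * variant calls: every non-reference substitution with consensus count
     ≥ 1 (threshold configurable), reported with VAF
     (= mutant consensus / coverage) and mutant molecules (= count / 2);
     calls at excluded positions are still emitted — exclusion only
     shields the error-rate denominator;
   * off-target fraction = (total − target-assigned reads) / total, so
     spacer-rejected reads count as off-target;
   * overall VAF = Σ mutant molecules over the panel's monitored positions
     / Σ molecules over all assays; molecules/mL when a plasma volume is
     given.

   Indels are not called anywhere; coordinates are 0-based internally and
   1-based in outputs.

All pipeline outputs are invariant under read-order permutation: families
are keyed, and outputs sorted, by (target, UMI).

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* consensus calling
relies on — family-wide template errors vs independent read errors,
ZTP label multiplicity, sub-percent variant fractions, off-target
contamination. It does not reproduce PCR branching dynamics, sequence-
dependent error or amplification bias, quality-score structure, fragment-
length variation, or genome-scale mapping ambiguity. Passing tests
therefore demonstrate that the algorithms are correct and calibrated under
the stated model, not that a particular wet-lab protocol achieves a given
error rate; conversely the error-suppression and recovery properties
tested here are exactly the mechanisms the real workflow exploits.

## Problem sizes and numerical choices

Tests and the acceptance script use 2 amplicons × 1,000 molecules
(≈ 140k reads) for recovery runs, n = 2,000 UMIs × 3 seeds for design
comparisons, and 10⁴ random pairs for oracle equivalence — sizes at which
every statistical check is several standard errors wide while a full run
completes in well under a minute per scenario. Diversity is exact integer
math; collision probabilities are computed in log space; consensus and
pileups use vectorised per-column counts; the ZTP rate is solved by
`brentq` to machine precision. Degenerate inputs: zero reads is an error
("no reads"); zero molecules yields an empty, valid library; `n < 2` UMIs
cannot form pairs and is refused.

## Known limitations

* The interaction rule is a combinatorial stability proxy; no
  nearest-neighbour ΔG, hairpin/kissing-loop structure, or melting
  temperature is computed.
* The k-mer assigner presumes short, mutually distinguishable amplicons;
  it is not a read aligner and does not handle split or reverse-strand
  reads.
* Consensus is single-strand (one UMI per label); duplex strand-aware
  consensus is out of scope.
* Family merging beyond Hamming distance 1 directional absorption, and
  UMI-error channel modeling, are intentionally minimal.
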