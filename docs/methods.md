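# Methods

## The tRNA Adaptation Index

tAI treats a genome's tRNA gene copy numbers (tGCN, indexed by anticodon) as
a proxy for tRNA abundance and asks how well a gene's codons match that
supply. For each sense codon `c` the absolute adaptiveness sums the cognate
Watson–Crick anticodon and the single wobble anticodon able to read it,
each discounted by a selective constraint `s ∈ [0,1]` (0 = pairs as well as
Watson–Crick, 1 = useless):

| codon 3' base | Watson–Crick (s index) | wobble (s index) |
|---|---|---|
| U | A34 (s1) | G34 — G:U (s5) |
| C | G34 (s2) | A34 read as inosine — I:C (s6) |
| A | U34 (s3) | A34 as inosine — I:A (s7) |
| G | C34 (s4) | U34 — U:G (s8) |

Defaults `s = (0, 0, 0, 0, 0.41, 0.28, 0.9999, 0.68, 0.89)` follow the dos
Reis formulation; they are constructor parameters (`WobbleParams`) because
they were estimated for model organisms, not for *Streptomyces* phages. In
prokaryote mode (default: everything here is bacterial/phage) codon AUA is
read by the lysidine-modified CAU-anticodon Ile2 tRNA, `W(AUA) =
(1 − s9)·tGCN(CAU)`, and AUG keeps only its Watson–Crick CAU term.

Relative adaptiveness is `w = W / max(W)`. Codons with `w = 0` (no reading
anticodon in the pool) receive the geometric mean of the non-zero weights;
they are tracked (`zero_substituted`) and the count of imputed codons used
in each score is reported, because a tAI built mostly from imputed weights
says little. A gene's tAI is the geometric mean of `w` over its codons.
Stop codons are never scored; ATG is excluded by default (a one-codon
family offers no synonymous choice) but can be included. All of this is
computed in log space; agreement with a naive product-then-root oracle is
tested to 1e-12.

Caveat that shaped several design choices below: because each pool is
normalized by its own `max(W)`, comparing one gene's tAI *across pools*
responds not only to adaptation but to pool shape — a pool dominated by one
abundant anticodon depresses every other codon's `w`, a flat pool inflates
them. This is a property of tAI itself, not of this implementation.

## Dual-predictor reconciliation

tRNA gene sets are built from two predictors (a structure-aware one,
tRNAscan-SE-like, called P; and an Aragorn-like one, Q) merged with three
rules: (a) same anticodon, same strand, starts within a 10 bp window →
one gene with the Q-side coordinates; (b) exception for CAT anticodons
(Met/Ile2/fMet need structural evidence) → the P-side call is kept; (c) a
P call with undetermined isotype pairing positionally with a Q call → the
Q call, and (c) outranks (b) since an undetermined call carries no isotype
information. Matching is greedy on smallest start-coordinate offset with
two deterministic tie-breaks: identical-anticodon matches outrank
undetermined positional matches at equal offset (without this, an
undetermined P call can steal another call's exact partner, and re-merging
the merged set against an input can grow it — property testing found the
counterexample), then leftmost start. Merging is idempotent; reconciliation
never invents an anticodon absent from both inputs. Pseudo-tRNA calls and
tmRNA genes are excluded from pools by default; unknown-anticodon genes are
excluded with a logged count.

## The paired comparison

For each phage in a manifest the focal gene (default selector: product
regex "major capsid", the usual proxy for translational optimization of
structural genes) is scored under the host pool and under the phage's own
pool; a phage whose own pool is empty and that names a helper is scored
under the helper's pool alone (host+helper mixtures exist via
`combine_pools` for sensitivity analyses but are not the default). The
paired differences go into a Wilcoxon signed-rank test: zeros dropped,
midranks for ties, statistic W⁺ = sum of ranks of positive differences.
The null distribution of W⁺ is built by convolution over the realized
(doubled, hence integer) rank vector — arithmetically identical to
enumerating all 2ⁿ sign assignments and therefore valid under ties — for
n ≤ 50, where float64 still represents the assignment counts exactly; n = 50
also comfortably covers panel sizes of interest while remaining microseconds
fast. Beyond that a normal approximation with tie correction and a 0.5
continuity correction is used; at the boundary the two agree to < 0.01.
Two-sided p = min(1, 2·min(tail probabilities)). An all-zero difference
vector yields a flagged degenerate result (p = 1, n = 0) rather than an
error.

## The synthetic study system

The generator emulates the satellite–helper systems' statistics so the
whole pipeline runs end-to-end with no downloads. Defaults
(`SyntheticConfig`):

- **Phage pools** (`covering` architecture): one isoacceptor anticodon per
  amino-acid family, chosen with per-base GC weighting at `gc_target = 0.49`
  (the helpers' genome GC), remaining copies dealt round-robin; total
  uniform in `pool_size_range = (35, 45)` — the helpers carry 42 and 41
  tRNA genes. Near-uniform copy numbers with family coverage are what real
  phage tRNA sets look like, and they matter for tAI: they keep each
  family's best weight high, so adaptation is expressible.
- **Host pools** (`skewed` architecture): anticodons drawn with replacement,
  per-base GC-weighted at `host_gc_target = 0.71` (*Streptomyces*-like),
  total in `host_pool_size_range = (60, 70)` — a larger, compositionally
  biased bacterial repertoire concentrated on GC-rich anticodons.
- **Focal genes**: amino acids uniform over the 20 families,
  `gene_length_codons = 300` (a typical major-capsid-protein length), codon
  within a family drawn with probability ∝ `w^t` against a designated pool.
  `adaptation_t = 2`; t = 0 is uniform synonymous choice and t → ∞ the
  family argmax, so one parameter spans no adaptation to perfect adaptation.
  An ATG start and TAA stop are appended.
- **Genomes**: linear GenBank records with tRNA features (anticodon
  qualifiers at gene positions 33–35) and CDS features, 60 bp spacers so no
  realistic merge window can cross-pair neighbours. Satellites carry no
  tRNA genes; their gene is adapted to their helper's pool.
- **Predictor noise**: the P view keeps truth coordinates, the Q view's are
  shifted uniformly within ±`jitter` bp (so the inter-predictor discrepancy
  is at most `jitter`), a fraction of P calls is relabeled undetermined,
  and each view independently drops calls. Defaults (3, 0.1, 0.05).

All draws flow from one `numpy` Generator; panels are bit-reproducible
under a fixed seed.

What the generator does **not** emulate: real codon usage is shaped by
amino-acid composition, GC pressure along the genome, and expression level,
not only tRNA supply; real tRNA predictors disagree in structured ways
(introns, pseudogene scoring) rather than by uniform jitter; host
repertoires have isoacceptor structure beyond a GC-weighted draw; genes sit
on both strands. Passing tests therefore demonstrate that the pipeline
recovers a known planted preference under controlled conditions — not that
any particular real phage is adapted to its helper.

## Calibration and numerical choices

- **Type-I error**: a phage-style and a host-style pool give systematically
  different tAI to the *same unadapted* gene (the normalization caveat
  above), so "t = 0 with one pool of each kind" is not a null for the test —
  the asymmetry is real signal. The calibration null draws both pools from
  the phage distribution (`simulate_tai_pairs(..., exchangeable=True)`),
  making the paired differences exchangeable and symmetric about zero.
  Measured rejection: 0.037–0.050 at α = 0.05 (2,000 panels of 16 pairs);
  slightly conservative, as expected for a discrete exact test.
- **Direction recovery**: at t = 2 under the default architectures the
  self-minus-host difference is positive for every pair with a wide margin
  (minimum pairwise difference ≈ +0.2 across seeds), so the 31-pair panel
  yields the maximal rank sum and exact p = 2·2⁻³¹.
- Problem sizes in tests and `scripts/acceptance.py` (2,000 null panels,
  1,000 oracle genes, 50 merge replicates, enumeration up to n = 12) were
  chosen to give stable rates while keeping a full run in the low minutes
  on one core.
- Degenerate inputs: all-zero pools raise a dedicated error at weight
  construction; genes with no scorable codons raise an empty-gene error;
  trans-spliced CDS locations are rejected; ambiguity codes inside a CDS
  skip the affected codons with a logged count instead of aborting a batch.
- %GC counts G, C and S in the numerator over the full length — exact on
  unambiguous sequences, conservative otherwise. Presentation rounding
  (1 decimal for %GC, 4 for tAI) is confined to the CLI; library values are
  full precision.

## Known limitations

- The s-vector defaults were fit to model organisms; *Streptomyces*-specific
  constraints would need species-specific optimization, which is out of
  scope.
- Cross-pool tAI comparisons inherit the normalization caveat; the paired
  design mitigates but does not remove it.
- The deposited-genome checks require a one-time `poolfit fetch` (network);
  offline runs skip them and everything else runs on synthetic data.
- tmRNA genes are never counted in pools; selenocysteine/pyrrolysine
  recoding is not modeled (TGA/TAG are plain stops).
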