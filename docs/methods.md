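# Methods

## Statistics

**Uncorrected p-distance.** For two aligned sequences, sites where either
residue is masked are dropped; over the remaining `compared_sites` the
distance is the fraction that differ. No correction (JC/K2P) is applied —
the downstream clock calibrations are quoted on the uncorrected scale, so
correcting first would double-count saturation. Masking is controlled by a
`SitePolicy`:

- *mode* — `pairwise_deletion` (default) drops masked sites per pair;
  `complete_deletion` drops a site for the whole computation when any
  participating record is masked there. For a single pair the two modes
  coincide.
- *ambiguity* — `treat_as_missing` (default) masks IUPAC ambiguity codes
  like `N`; `strict_mismatch` keeps them comparable but never matching any
  state, themselves included. Both extremes are offered because published
  barcode-divergence protocols rarely state their choice; the default
  matches the de-facto behaviour of common barcoding distance software.
  Gaps (`-`) and `N` are always masked. A pair with zero comparable sites
  has no defined distance and is reported as an error, never as 0.

**Fixed (diagnostic) substitutions.** A site is diagnostic between groups
A and B iff the unmasked members of each group show exactly one residue
each and the two residues differ. "Invariant" is judged over unmasked
members only: a site where one whole group is masked is not evaluable and
is excluded from `evaluated_sites` (the criterion presupposes observed
states; counting such sites as non-diagnostic would leave the count
unchanged but inflate the denominator). Under `strict_mismatch` a site
whose single observed state is an ambiguity code is never reported as
diagnostic — an uncertain base cannot assert a fixed difference. Positions
are 1-based in all output.

**Closest pair.** The minimal inter-group distance scans all
between-group pairs of the full pairwise matrix. Ties are broken
lexicographically on the `(sample_a, sample_b)` id pair and all tying
pairs are reported, so output is reproducible byte-for-byte.

**Clustering.** Haplogroups are the connected components of the graph
joining pairs with p ≤ threshold — single linkage, chosen because the
haplogroup notion is connectivity-like ("reachable through a chain of
similar haplotypes") and needs a single parameter. The default threshold
0.01 sits below the smallest inter-haplogroup minimum the package is
designed around (~2 %) and above typical within-haplogroup polymorphism
(≲0.6 %). Clusters are labelled C1, C2, … by decreasing size, ties by
smallest member id. This is an honest distance-based stand-in for
tree-based lineage delineation, not a replacement for phylogenetic
inference.

**Discordance.** A sample is discordant when its input taxon label differs
from the majority taxon of its cluster. Majority ties are resolved to the
lexicographically smallest taxon and the cluster is flagged, so the caller
can inspect rather than trust such cases.

**Clock.** t = p / r with r a *pairwise* rate in % uncorrected distance
per Myr — no factor of 2, because the calibrations used (1.5 %/Myr for
COI across invertebrates; 2.3 %/Myr for arthropod mitogenomes) are already
pairwise. The interval reports the two point estimates ordered: the faster
rate gives `t_low`. Human-facing values (percentages, Myr endpoints) are
rendered at one decimal with round-half-up; machine output always carries
the raw fractions.

## Synthetic data

**Constructive fixture** (`make_fixture`). The default configuration
emulates a five-haplogroup COI study design on L = 658 sites: reference
haplogroup P1 (18 samples), P2 (6 persea-type samples, 7 diagnostic sites
vs P1, closest-pair total 13), P3 (4, 10, 15), A (22, 11, 16), H (2, 10,
16), plus 3 acentria-taxon samples carrying exact P2 haplotypes
(introgression: the acentria taxon totals 25, split 22/3) and four
outgroup blocks (casta 13, didyma 7, deserticola 14, trivia 9 samples) at
≥6 % divergence — 98 records in all. Construction is by planting, not
simulation:

- a random base sequence (seeded NumPy generator; all draws flow from one
  generator, so the output is byte-reproducible given the seed);
- per haplogroup, a block of consecutive diagnostic sites where every
  member carries one substituted base;
- per haplogroup, a block of "extra" sites realising the non-fixed part of
  the closest-pair total: every group member carries a substituted base
  while one reference sample carries a third state. Such a site differs in
  *every* group×reference pair yet is polymorphic within the reference,
  hence not fixed — so every inter-group pair differs at exactly
  `closest_pair_total` sites plus whatever polymorphism the specific pair
  carries, making the planted total the exact minimum by construction (no
  post-hoc verification or reseeding needed);
- per group, within-group polymorphic sites assigned round-robin to
  members other than the designated closest sample (one alternative
  carrier per site);
- disjoint outgroup blocks of 45 substituted sites (6.8 %).

All blocks are disjoint; the config validator rejects plans whose site
budget exceeds L, a diagnostic count above its closest-pair total, or an
unknown introgression donor. The truth table records every planted
quantity, both groupings (taxon-level input labels and haplogroup-level
assignments) and the introgressed sample ids.

What the fixture does *not* emulate: recombination-free but
mutation-realistic site patterns (transition/transversion bias, codon
structure), length variation or sequencing artefacts, and continuous
within-group diversity clines. Exact recovery of the planted statistics
therefore shows the *operations* are correct, not that real data would
yield these numbers.

**Jukes–Cantor simulator** (`simulate_jc`). Two lineages evolve
independently from a random root for `split_time` t Myr at per-lineage
rate mu (substitutions/site/Myr): per site the substitution count is
Poisson(mu·t) and each event moves to a uniformly chosen different base.
The expected uncorrected distance between the sides is
(3/4)(1 − exp(−(8/3)·mu·t)), saturating at 3/4. Samples within a side are
copies of the side's evolved ancestor; an optional introgression event at
time t_i transfers haplotypes that share the donor lineage's history until
t_i and then evolve on their own branch of length t_i. Defaults
mu = 0.009 subs/site/Myr (pairwise 2·mu = 1.8 %/Myr, inside the
1.5–2.3 %/Myr calibration band) and t = 1.3 Myr put the expected distance
at ~2.3 %, the regime the clock analysis targets.

## Test design and problem sizes

- Oracle equivalence: the distance matrix, diagnostic-site report and
  clustering are checked for exact agreement against naive per-site /
  double-loop reference implementations (kept in `tests/_oracles.py`, free
  of package internals) on 100+ random alignments with n ≤ 12, L ≤ 100 and
  random gaps/ambiguities, under all four policy combinations.
- Parameter recovery: 200 replicate pairs at t = 1.3 Myr, L = 658,
  mu = 0.009 recover t within 15 % relative error via the pairwise-rate
  clock; the residual bias is the uncorrected-distance compression
  (expected p = 2.30 % vs linear 2.34 %, ~1.5 % downward). The
  small-divergence mean-distance check (mu = 1e-4) uses 2000 replicates so
  Monte-Carlo error (~5 % relative) sits well inside the 15 % band; the
  saturation check uses 20 replicates at mu·t = 6 against 0.75 ± 0.02.
  All stochastic tests run on fixed seeds.
- The printed holotype barcode (654 bp as printed, stored with its
  original 8-line wrapping in `tests/data/KY777529.fasta`) must parse into
  a single all-ACGT record.

## Limitations

- Single-linkage clustering is threshold-sensitive: lineages separated by
  less than the threshold chain together. The 1 % default assumes a
  barcode gap between within-group and between-group divergence.
- The discordance scan detects *mitochondrial* introgression only, and
  only when the donor haplogroup survives as a distinct cluster.
- The clock assumes rate constancy and a pairwise calibration on the
  uncorrected scale; at p ≳ 5 % the uncorrected distance visibly
  understates divergence time.
- Inputs must be pre-aligned; the package performs no alignment and no
  chromatogram handling.
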