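# barcodiv

DNA-barcode divergence analysis for mitochondrial haplogroups: diagnostic
(fixed) substitutions, minimal inter-group uncorrected *p*-distances,
distance-threshold haplogroup clustering with introgression screening, and
strict-clock dating of lineage splits.

## The problem

Short mitochondrial markers — typically the 658-bp 5′ fragment of *COI* —
are the workhorse of species delimitation in insects. Given an alignment of
barcodes partitioned into groups (taxa or haplogroups), two classic
criteria quantify how divergent two groups are:

1. **Fixed (diagnostic) substitutions** — the number of sites invariant
   within each group but showing different states between them. For groups
   *A* and *B* a site *i* is diagnostic iff every unmasked member of *A*
   shows one residue *x*, every unmasked member of *B* shows one residue
   *y*, and *x ≠ y*.
2. **Minimal inter-group uncorrected *p*-distance** — over all pairs with
   one member in each group, the smallest proportion of compared sites at
   which the two sequences differ,
   *p* = (differing sites)/(compared sites), counting both fixed and
   non-fixed substitutions and applying no multiple-hit correction.

Haplogroups themselves are recovered as single-linkage clusters of the
pairwise *p*-distance matrix (connected components of the graph joining all
pairs with *p* ≤ threshold; default threshold 1 %). Comparing clusters with
the taxon labels the samples carried in flags taxon/haplogroup
**discordance**, the signature of mitochondrial introgression after
hybridization: a minority of one species' samples carrying another
lineage's haplotype.

A divergence time follows from a strict clock with a *pairwise* rate *r*
(percent uncorrected pairwise distance per million years):
*t* = *p* / *r*. Two standard arthropod calibrations bracket the estimate —
1.5 %/Myr (*COI*, various invertebrates) and 2.3 %/Myr (whole mitogenome,
various arthropods) — the faster rate giving the lower bound.

The package ships two synthetic-data generators: a **constructive fixture**
that plants a five-haplogroup *Melitaea persea*-complex-like design
(diagnostic counts, closest-pair totals, within-group polymorphism,
outgroup blocks and a 3-of-25 introgression split) so every statistic is
recovered exactly, and a seeded **Jukes–Cantor simulator** for stochastic
parameter-recovery experiments.

## Worked example

Generate the default fixture and run the divergence table:

```sh
barcodiv fixture --seed 1 --out demo
barcodiv diagnose --alignment demo/fixture.fasta --groups demo/haplogroups.tsv --out demo
```

which prints `fixture: 98 records × 658 sites` and writes
`demo/divergence.tsv`; the rows against the reference haplogroup P1 read

```text
group_a  group_b  fixed_substitutions  min_p_percent  closest_a  closest_b  differing_sites
P1       P2       7                    2.0 %          P1-01      ACE-23     13
P1       P3       10                   2.3 %          P1-01      P3-01      15
P1       A        11                   2.4 %          P1-01      A-01       16
P1       H        10                   2.4 %          P1-01      H-01       16
```

i.e. haplogroup A differs from P1 by 11 fixed substitutions and a minimal
uncorrected distance of 16/658 = 2.4 %; P2, the introgressed haplogroup, is
the closest to P1 (7 fixed substitutions, 2.0 %). Clustering the
persea-complex samples at the default 1 % threshold yields the five
lineages, and the discordance report flags exactly the three
acentria-taxon samples carrying P2 haplotypes. Dating the A–P1 split:

```sh
barcodiv date --p-percent 2.4
```

```json
{ "t_low": 1.0434782608695652, "t_high": 1.5999999999999999,
  "rendered": "1.0–1.6 Myr" }
```

— under the 2.3 %/Myr calibration the split is ~1.04 Myr old, under
1.5 %/Myr ~1.6 Myr, so the haplogroup is dated to roughly 1–1.6 million
years.

## Library surface

```python
from barcodiv import (
    read_fasta, read_grouping, restrict,            # io
    p_distance, distance_matrix,                    # distances
    fixed_substitutions, min_intergroup,            # divergence criteria
    divergence_summary,                             # reporting
    single_linkage_clusters, discordant_samples,    # haplogroups
    divergence_time, divergence_interval,           # clock
    make_fixture, simulate_jc,                      # synthetic data
)
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
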