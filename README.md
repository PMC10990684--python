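# mike

Alignment-free, assembly-free phylogenetics from raw sequencing reads.

Building a phylogeny for dozens or hundreds of resequenced samples normally
means mapping to a reference, calling SNPs and aligning — expensive, and
impossible when no reference exists. `mike` instead estimates pairwise
genome similarity directly from read k-mer content using a prefix-grouped
one-permutation MinHash sketch, converts similarity to an evolutionary
distance, and infers a distance tree. It is aimed at population/genus-scale
studies (plant accessions, polyploid crops, strain panels) where relative
relationships matter more than deep-time branch lengths.

## Method in brief

Every read is decomposed into canonical k-mers (k = 21 by default), 2-bit
encoded (A=00, C=01, G=10, T=11) and counted; k-mers seen fewer than
`min_count` (default 2) times are dropped. Each k-mer code splits into a
prefix (⌈k/2⌉ bases) and suffix (⌊k/2⌋ bases); k-mers sharing a prefix form
a group, and a single shared random permutation π of [1, 4^⌊k/2⌋] assigns
each group the fingerprint h_π = min π(suffix) over its present suffixes —
one MinHash value per occupied group instead of one global sketch. For two
samples the Jaccard coefficient J = |S₁∩S₂|/|S₁∪S₂| is estimated as the
fraction of occupied groups whose fingerprints agree, and mapped to a
per-site evolutionary distance via the Jukes–Cantor-style identity

    d = 1 − (2J/(J+1))^(1/k),

from W/L = 2J/(J+1) and the k-mer survival probability (1−d)^k. Trees are
inferred from the distance matrix with NJ, BIONJ (default) or UPGMA, and
topologies are compared with the normalized Robinson–Foulds distance
(symmetric bipartition difference / 2(n−3)). A genome-evolution simulator
(region-structured Jukes–Cantor substitutions; haploid, autotetraploid,
allotetraploid and WGD/hybridisation polyploid lineages; Illumina-like
reads) provides ground truth for every stage. See `docs/methods.md` for
the full model description and design choices.

## Worked example

Simulate a six-leaf haploid lineage (100 kb genome, 40 generations,
15× reads with 1% substitution error), sketch the read sets, build the
distance matrix and BIONJ tree, and score it against the tree built from
the recorded true divergences:

```
mike sim --mode haploid --seed 7 -L 100000 --generations 40 \
         --n-offspring 6 --coverage 15 --err-rate 0.01 -o data
mike sketch data/*.fastq -k 21 --min-count 2 --seed 42 -o sketches
mike dist sketches/*.msk -o d.phylip
mike tree --method bionj d.phylip -o mike.nwk
mike tree --method bionj data/true_dist.phylip -o ref.nwk
mike rf mike.nwk ref.nwk
```

The distance matrix (`d.phylip`) comes out as:

```
6
hap01       0.000000  0.023713  0.018718  0.023788  0.010902  0.023651
hap02       0.023713  0.000000  0.023336  0.017927  0.023557  0.010917
hap03       0.018718  0.023336  0.000000  0.023323  0.018805  0.023167
hap04       0.023788  0.017927  0.023323  0.000000  0.023638  0.017910
hap05       0.010902  0.023557  0.018805  0.023638  0.000000  0.023394
hap06       0.023651  0.010917  0.023167  0.017910  0.023394  0.000000
```

Entries are estimated per-site substitution probabilities: the sister
pairs (hap01, hap05) and (hap02, hap06) sit at ≈0.011, within-clade
non-sister pairs at ≈0.018–0.019, and cross-clade pairs at ≈0.023–0.024,
matching the simulated split depths. `mike rf` prints

```
0.000000
```

— the sketch-based BIONJ tree has exactly the reference topology. The
inferred tree itself (`mike.nwk`):

```
((((hap01:0.0055,hap05:0.0054):0.0041,hap03:0.0092):0.0051,hap04:0.0090):0.0034,hap02:0.0055,hap06:0.0054);
```

The same pipeline is available as library calls (`mike.count_kmers`,
`mike.build_sketch`, `mike.estimate_jaccard`, `mike.distance_matrix`,
`mike.bionj`, `mike.rf_distance`, `mike.simulate.*`).

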