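# Methods

## The sketch

A sample's content is reduced to the set *S* of distinct canonical k-mers
(default k = 21) surviving an abundance filter. Each 2k-bit k-mer code
(A=00, C=01, G=10, T=11, first base high, so integer order = lexicographic
order) is split into a prefix of ⌈k/2⌉ bases and a suffix of ⌊k/2⌋ bases.
K-mers sharing a prefix form a *group*. One random permutation π of
[1, 4^⌊k/2⌋], shared by every sample of a run, ranks the suffixes; a group's
fingerprint is

    h_π(g) = min { π(s) : suffix s present in group g },

the first non-zero entry of the group's one-hot existence vector multiplied
by π. A sketch is the sorted list of (prefix, fingerprint) pairs for
occupied groups — at most 4^⌈k/2⌉ entries drawn from a 4^k universe. Because
the input codes are sorted, groups are contiguous runs and the sketch is
built in one linear pass.

**Jaccard estimator.** For two sketches sharing (k, split, π),

    Ĵ = #{groups occupied in both with equal fingerprints}
        / #{groups occupied in at least one}.

For a group occupied in both samples, P(equal fingerprints) over random π
is exactly the Jaccard similarity of the two suffix sets (verified in the
tests by exhaustive enumeration of all permutations of a small domain). A
group occupied in only one sample counts as a mismatch (denominator only);
groups empty in both are ignored — no densification, matching the
"smallest non-zero value" selection rule. Consequences worth knowing:

* E[Ĵ] is the *mean per-group* suffix Jaccard over occupied groups, not the
  size-weighted global J. When groups are (union-)singletons — the typical
  regime at k = 21, where the 4^11 prefix space dwarfs genome k-mer counts —
  the two coincide and Ĵ equals J exactly. When many groups hold several
  k-mers (small k, or error-inflated sets), Ĵ acquires a mean-of-ratios
  bias of order a few 10⁻² relative; the evaluation harness measures it.
* Conditional on the two sets, only multi-k-mer groups respond to the
  permutation at all, so the across-seed variance of Ĵ is far below the
  nominal binomial J(1−J)/U scale.

**Permutation.** An explicit Fisher–Yates table over [1, 4^⌊k/2⌋] from
numpy's PCG64 generator; the seed (default 42) is recorded in every sketch
file and compatibility is enforced, not assumed. Suffix lengths above 12
bases are refused (the table would exceed 4^12 entries).

## K-mer counting

Counting is internal (no external counter needed): reads are packed into a
padded byte matrix and window codes are produced by a rolling two-bit shift
over columns, vectorised across reads; whole genomes use a shifted-slice
path vectorised across positions. Windows containing any non-ACGT character
are skipped — substituting would fabricate sequence. Counting is canonical
by default (min of code and reverse complement) because read data is
unstranded. The abundance filter defaults to min_count = 2, the customary
counter default, which removes the great majority of singleton
sequencing-error k-mers; it is a flag, not a constant. KMC text dumps
(`KMER<TAB>COUNT`) are accepted interchangeably with reads; counts of a
k-mer and its reverse complement are pooled before filtering.

## Distance

With two equal-length genomes sharing W of ~L k-mers each,
J = W/(2L−W) gives W/L = 2J/(J+1). Under Jukes–Cantor substitutions a
k-mer survives unchanged with probability (1−d)^k, so

    d = 1 − (2J/(J+1))^(1/k),

mapping J = 1 → d = 0 and J = 0 → d = 1 (no infinity, unlike a log
transform). The derivation assumes equal genome lengths, independent
k-mers, and low divergence; above d ≈ 0.2 at k = 21 the Jaccard signal
saturates. Matrices are written as relaxed (whitespace-delimited) square
PHYLIP because realistic sample accessions exceed ten characters.

## Trees

NJ (Saitou–Nei Q-criterion, standard two-point branch lengths), BIONJ
(same agglomeration order; reduction weights λ minimise the variance of
the reduced matrix under Gascuel's var ∝ distance model, clamped to [0,1];
λ = 1/2 reproduces NJ's update exactly), and UPGMA (average linkage,
rooted ultrametric). Numerical contracts: pair-selection ties break at the
lowest (i, j) index pair; negative branch lengths are clamped to zero and
counted in the log; n < 3 taxa is an error. Trees are dendropy objects, so
Newick round-trips and bipartition handling come from dendropy.

Robinson–Foulds comparison is the classical symmetric difference of
non-trivial bipartitions normalised by 2(n−3), the maximum for two fully
resolved unrooted trees; rooted inputs are unrooted (basal bifurcation
collapsed) first. The matching-based "generalized RF" family is
deliberately not implemented; the score here is the classical normalized
form and is labelled as such.

## Simulator

The generator reproduces the package's evaluation conditions rather than
any particular organism:

* **Ancestor** — i.i.d. sequence, GC fraction 0.5 by default.
* **Regions** — alternating conserved/mutable blocks (default 10 kb blocks,
  conserved fraction 0.5). Conserved sites never mutate; the invariant is
  asserted after simulation.
* **Substitutions** — per generation, each mutable site flips independently
  with probability `rate` (default 10⁻³), uniformly to one of the three
  other bases (Jukes–Cantor). Default total depth is 50 generations, giving
  ~0.05 expected per-mutable-site divergence root-to-tip — a shallow,
  genus-level scale chosen to stay well below k-mer saturation; a run of
  ~1000 generations at rate 5·10⁻⁵ is statistically the same process.
* **Haploid** — lineages bifurcate on a balanced schedule (splits evenly
  spaced in time, lowest-index lineage first when the leaf target is not a
  power of two) so a true binary genealogy exists for RF scoring.
* **Autotetraploid** — each generation draws 2 of the 4 copies, mutates
  them, and doubles them into the next 4-copy genome (unreduced-gamete
  style). The doubling bottleneck keeps one lineage's copies coherent.
* **Allotetraploid** — two tetraploid pools first diverge from the common
  ancestor, then each generation both pools advance one tetraploid step,
  one paternal and one maternal chromosome pair are drawn, and two hybrid
  offspring (2+2 copies, each with its own fresh mutation round) are
  emitted, forming a sister cherry on a time-ladder genealogy; 2n leaves.
* **Polyploid** — a validated event schedule of whole-genome duplications
  (copy doubling) and hybridisations (half the copies from each even-ploidy
  parent); the default cascade emits ploidies 2, 4, 6, 8, 12, 16.
  Hybridisation is a reticulation, which a tree cannot carry; the hybrid
  attaches to its lower-ploidy parent in the recorded genealogy, and the
  polyploid dataset is accordingly the hardest case for tree scoring.

True divergence between two genomes is the realised per-mutable-site
Hamming fraction, averaged over all copy pairs for polyploids, recomputed
directly from the final sequences.

**Reads** are drawn uniformly from both strands of all copies until total
bases reach coverage × L × ploidy, with i.i.d. substitution errors
(default 1%) and constant Phred qualities encoding the error rate. No
indels, no quality profile, no GC bias, no duplicates: substitution errors
are the operative noise for k-mer content, which is all the sketch sees.
Passing tests therefore demonstrate robustness to substitution noise and
coverage sampling, not to the full error structure of real instruments.

## What the benchmarks show

`mike.evaluation` (driven by `scripts/acceptance.py` and the acceptance
tests) runs two experiments sized for a single CPU: (1) ten same-genome
read-set pairs from a 1 Mb genome at coverages 10–50×, comparing the
sketch estimate against the exact sorted-set Jaccard of the same filtered
k-mer sets; (2) a 16-leaf haploid lineage at 500 kb sequenced at 20×,
comparing the BIONJ tree from sketch distances against the BIONJ tree from
true divergences (median normalised RF over three seeds).

A property of experiment (1) worth stating plainly: at a 1% substitution
error rate, error k-mers recur (each genomic k-mer has only 63
single-substitution neighbours), so above roughly 15× coverage they pass
the min_count = 2 filter in numbers that pull the *exact* Jaccard of two
same-genome read sets well below 0.9 and move the estimator out of its
near-singleton-group regime. The harness reports what it measures; at a
0.1–0.2% error rate the same experiment stays in the J > 0.9, RMSE < 0.01
regime throughout.

## Known limitations

Equal-genome-length assumption in the distance derivation (no correction
for strongly unequal sizes); distance-based trees only; k ≤ 31; in-memory
counting (desk-scale inputs); classical RF only; simulator omits indels,
recombination, selection and coalescent structure.
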