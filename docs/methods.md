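# Methods

`bathyvir` implements the analysis chain used to recover and characterize
complete genomes of uncultured viruses from fosmid-scale metagenomic
contigs, together with a synthetic-data generator that plants an exact
expected answer for every stage. This note describes the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not show about real data.

## Completeness by terminal redundancy

Tailed dsDNA phages (caudovirales) replicate through concatemers in which
the genome is repeated head-to-tail. A fosmid insert longer than one genome
unit therefore carries the first bases of the genome again at its end. We
call a contig a complete, circularly permuted genome when an exact prefix
of the contig reappears as its suffix — a terminal direct repeat — strictly
longer than `min_repeat` (default 50 bp, strict `>`). Trimming the second
repeat copy yields the circular genome; the trimmed sequence is a rotation
of the underlying genome, and `trimmed_len + repeat_len` equals the contig
length.

Numerical choices: repeats are exact matches only (no mismatch tolerance) —
the conservative, testable reading of "repeated sequence"; the repeat is
anchored at the contig termini by default, with an opt-in `max_offset` (up
to ~100 bp) for ragged assembly ends, whose cost grows quadratically in the
offset. The detector finds the longest border (prefix = suffix) by probing
occurrences of the 16-bp prefix, which is exact and fast: for a random
30-kb contig the chance of a >=51-bp terminal identity is < 4^-51 * L^2, so
the expected false-complete rate is indistinguishable from zero, and the
test suite asserts zero over 1,000 random 30-kb contigs.

## Contig classification

External annotation pipelines are out of scope; instead gene calls carry a
closed marker-category vocabulary (terminase, portal, tail, capsid,
integrase, other_viral, eukaryotic_viral, cellular, tRNA, unknown) supplied
through an editable label-to-category map. Classification codifies manual
curation rules:

- **eukaryotic_viral**: more than `euk_majority` (default 0.5) of
  categorized genes are eukaryotic-viral markers;
- **provirus**: a maximal block of viral/integrase/unknown genes containing
  at least `min_viral` (default 3) structural viral genes, flanked on at
  least one side by `min_flank` (default 2) consecutive cellular genes;
- **caudoviral**: at least `min_viral` structural viral genes and no
  cellular tract of `min_flank` at either contig end;
- **cellular**: no viral genes at all; anything else is **ambiguous**.

Decision order is eukaryotic_viral, provirus, caudoviral, cellular,
ambiguous, so every contig gets exactly one label. Integrase presence is
recorded but not required for a provirus call, and integrase does not count
toward `min_viral` (it marks lysogeny, not virion structure). `min_viral=3`
and `min_flank=2` are this package's quantification of qualitative curation
practice and are exposed in the config. A naive six-frame ATG-to-stop ORF
caller (`find_orfs`, minimum 60 codons) is provided as a test stand-in for
a real gene predictor.

## Alignment core

All comparisons go through one affine-gap local aligner. Scoring:
nucleotide `(match, mismatch, gap_open, gap_extend) = (+2, -3, -5, -2)`;
protein BLOSUM45 with gaps `(-15, -2)`. A gap of length L costs
`gap_open + L * gap_extend`. When the query-by-subject product is at most
2e6 dynamic-programming cells the exact Smith-Waterman matrix is computed
(numba kernel); larger problems use 13-mer seed-and-extend, where candidate
seed diagonals are clustered into windows and each window is resolved with
the same exact kernel. For read-length queries the top score therefore
equals the optimal local score whenever a seed exists; reads too diverged
to share a 13-mer with the reference (well below the recruitment identity
filter) can be missed, which is the standard trade of seeded search.
Identity is matched columns over all alignment columns including gaps; N
(nucleotide) and X (protein) never count as matches. Ties between
equal-scoring hits break by lowest subject id, then lowest subject start.

E-values use the Karlin-Altschul form `E = K * m * n * exp(-lambda *
score)` with fixed per-scheme constants (nt: K=0.41, lambda=0.625; aa:
K=0.0551, lambda=0.2291). These are coarse; only the threshold semantics of
the downstream filters are contractual, never numerical agreement with any
external search tool. The test suite checks the aligner's optimal scores
against Biopython's exhaustive `PairwiseAligner` on hundreds of seeded
random pairs in both alphabets.

Maximal exact matches (for att sites) are enumerated by k-mer seeding
(k = min(min_len, 14)) with maximal extension on both strands; every match
of at least `min_len` contains a seed, so the enumeration equals the
brute-force set of maximal common substrings, which the tests verify by
full diagonal scanning.

## Genome grouping by shared protein content

For an ordered genome pair (A, B), each A protein's best hit among B's
proteins (highest score, ties by subject order) is *conserved* when the
aligned region is >30 aa (strict), the E-value is <=0.01 and identity is
>30% (strict); one hit per protein. The directed fraction
`f(A->B) = conserved(A,B) / conserved(A,A) * 100` is normalized by the
query genome's self-comparison; since "which self" is ambiguous, the matrix
entry symmetrizes the two directions by arithmetic mean (config: mean, min
or max), giving a symmetric matrix with diagonal 100. Genomes connected at
strictly >20% form groups as single-linkage connected components;
singletons are allowed. Raising the threshold provably refines the
partition.

A shared-4-mer prefilter skips protein pairs with no common 4-mer before
aligning; a hit clearing the >30%-identity/>30-aa bar essentially always
shares a 4-mer, and the filter makes the all-vs-all 28-genome comparison
run in seconds.

## Fragment recruitment and RPKG

Reads are aligned to each genome; a hit is recruited only with >95%
identity, alignment length >50 bp and E-value <1e-5, all strict (boundary
values excluded). Each read counts toward at most one genome — its best
filtered hit, ties broken by lowest genome id then position — with a config
flag to count all filtered hits instead. Abundance is
`RPKG = n_recruited / (genome_len/1000) / (dataset_bases/1e9)` (reads per
kilobase of genome per gigabase of dataset); report tables flag profiles
above the strict >2 RPKG display threshold. Plot series place one point per
recruited read at its alignment midpoint with identity in percent, so plots
are bit-reproducible. Datasets are depth-classed as surface (<500 m),
mesopelagic (exactly 500 m) or bathypelagic (>500 m).

## GC profiles and bimodality

Per-read GC percent (N ignored; zero-information reads excluded with a
warning) is binned at 1% into a [0, 100] histogram. Modes are local maxima
of a moving-average smoothed histogram (window 5 bins) with prominence at
least 5% of the smoothed maximum and separation of at least 10 GC
percentage points; the histogram is zero-padded so edge modes are
detectable. This is an operationalization of visual bimodality, not a
formal dip test, and the parameters are exposed in config.

## Host prediction

Site-specific integration duplicates a core sequence present as attP next
to the phage integrase and as attB at the 3' end of a host tRNA. Candidate
links are all maximal exact matches strictly longer than 30 bp (100%
identity by construction) between a phage and host contigs, both strands. A
link is significant when the host-side interval overlaps a tRNA feature by
at least 1 bp (config option to require containment) and the phage-side
interval lies within 5,000 bp of an integrase gene — the proximity radius
is this package's quantification of "close to the integrase", exposed in
config. Multiple links are ranked by match length, then integrase distance.
CRISPR spacers are matched by ungapped scanning of both strands with a
mismatch budget (default 0); spacers under 20 bp are skipped with a
warning.

## Synthetic data: what it emulates, and what it does not

Generators are fully deterministic under a seed; one global seed expands to
per-operation children through numpy `SeedSequence` spawn keys
(`child_seed(seed, counter)`).

- **Genomes**: i.i.d. bases at a target GC, lengths and GC drawn by default
  from 29.8-41.2 kb and 30-61% — the observed ranges for complete deep-sea
  caudoviral genomes that this analysis targets.
- **Fosmid contigs**: a walk of `insert_len` bp along the circular genome
  from a seeded offset; walks longer than the genome plant a terminal
  repeat of exactly `insert_len - genome_len` bp.
- **Hosts**: the att core is lifted from the phage 200 bp downstream of its
  integrase and inserted as the 3' end of a host tRNA; bases adjacent to
  the core are forced to mismatch so the planted exact-match length is an
  exact statistic. `make_att_host` plants attB only (the
  uninfected-host-relative case, with a 55-bp default core mirroring the
  reported attB/attP hit); `make_host_with_provirus` additionally performs
  Campbell-style integration, duplicating the core as attL/attR around the
  inserted, rotated phage, with cellular gene calls outside and viral ones
  inside.
- **Reads**: fixed-length, substitution-only errors (each base flipped with
  probability 1 - identity to one of the three other bases), uniform start
  and strand over weighted source contigs, so mismatch counts are exactly
  Binomial(L, 1 - identity). Depth communities mix a low-GC and a high-GC
  source genome; weight 0 emulates photic-zone unimodality.

Not emulated: indels and platform error profiles (indel handling in the
aligner is tested with hand-built cases instead), read-length
distributions, chimeras, real genome composition (coding structure, skew,
repeats), and real annotation noise. Passing tests therefore demonstrate
the correctness of the decision rules and arithmetic under the stated
model, not end-to-end accuracy on real libraries — in particular, real
contigs may carry ragged ends (see `max_offset`) and real annotations
mislabel categories, which no synthetic test here measures.

## Problem sizes

The default verification runs use 30-kb contigs (1,200 for the
false-positive bound), 500 random alignment pairs up to 500 symbols, 28
genomes of 10 proteins (~100-160 aa) for grouping, 5,000 perfect 100-bp
reads for the RPKG identity, 100 phage/host pairs for att recall, and
4,000-read GC mixtures — sizes chosen so the whole suite completes in
about a minute on one core while keeping every binomial/chance bound far
from its threshold. The bundled demo (8 genomes, 2 hosts, 3 read datasets)
runs end-to-end in a few seconds.

## Known limitations

- E-values are internally consistent but not comparable to external tools.
- Seeded search can miss hits below ~90% identity for 13-mers; recruitment
  filters discard such hits anyway, but sensitivity analyses at lower
  identity should reduce `k`.
- The conserved-hit prefilter can in principle drop a >30%-identity hit
  with no shared 4-mer; disable with `prefilter_k=0`.
- Grouping treats "normalized by self-comparisons" as query-side
  normalization with mean symmetrization; min/max are available where the
  distinction matters.
- Provirus calls require categorized flanks; contigs with sparse annotation
  degrade to caudoviral/ambiguous.
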