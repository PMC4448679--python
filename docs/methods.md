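# Methods

## Signal model

ChIP-exo reads are reduced to their most 5′ base: a plus-strand read counts
at its leftmost coordinate, a minus-strand read at `end − 1`. These 5′ ends
mark where lambda exonuclease stalled, about 5–6 bp short of a protein:DNA
cross-link, so their strand-specific pile-up around a binding site is treated
as the primary signal. Reads are counted at their 5′ bp regardless of length;
paired-end mates, if present, are counted as independent single-end reads
(with a warning), since ChIP-exo libraries are typically single-end. Reads
are filtered at `min_mapq = 1` by default, and duplicates are **kept** by
default (`dedup = False`): exonuclease stops legitimately stack at identical
coordinates, so deduplication would erase exactly the signal of interest.
Both knobs are exposed.

## Motif matching

A position weight matrix stores column-stochastic probabilities over
{A,C,G,T}. Counts read from JASPAR (2014 4-row dialect) or TRANSFAC blocks
are regularized with a total pseudocount of 0.01 per column, split by
background frequency (0.0025 per base under the default uniform background),
which keeps log-odds finite and matches common practice. The background is
uniform by default and overridable, e.g. from a genome composition estimate.

Scores are additive log₂-odds. For p-value thresholds the per-column
log-odds are rounded onto a lattice of 10⁻³ log₂ units (floored at −30) and
the exact distribution of the lattice score under the i.i.d. background is
computed by dynamic programming — a convolution over columns, linear in the
lattice span. `threshold_for_pvalue(p)` returns the smallest attainable
lattice score whose exact tail mass is ≤ p. Scanning compares window scores
on the same lattice, so thresholding is exact with respect to the
discretized score; the discretization error per window is at most
L · 5·10⁻⁴ log₂ units, negligible against any motif's information content.
Because a sum of independent per-column scores does not depend on column
order, the distribution is cached keyed by the (background, column multiset)
pair; permuted motifs share the entry, which is exact, not an approximation.

Windows containing non-ACGT symbols are skipped rather than scored (their
log-odds would be undefined). Overlapping same-motif hits are greedily
resolved keeping the higher score, with ties going to the + strand and then
the leftmost site; palindromic double-hits (same window matching in both
orientations with equal score) therefore keep the + strand. All resolved
hits are kept per region — footprints are per-site quantities, not
best-per-peak. Consensus-pattern scanning applies no overlap resolution:
a sequence satisfying the pattern in both orientations is genuinely two
oriented sites.

Degenerate consensus patterns are IUPAC strings with a set of *constrained*
1-based positions that must match the code and *anti* positions that must
carry any base except one matching the code. Only A/C/G/T/N occur in the GBS
consensus, but all IUPAC codes are supported.

## Anchors and orientation normalization

Each hit's anchor is the floor-center of the site measured along the motif's
own 5′→3′ axis: `start + L//2` on +, `end − 1 − L//2` on −. For odd motif
lengths the two coincide with the plain floor-center of the interval. The
motif-side definition was chosen deliberately: with a genome-side floor
center, even-length motifs acquire a 1-bp asymmetry that breaks exact mirror
invariance of the pipeline, whereas the motif-side anchor makes
"reverse-complement the genome, mirror all reads and intervals, re-run"
produce bit-identical profiles for every motif length. That invariance is
asserted in the tests and is the single check that pins down all strand and
sign conventions.

Profile windows cover relative positions `r ∈ [−F − L//2, F + ⌈L/2⌉ − 1]`
(width `L + 2F`). For a + site, `value(r, s)` is the 5′ count at
`anchor + r` on strand `s`; for a − site the window is position-reversed and
strand-swapped (`value(r, fwd) = count(anchor − r, genomic reverse)`), so
"forward" always means the strand carrying the motif as matched. The default
flank is `F = 30` bp: the GBS-bound receptor protects ~30 bp and published
profiles extend tens of bp past the motif; it is configurable. Off-chromosome
positions contribute zeros. Overlapping site windows each receive full
counts — no read-ownership assignment — matching per-site footprint
semantics. Heatmap rows are ordered by descending total window count
(occupancy).

## Permutation control and coverage p-value

The null for coverage enrichment is the same analysis anchored at permuted
motifs: `n_perm` seeded uniform column permutations (the identity is
rejected and resampled — an unshuffled control is no control), each
rescanned with the identical threshold procedure at the same match p-value,
keeping match abundance comparable. Each permuted profile is normalized per
matched site; a permutation with zero matches contributes an all-zero
profile and a log warning, keeping the permutation count exact. The envelope
is the position-wise median and interquartile range of the normalized
permuted profiles.

The test statistic is the whole-window, both-strand normalized coverage
total — the simplest statistic consistent with "is there more 5′ signal at
these sites than at composition-matched random anchors". The p-value is the
add-one estimator `(1 + #{null ≥ obs}) / (1 + n_perm)`, never 0 and never
above 1; enrichment is observed / median(null) (infinite when the null
median is 0, which happens when most permutations match nothing — use a
larger match p-value or more regions in that regime). The default
`n_perm = 50` resolves p down to 1/51 ≈ 0.02 at desk-scale cost. Ranking a
library sorts by ascending p-value, then descending enrichment; matchless
motifs sort last and are flagged, not dropped. No multiple-testing
correction is applied by default — the workflow ranks rather than
thresholds. Because the statistic is per-site-normalized and the null is
recomputed from the same index, the ranking is invariant to global read
count scaling.

Subsampling (`subsample_profile`) draws sites uniformly without replacement
with a seeded generator; profile differences are taken between
per-site-normalized profiles (each divided by its own site count), which is
what makes a 505-site subsample comparable to a several-thousand-site full
set.

## Clustering

`select_top_occupied` keeps the n sites with the largest total window count
(ties by genomic coordinate), and `cluster_sites` runs standard
squared-Euclidean k-means (scikit-learn, best of `n_init = 10` seeded
restarts) on each site's concatenated (forward, reverse) window vector.
Vectors are scaled to unit total by default so that shape, not occupancy,
drives the clustering; defaults `k = 4`, all exposed, since no canonical
values exist for these choices. Centroids and inertia are recomputed from
the final assignment so each centroid is exactly its members' mean.
Empty-cluster handling is scikit-learn's relocation rule, deterministic
under the seed.

## Simulator

The generator emulates the study conditions end to end: an i.i.d. background
genome; one peak per equal-width slot at a random in-slot offset (hence
never overlapping); one motif instance planted at each peak center, on the
minus strand with probability `site_strand_prob` (default 0.5), as the PWM
consensus by default (or PWM-sampled, or an explicit sequence list, or a
consensus-pattern-satisfying sequence). Signal reads per site are
Poisson(`reads_per_site`, default 20); each read draws a cross-link
component `(offset, protected strand, weight)` — mirrored for minus-strand
sites — and a stop distance (uniform on 5–6 bp by default), and places its
5′ end *upstream of the cross-link on the protected strand's own 5′→3′
axis*: smaller coordinate on forward, larger on reverse. Reads extend 36 bp
3′-ward, truncated at chromosome ends. Background reads are uniform in
position and strand at `background_rate` (default 10⁻³ reads/bp).

The default cross-link mixture mimics a GBS-bound dimer: heavy "outer"
components (−8, +) and (+8, −) from each monomer's main cross-link, and
lighter "inner" components (+8, +) and (−8, −) from the same cross-link
points protecting the opposite strand when only one monomer is cross-linked
(weights 0.35/0.35/0.15/0.15). With a 5–6 bp stop this reproduces the
characteristic four-peak profile: outer maxima near ∓14, inner peaks near
±2–3. Default peaks are 400 bp — a realistic ChIP-seq peak width, and wide
enough that permuted-motif windows rarely overlap the central pile-up; with
peaks much narrower than about twice the profile window the permutation
control is conservative because random anchors still capture planted signal.

A complete truth table (per-site anchors/strands/sequences and per-read
component, stop distance and 5′ position; region class labels in two-motif
mode) accompanies every dataset. What the simulator does **not** model:
sequencing errors, mappability, GC or fragment-length bias, PCR duplicates,
inter-site occupancy variation beyond Poisson counting, or peaks without
sites. Tests passing on simulator output therefore validate coordinate
arithmetic, strand logic, calibration, and statistical behavior under the
stated model — not robustness to those real-data artifacts.

## Numerical and scale choices

Tests and the acceptance script run on one CPU in minutes by construction:
the planted-footprint dataset uses 2,000 sites at 20 reads/site, the null
calibration 200 simulations of 60 peaks with 50 permutations each, ranking
20 runs of 100 peaks against 5 permuted decoys, clustering two 250-site
populations, and subsampling 1,000 draws of 505 sites. The binomial and KS
checks use 3-sigma / alpha = 0.01 bands with fixed seeds. The subsampling
unbiasedness check compares the maximum absolute deviation of the mean
profile against 3× the largest per-position Monte-Carlo standard error — a
scalar comparison, because a per-position 3-sigma rule over ~150 positions
would reject a correct implementation about a third of the time.

## Known limitations

Coverage p-values need enough permuted matches to be stable; with very
strict match p-values most permutations match nothing and the enrichment
ratio degenerates (flagged via the null median). The exact-DP threshold
assumes an i.i.d. background — no dinucleotide or Markov models. Scanning is
restricted to supplied regions; whole-genome scans, peak calling, de novo
motif discovery and motif-redundancy grouping are out of scope.
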