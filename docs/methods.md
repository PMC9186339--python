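# Methods

## Phasing model

Phasing operates on biallelic SNV het sites only, addressed by a 0-based
per-chromosome ordinal over het sites sorted by position. A *fragment* is one
read (or read pair, or Hi-C pair) reduced to its allele observations
`(site_index, allele, base_quality)`; a fragment with fewer than two
observations carries no linkage and is dropped.

### Linkage graph

Within a window of `window_size` variants (default 200, the window scale at
which spectral phasing is routinely run), each variant `v` owns two nodes
encoding the two possible assignments of its alleles to haplotype A. For every
pair of observations inside the window a fragment adds weight to the edge
consistent with its observation and, symmetrically, to the mirrored edge. With
quality weighting on (default), the weight is the probability both base calls
are correct, `(1 − 10^(−q_u/10))(1 − 10^(−q_v/10))`; Phred 20 observations
therefore contribute 0.9801 rather than 1.

### Fiedler bipartition in the phase-consistent sector

The mirror construction makes the adjacency matrix exactly invariant under
swapping every variant's node pair, so Laplacian eigenvectors split into a
symmetric sector (`f[(v,0)] = f[(v,1)]`, containing the all-ones vector) and
an antisymmetric sector (`f[(v,0)] = −f[(v,1)]`). Only antisymmetric vectors
can assign opposite signs to a variant's node pair — the condition for a valid
phase call — so the Fiedler vector is taken as the lowest eigenvector of the
antisymmetric sector. It is computed economically as the smallest eigenvector
of the k×k signed Laplacian `H = Dtot − (W_cis − W_trans)` per connected
component (components over variants; a dense symmetric eigensolver keeps the
computation deterministic for fixed input). Taking the global Fiedler vector
instead is unreliable under noise: it often falls in the symmetric sector,
where the sign test rejects every variant.

The sign rounding of the eigenvector is then polished by a greedy single-flip
ascent on the signed agreement `xᵀ(W_cis − W_trans)x` — the graph's own
objective, used only as a local cleanup of the spectral relaxation's rounding.
A variant is phased when its eigenvector magnitude reaches `fiedler_tol`
(default 1e-6); entries at or below tolerance mean "no net linkage" and the
variant is left unphased rather than guessed, emitting a block cut.

### Window stitching

Consecutive windows advance by `window_size − window_overlap` (default
overlap 20). The new window's orientation relative to the accumulated phasing
is the majority vote (agreements − disagreements) over the overlap's co-phased
variants; a zero margin or empty overlap cuts the block at the boundary
rather than guessing. Within a window, connected-component boundaries also cut
blocks. Phase sets are identified by the position of each block's first
variant.

### Orientation conventions

Output is invariant under a global haplotype flip (swap of A and B); all
accuracy comparisons are flip-aware. Switch error counts orientation changes
between consecutive co-phased variants after choosing, per block, the global
orientation minimizing mismatches; hamming rate is that minimized mismatch
fraction. Both pool numerators and denominators over blocks.

## Fragment filters

* Hi-C: fragments whose span between outermost observed variants strictly
  exceeds `hic_max_insert` (default 40 Mbp) are removed. The span is a proxy
  for the mapped pair separation, the quantity the filter targets: contacts
  with very large apparent separation are enriched for trans-homolog ligation,
  whose second anchor reports the opposite haplotype and injects systematically
  wrong linkage.
* Long reads: observations below `longread_min_baseq` (default Q20) are
  masked before phasing; the fragment survives if at least two observations
  remain. The mask applies to long reads only — short-read and Hi-C qualities
  are retained and act through the edge weights.

## Block merging

Blocks from two phased inputs of different priority form a connection graph.
An edge requires strictly more than `min_shared` co-phased SNVs (default 2;
the threshold is user-defined in practice and exposed as `-N`) and an
unambiguous orientation: over shared variants, `agree > disagree` (same) or
`disagree > agree` (flip); exact ties are conflicts, logged and excluded.
Merging unites each connected component containing at least one primary:
orientations propagate by BFS from a primary; an inconsistently oriented cycle
drops its lowest-shared edge and retries. Within a component, primary alleles
win wherever any primary phases a variant — globally, so a conflict-excluded
primary in another component keeps its variants — and the secondary
contributes only variants no primary phases. Secondary-only components are not
emitted: merging extends and joins the primary callset, it does not import
panel blocks wholesale. Variants phased in neither input stay unphased; no
imputation is attempted.

## Read QC

Four rules on paired FASTQ, order-independent on the keep/drop outcome:

1. N fraction strictly above 2% in either mate.
2. At least 40% of bases at Phred ≤ 7 in either mate (the inclusive reading
   of "40% of bases" at the boundary).
3. Adapter detected: some ungapped placement (all offsets, including 3'
   partial overlaps) overlapping strictly more than 10 bp with at most 3
   mismatches.
4. Abnormal insert: the mates themselves overlap credibly — at least 10 bp at
   a mismatch fraction within 10% after reverse-complementing mate 2 — or the
   insert such an overlap implies (`len1 + len2 − overlap`) is below 30 bp.
   Overlaps shorter than 10 bp are treated as too little evidence to imply an
   insert, so very short inserts on very short reads are undetectable by
   design; this is the one place the rule wording ("when the length of the
   reads pair was minor") is ambiguous, and the insert-size clause is applied
   only through a detected overlap.

Duplicates are pairs with byte-identical `(seq1, seq2)`; identity ignores
names and qualities. All but the first occurrence are dropped.

Note the adapter rule's ungapped ≤3-mismatch scan has a small chance-hit rate
on random sequence (≈2% per 100 bp pair with a 13 bp adapter); screening is
therefore active only when an adapter is declared.

## Population statistics

LD r² is computed from phased haplotype counts directly (the cohort is
phased); no EM over unphased genotypes. Monomorphic sites are excluded with a
warning. The decay curve averages r² over all polymorphic pairs within
`max_dist` (default 500 kb, for tractability) in distance bins; the decay
distance interpolates linearly between the midpoints of the bins straddling
the threshold (default r² = 0.5), with no monotone smoothing; a curve that
never crosses reports infinity ("beyond max_dist").

## Synthetic data

The simulator emulates the study's data types at desk scale; all generators
are deterministic under `SimConfig.seed` with independent per-stage streams.

* **Truth**: uniform-random distinct het positions on a random reference,
  random REF/ALT and phase. Defaults (1 Mb, 2,000 het SNVs) give the ~1/500 bp
  het density at which a 200-variant window spans ~100 kb.
* **Short reads**: normal insert (default 350 ± 50 bp, 150 bp reads, 30×),
  both mates observing the same homolog.
* **Long reads**: exponential lengths (default mean 20 kb, matching a
  long-insert SMRT-style library, 20×); each observation flips with
  `allele_error` (default 5%, the regime where per-base error dominates
  long-read phasing), base qualities jittered around the corresponding Phred.
* **Hi-C**: two short anchors; cis separation from a Pareto-tailed
  distribution (so some cis pairs exceed any fixed filter), and with
  probability `trans_noise_rate` a trans contact whose second anchor reports
  the opposite homolog and whose apparent separation is drawn uniformly from a
  configurable oversize range — tying the error mode to the oversize spans the
  insert filter removes, which is the physical rationale for that filter.
* **Panel**: the truth walked left to right, toggling orientation with
  `panel_switch_rate` per step (default 2%, a realistic panel switch-error
  scale), in one chromosome-wide phase set.
* **Cohort**: each haplotype is a mosaic of founder haplotypes with
  exponential segment lengths; shorter segments mean more historical
  recombination and faster LD decay. The default of two founders makes r² → 1
  at zero distance (with more founders attainable r² is capped near
  1/n_founders, below the 0.5 decay threshold); roughly half the sites are
  monomorphic and excluded. This is a stand-in with tunable LD structure, not
  a demographic model: it produces no realistic site-frequency spectrum,
  mutation–recombination interplay or population structure, so cohort tests
  demonstrate the statistics' machinery, not population-genetic realism.

What passing tests show: the phasing, merging and measurement machinery is
correct on data whose generative process matches the model's assumptions
(independent errors, known error mode for Hi-C, uniform het placement). Real
data adds alignment artifacts, reference bias, duplicated sequence and
structural variation, none of which the simulator emulates.

## Numerical and design choices

* Dense symmetric eigensolver per component (≤400 nodes at default window
  size): deterministic, no iterative-solver seed sensitivity; a failure falls
  back to leaving the component unphased.
* Degenerate eigenvalue ties produce whatever basis the solver returns;
  variants whose entries then fail the sign or tolerance test are unphased —
  conservative by construction.
* Stitching and orientation ties always cut or exclude, never guess.
* N50 uses the cumulative-half convention over the metric's own total (not
  genome length); AN50 applies it to adjusted spans, where the adjusted span
  scales the block span by the fraction phased of het sites inside the
  block's genomic range. AN50 can exceed N50 on skewed block sets; no
  ordering between them is asserted anywhere.
* MVP ties break by larger span, then smaller start position.
* The pipeline is single-threaded; `--threads` is accepted for interface
  stability but unused at desk scale.

## Test and acceptance problem sizes

Unit and property tests run on 20–200 kb chromosomes with 100–2,000 het
sites. The acceptance checks use: a 1 Mb / 2,000-het / 20× error-free
long-read bundle (truth recovery); 200 random 8-variant windows at 10×
coverage for the exhaustive-MEC comparison (100% agreement noise-free, ≥95%
at 5% allele error); 20 seeded Hi-C replicates with `trans_noise_rate = 0.3`
concentrated in oversize pairs (sign test on switch-error improvement); 50
merge replicates against a 2%-switch panel; 1,000 random multisets for the
continuity-metric oracles; a 60-case QC boundary table; and 10 cohort
replicates per mosaic segment length for LD-decay ordering. The merge
replicates use primary blocks of 29 variants so orientation votes have odd
shared counts and cannot tie — a tie is a legitimate conflict exclusion, not
a merge failure, and is exercised separately in the unit tests.

## Known limitations

* Diploid SNV phasing only: no polyploids, indels or structural variants;
  consensus building is SNV-substitution only (no coordinate shifting).
* Fragment extraction from alignments is out of scope; the fragment-file
  dialect is the ingestion boundary.
* The merge algorithm takes the two prose cases (bridge and extend) as the
  complete rule set.
* LD decay beyond `max_dist` is not measured, only reported as a bound.
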