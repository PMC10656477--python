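# Methods

This note documents the models and procedures implemented in `elekit`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical and design decisions
made where the problem left the design open.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`; conversion to
1-based inclusive happens only at the GFF3 boundary (on read and write).
Overlap is strict half-open overlap (`A.start < B.end and B.start < A.end`),
so bookended intervals never overlap. Output files are always written in a
canonical order (chrom lexical, start, end, strand) so repeated runs diff
cleanly. CTSS tables are strand-specific: + and − records at the same
position are distinct features.

## Tag clustering

Per-sample counts are normalized to reads per million (RPM). Clustering runs
per tissue on the pooled replicate signal (mean replicate RPM per position):
positions at or above the RPM floor (default 0.5 RPM) are chained into a
cluster while consecutive retained positions are at most `max_dist` (default
20 bp) apart; sub-threshold positions neither seed nor join clusters. The
distance and RPM defaults are the conventional defaults of distance-based
CAGE cluster callers; both are configurable.

Replicate support is counted at CTSS-overlap level: a replicate supports a
cluster when it contributes at least one position inside the cluster
interval at or above the RPM floor, and a tissue cluster is kept when at
least `min_supporting_samples` (default 2) replicates do. This reading of
"supported by at least two samples" is robust to depth differences between
replicates; requiring independently called per-replicate clusters is
stricter and would discard reproducible but shallow signal.

Tissue cluster sets merge into a unified set by ≥ 1 bp same-strand overlap
(union interval); under the half-open convention, bookended adjacency is
ambiguous, so strict overlap is used. The dominant position is the argmax
of all-sample pooled RPM; clusters wider than 10 bp (strictly) are *broad*.

Clusters that fail the support filter, plus sub-threshold pooled signal not
overlapping any retained cluster, form the **weak pool** passed to
chromatin-state rescue. Both failure routes feed the pool because a "weak
CAGE signal" can be weak either in amplitude or in reproducibility.

## Chromatin-state HMM

Tracks are quantified in 500-bp bins and binarized by a Poisson upper-tail
test against the track-wide mean (mark a bin iff P(X ≥ count) < 10⁻⁴) — the
convention of binarization-based chromatin segmentation. The model is an
HMM with independent Bernoulli emissions per track (product form), fitted
by scaled-forward–backward Baum–Welch over per-chromosome chains. The
log-likelihood is asserted non-decreasing at every iteration (10⁻⁸
tolerance); transition rows and the initial distribution are renormalized
each M-step; emissions are clipped to [10⁻⁶, 1−10⁻⁶] to avoid degenerate
zero-probability observations.

Initialization seeds one state per well-supported distinct binary emission
pattern (support ≥ max(10, 0.2 % of bins), most frequent first, with a
small random perturbation); surplus states start as exact uniform clones,
whose EM updates remain identical by symmetry so they cannot split a
pattern's posterior mass. Restarts (default 5 library-side, 3 in the
pipeline) draw sub-seeds from the master seed; the best final likelihood
wins, ties by restart index. After the best restart is chosen, states whose
emission vectors agree within 0.05 (max-abs) are consolidated
occupancy-weighted into one state: with more states than distinct signal
combinations, EM is free to clone a pattern state into interchangeable
copies, and consolidation restores one state per combination without
materially changing the modeled distribution. The fitted model may
therefore have fewer states than requested.

Decoding is posterior (forward–backward) argmax per bin, ties toward the
lower state index; Viterbi is available behind a flag. Posterior decoding
gives smoother per-bin calls for the rescue step than Viterbi's single best
path. State indices are arbitrary labels: the TSS-active state is always
identified functionally as the argmax of
P(CAGE=1)·P(H3K4me3=1)·P(H3K9ac=1), never by number.

## TSS annotation

Fixed precedence: (1) a cluster overlapping a gene's 5′UTR or the
strand-aware 500-bp window upstream of its TSS is a gene TSS (ambiguity →
nearest TSS to the cluster's dominant position, then lexical gene id);
(2) remaining clusters strictly more than 3 kb from every gene-model
interval are intergenic, and intergenic clusters overlapping ≥ 1 bp of an
H3K4me3 or H3K9ac peak are ELE TSSs; (3) weak-pool clusters whose dominant
position falls in a bin decoded as the TSS-active state and which overlap a
gene body or promoter window are rescued as low-confidence gene TSSs;
(4) everything else is `intergenic_other` or, within the ≤ 3 kb gap zone,
`proximal_unclassified` — an explicit label rather than silent loss. The
five categories are mutually exclusive and exhaustive; the category counts
sum to the number of input clusters on every run, and assignment is
invariant to input order.

## Enhancer–gene linking

RP(gene) = Σ 2^(−dᵢ/d₀) over ELEs with dᵢ ≤ 20·d₀, d₀ = 100 kb, distances
measured dominant-position-to-TSS (point to point, since both are single
positions). Candidate pairs live within a 2 Mb window. The "top 50 % RP"
filter is interpreted as the median RP over genes having at least one
contributing ELE (not over all genome genes, and not over pairs); the
quantile is configurable. The expression correlation is the per-pair
Pearson r of per-sample CAGE RPM across all tissue × replicate samples
(gene expression = CAGE RPM of the gene's own TSS cluster, not RNA-seq);
a zero-variance vector has no defined r and fails the filter. A pair is
predicted iff r > 0.5 (strict) and the gene's RP reaches the threshold.

Tissue specificity of any feature uses the τ index over per-tissue mean
RPM, τ = Σ(1 − xᵢ/x_max)/(n−1), with τ ≥ 0.8 ⇒ specific to the argmax
tissue, lower ⇒ ubiquitous, all-zero ⇒ silent. τ is the field's standard
specificity statistic; 0.8 is a conventional stringency.

## TE analysis and LTR dating

An ELE is TE-embedded iff its dominant position lies inside an annotated TE
(point containment; interval-overlap mode exists behind a flag); nested TEs
resolve to the innermost (shortest) element. Family/subfamily enrichment
contrasts ELE-bearing vs non-bearing copies of a group against all other
TEs (whole-genome background); tissue-bias enrichment contrasts group
membership against tissue-specific labels with all ELEs as background. The
two-tailed Fisher p sums hypergeometric probabilities of all same-margin
tables with point probability ≤ observed; ties are compared in exact
integer arithmetic (the weights share a common denominator), so the
conventional two-tailed rule is honored without floating-point ambiguity.
Raw p and Benjamini–Hochberg q are both reported.

LTR pairs are globally aligned with affine gaps (match +1, mismatch −2, gap
open −5, gap extend −1; a length-L gap costs 5 + (L−1), i.e. the open score
covers the first gapped position). Alignment columns containing gaps or N
are excluded from the site count. The K2P distance is
d = −½ln(1−2P−Q) − ¼ln(1−2Q); arguments leaving the log domain yield a
*saturated* sentinel rather than a number. Insertion age follows
time = distance/(μ·2·100) with distance in percent — the ÷100 converts the
percent convention of distance-matrix output back to substitutions per
site, so equivalently time = d/(2μ) — at μ = 1.3×10⁻⁸ per site per
generation.

PWM scanning is a both-strand log-odds scan; the hit threshold is the
smallest score whose upper-tail probability under the background is ≤ 10⁻⁴,
computed by exact enumeration of the score distribution (position-wise
convolution with score collapsing at 10⁻⁹ resolution). A motif too short to
ever reach that tail bound but carrying hard constraints (zero-probability
bases, hence impossible windows) falls back to demanding the maximum
attainable score — exact consensus matching; a motif with no impossible
windows (e.g. uniform) simply never hits. Abundance is normalized per TSS
of each group; groups are compared with a two-tailed Welch t-test on
per-sequence counts, with an ε variance guard for the all-equal-counts
degenerate case.

## Subgenome homology

Collinear anchors are homoeolog pairs lying on a strictly-increasing chain
in both subgenomes (longest increasing subsequence per chromosome pair,
O(n²) DP with a deterministic earliest-chain tie-break), requiring chains of
≥ 3 pairs; this replaces external collinearity tools with a desk-scale,
deterministic equivalent. Regions between consecutive anchors are syntenic
blocks. The homology query is the ELE TSS plus 200 bp downstream on the
ELE-RNA strand, aligned by affine-gap Smith–Waterman against the
counterpart block only. Significance uses Karlin–Altschul
E = K·m·n·e^(−λS) with λ solved numerically (Brent) for the ungapped
match/mismatch scheme under a uniform base background, and K fixed at 0.28
(the magnitude tabulated for such schemes); applying ungapped statistics to
gapped scores is a deliberate approximation — at the E ≤ 0.01 cutoff with
201-bp queries the decision is far from the boundary for both true copies
(E ≈ e^(−250)) and random sequence (false-hit rate < 5 %, verified by null
simulation). A hit overlapping an H3K4me3 or H3K9ac peak in the counterpart
subgenome (union of tissues by default) is an active homologous ELE; calls
against both other subgenomes combine into `<home>_specific`, `shared_two`
or `common`.

## The synthetic study conditions

The generator plants, per run: 3 subgenomes (A/B/D) of 2 Mb; 40 genes per
subgenome in homoeologous order (collinear fraction 0.9), gene length
1.2 kb with a 200-bp 5′UTR, 60 % sharp TSSs; TE subfamilies with
`RLG_famc7.3` expanded 40/2/2 across A/B/D and three control subfamilies at
equal counts; 60 ELEs of 300 bp — half inside A's expanded subfamily copies
(spike-specific), ~15 % in other TE copies, four three-copy loci with
identical sequence and active marks in all subgenomes (the *common* class),
and the rest subgenome-private intergenic singles; full-length LTR elements
whose 3′ LTR is the 5′ LTR diverged by a uniform draw from 1–10 %
substitutions/site under a K2P-symmetric process with transition events
twice transversion events (α = 4β), so the dating model is correctly
specified and the estimator is consistent by construction; CAGE counts per
sample as Poisson draws around tissue-level means (genes 30, targets 60 in
active tissues, ELEs 40, weak genes 0.25 per replicate; background noise
2×10⁻⁵ reads/bp), with sharp TSSs concentrating ≥ 90 % of signal within a
few bp, broad TSSs uniform over 20–40 bp, and ELEs emitting bidirectionally
from their 5′ edge; promoter/ELE bins carrying CAGE+H3K4me3+H3K9ac+open+
run-on signal and gene bodies carrying 3′-biased elongation signal
(K36/RNA/run-on starting past the promoter window — which is also why
strong and weak promoters share one chromatin signature and a single
TSS-active state serves both annotation and rescue); TE bodies heavily
CG/CHG methylated (0.9) except hypo-methylated (0.05) windows around
planted ELEs.

Target links are planted at the nearest genes *in the upper half of the
planted RP distribution* (RP computed from planted ELE positions at
generation time). This is deliberate: the linking rule's top-50 % RP filter
cannot, by definition, recover a target whose gene is below the median, so
links planted there would be unrecoverable by construction rather than by
method error. When no fresh gene is available, an ELE reuses an
already-targeted gene and adopts that gene's active tissues so both links
remain expression-consistent.

Everything is a pure function of (config, seed); the same seed reproduces
byte-identical outputs. What the generator does **not** emulate: realistic
sequence composition (uniform background plus planted motifs only), read-
level artifacts, Hi-C contacts, TE sequence homology between copies (TE
identity lives in the annotation table; copies have independent random
sequence so that subgenome-specificity is controlled by the planted
architecture), or any quantitative match to a real genome's cluster counts.
Passing tests therefore demonstrate correctness of the *rules and
estimators* under a recoverable planted model, not performance on real
wheat-scale data.

## Problem sizes and determinism

The default pipeline (6 Mb genome, 8 CAGE samples, 12,000 HMM bins ×
7 tracks, ~1,100 clusters, 80 dated LTR elements, ~120 homology queries)
runs end-to-end in about 1–2 minutes on one core; the test suite adds
small-instance oracles (path enumeration for HMM likelihood and alignment
scores, exact-arithmetic Fisher enumeration, transitive-closure clustering,
brute-force interval scans and PWM rescoring) at sizes where exhaustive
computation is feasible. All randomness flows from explicit integer seeds:
the simulator derives stage seeds (seed, seed+1, seed+2), the HMM derives
restart sub-seeds from its seed, and reruns at a fixed seed are
bit-identical.

## Known limitations

- Karlin–Altschul K is a fixed approximation (λ is exact); E-values near
  the 0.01 boundary inherit that imprecision.
- The HMM's state consolidation assumes interchangeable duplicates are
  numerical artifacts; biologically distinct states with emissions within
  0.05 everywhere would be merged (not observed at the default tolerance).
- Gene expression for link correlation is CAGE signal at the gene TSS
  cluster; genes without a called cluster cannot be linked.
- The two-tailed Fisher implementation enumerates the hypergeometric
  support; tables with margins in the millions would be slow (irrelevant at
  this scale).
- Bidirectional ELE transcription yields one called cluster per strand;
  downstream stages treat them as separate ELE-TSSs, and evaluation against
  truth deduplicates by planted element.
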