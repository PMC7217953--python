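# Methods

## Scope and data model

`splicesig` analyses two-group comparisons of alternative splicing from
junction-spanning read counts.  Gene models (gene/transcript/exon GTF) are
held with 0-based half-open coordinates internally; GTF is read and written
1-based inclusive.  Junctions are genomic objects with donor < acceptor on
the genome axis: exon–exon junctions are keyed by the excised intron
`[donor, acceptor)`, and exon–intron boundary junctions by the two-base
window straddling the boundary.  Keying events by these coordinates makes
event identifiers stable across datasets, which is what allows signatures
from different experiments to be intersected.

## Event enumeration and classification

Five event types are enumerated from transcript structure:

- **intron retention** — every distinct annotated intron; inclusion evidence
  is the pair of exon–intron boundary junctions, exclusion the spliced
  exon–exon junction.
- **cassette exon** — an internal exon of one transcript spanned entirely by
  an exon–exon junction of another; inclusion = the exon's two flanking
  junctions, exclusion = the spanning junction.  Mutually exclusive exons
  appear as two linked cassette events sharing a cluster.
- **alt-5ss / alt-3ss** — two junctions sharing one genomic endpoint.  The
  label depends on strand: a shared right endpoint with variable left
  endpoints is alt-5ss on `+` (variable donors) and alt-3ss on `-`.
  Junction pairs already explained by a cassette event or an alternative
  promoter are excluded.
- **alt-promoter** — two transcripts with *disjoint* first exons (in
  transcription orientation) and identical downstream splice structure.
  Requiring disjoint first exons is deliberately conservative: overlapping
  first exons that differ at one boundary are alternative splice sites, not
  promoters.

Events competing over any shared junction are grouped into junction
clusters (connected components per gene, numbered left to right), and
significant results are reported once per cluster.  A note on symmetry:
reflecting all coordinates *and* flipping strand is the reverse-complement
view of the same molecule, so event types are invariant under it; reflecting
coordinates alone swaps alt-5ss and alt-3ss.  Both properties are tested.

## PSI quantification

PSI = I/(I+E) with I the summed inclusion reads (for intron retention, the
mean of the two boundary counts, avoiding double-counting a single retained
intron against its spliced junction) and E the summed exclusion reads.
Junctions absent from a count table are zero observations; missingness is
decided only at the event level, when supporting depth I+E falls below
`min_reads` (default 10 — the notion of a "detected" PSI value needs a depth
cutoff, and 10 supporting reads is a conservative, configurable choice).
The detection filter keeps events detected in strictly more than half of the
samples (configurable fraction, strict inequality).

## Differential splicing and expression

The moderated t-statistic shrinks each event's pooled two-sample variance
toward a prior shared across events:

    s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g),  t_g = ΔPSI_g/(s̃_g·√(1/n_A+1/n_B))

with p-values on d₀ + d_g degrees of freedom.  Hyperparameters (d₀, s₀²)
are estimated by the method of moments on log variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), trigamma(d₀/2) is matched to
Var(e) − mean(trigamma(d_g/2)) via a Newton trigamma inverse, and s₀² to the
corrected mean.  This is the standard eBayes construction; on shared
fixtures the estimates and t-statistics agree with Bioconductor limma to
machine precision (a cross-implementation test runs limma through Rscript).
Two boundary behaviours are defined explicitly: d₀ = 0 reduces to the
classical pooled t (tested to 1e-10), and when the spread of log variances
is at or below its theoretical chi-square minimum, d₀ = ∞ and s₀² is the
geometric mean of the observed variances — in that degenerate regime the
sample variances are direct observations of the prior, so no chi-square
bias correction applies.  When fewer than two events have positive variance
the model falls back to the unmoderated pooled t rather than failing.

Significance uses the literal thresholds: p ≤ α (inclusive, default 0.01)
AND |ΔPSI| > 0.1 (strict).  No multiple-testing correction is applied by
default, matching the raw-p thresholding convention of junction-level
splicing screens; a Benjamini–Hochberg mode is available (`fdr=True`).
Significant events are collapsed to one record per junction cluster keeping
the largest |ΔPSI| (ties: smaller p, then lexicographic event id — a
determinism rule, since no canonical choice exists).  Events with fewer than
two non-missing values in either group are flagged untestable and excluded,
not raised as errors.

Differential expression applies the same moderated t to log2(RPKM + 1)
(pseudocount configurable), with RPKM = counts·10⁹/(library·length), and
calls a gene at p ≤ 0.01 with a fold change ≥ 1.5 in either direction
(inclusive — a gene exactly at 1.5-fold passes).

## Signature concordance

A signature is the map event id → sign(ΔPSI) of a comparison's significant,
cluster-unique events.  Concordance over the events shared by two signatures
counts same-sign pairs; the percentage is undefined (reported NA, sorted
last, never 0 or 50) when nothing is shared.  Direction signs only are used
by default — the relevant biology is which way an event moves, not how far —
with an optional magnitude-weighted mode.  The null model is independent
fair signs per shared event, giving 50% expected concordance; the null
simulator's tails match the Binomial(n, ½) closed form and its calibration
is part of the acceptance suite.  Gene-symbol signature intersections
(upper-cased, deduplicated, up to six sets) report counts per Venn region.

## Motif enrichment

PFMs use the CisBP-RNA text layout (`Pos A C G U`, T accepted as U), with a
0.001 pseudocount and per-row renormalisation.  Scanning is single-stranded
RNA-sense log-odds against a uniform 0.25 background; a window is a hit at
≥ 80% of the motif's maximal score (configurable), and N bases contribute
the background log-odds (zero).  Target intervals per event are the
alternative exon body plus up- and downstream intronic flanks of up to
500 nt, truncated at neighbouring exons, strand-aware; intron-retention
events contribute the retained intron.  The enrichment statistic is a
per-interval presence/absence binomial z — with p̂ the background hit
fraction (clamped to [1/(2n_bg), 1−1/(2n_bg)]),
z = (k_t − n_t·p̂)/√(n_t·p̂(1−p̂)).  Presence/absence per interval rather than
per-hit counts keeps the statistic robust to the large length differences
between exon bodies and flank bins.  Sensible background sets are the
intervals of detection-filtered but non-significant events from the same
dataset.  Calibration: when targets and background come from the same
generative model, z is standard normal to within the acceptance bands
(mean ±0.1, sd ±0.15 over 1000 draws) provided the background set is an
order of magnitude larger than the target set — with n_t/n_bg not small, the
estimation of p̂ inflates Var(z) by ≈ 1 + n_t/n_bg.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
real genome content.  Per planted event type it builds a minimal gene:
inclusion + skipping transcripts (cassette), a single two-exon transcript
(intron retention), two transcripts sharing one splice site (alt-5ss/3ss),
or two transcripts with disjoint first exons (alt-promoter); strands are
drawn at random, exon lengths 80–200 nt, intron lengths 300–1200 nt.  For
each event and sample: total depth ~ NegativeBinomial(mean, dispersion)
(variance m + φm²), sample PSI ~ Beta with the group mean and intra-class
correlation ρ (ρ = 0 is a point mass), inclusion reads ~ Binomial(depth,
PSI).  Intron-retention boundary counts are an even binomial split of twice
the inclusion draw, so their mean equals the inclusion count.  Defaults —
10 samples/group, mean depth 200, dispersion 0.3, ρ = 0.05 — represent a
well-powered shRNA knockdown contrast with mild biological overdispersion,
chosen once and documented here.

When two enumerated events compete for a junction (a cassette's inclusion
junction is also the spliced form of its intron's retention event), events
are simulated independently and the planted event claims the junction; the
competing background event is left unsimulated but remains in the truth
table as non-differential.  This keeps planted effect sizes exact and
prevents group-dependent read sharing from leaking differential signal into
background events.  Unsimulated events still acquire PSI values downstream
(typically a constant 0 from the claimed junction's reads), which is the
correct null behaviour.

What the generator does **not** emulate: realistic sequence composition,
correlated events within a gene, isoform-level coupling between events,
library-size effects shared across events in a sample, and alignment
artefacts.  Passing tests therefore demonstrate the correctness and
calibration of the statistics under the stated generative assumptions, not
performance on any particular real dataset.

## Numerical choices and problem sizes

Tolerances: the classical-t limit is asserted to 1e-10; the trigamma inverse
iterates Newton steps to 1e-8 relative change; PFM rows must sum to 1 within
1e-6 after normalisation; scan thresholds include a 1e-12 slack against
floating-point ties.  The acceptance suite and `scripts/acceptance.py` use
10,000 shared events × 1,000 replicates for the concordance null, 10,000
events at n = 5/group for type-I error, 5,000 events for prior-df recovery,
a 200-gene dataset (50 planted events, 4:1 intron-retention:cassette, n =
10/group, depth 200) for pipeline recovery, and 1,000 null draws (40 target
/ 400 background sequences of 60 nt) for motif calibration — sizes chosen
to make Monte-Carlo error small relative to the asserted bands while the
whole suite runs in well under a minute per component.

## Known limitations

- Events with more than two competing paths (multi-path PSI) are out of
  scope; PSI is always a two-way inclusion/exclusion ratio.
- Only two-group designs; no paired or multi-factor tests.
- The moderated t operates on PSI values directly, not on counts; at very
  low depth the within-sample binomial noise is not modelled separately
  from biological variance.
- Alt-promoter detection requires exactly matching downstream structure, so
  promoters combined with internal splicing differences are not labelled.
- Motif scanning is sequence-only; RNA secondary structure is ignored.
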