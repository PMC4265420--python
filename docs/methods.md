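# Methods

`crmine` predicts cis-regulatory modules (CRMs) and their constituent
elements (CREs) by integrating many transcription-factor (TF) ChIP peak
datasets. The premise: cooperative TFs bind clustered sites, so peaks of
different TFs pile up over shared CRMs, and the motif combinations that
recur across datasets mark real regulatory grammar while dataset-specific
motifs are mostly noise. This note documents the model, the tunable
parameters, the numerical choices, and what the synthetic benchmark does
and does not establish.

## Pipeline model

1. **Peak preparation.** Peaks overlapping high-occupancy-target (HOT)
   regions are removed (promiscuous, likely artifactual). Peaks longer than
   `max_peak_len` (default 5,000 bp, strict) are discarded. Shorter peaks
   are padded equally on both ends up to `extend_target` (default 3,000 bp,
   the typical CRM length scale); a side's padding stops at the distal edge
   of the first exon it reaches and at chromosome ends, without
   compensation on the other side.

2. **Motif discovery.** A discriminative finder in the DREME mould runs per
   dataset against a matched negative set generated from an order-3 Markov
   model of the positive sequences (+1 smoothing; deterministic under a
   seed). Exact words of widths 8–12 are enumerated on both strands and
   scored by a one-sided Fisher exact test on peak-level presence
   (positives vs negatives); the best seeds are generalized one IUPAC
   position at a time; the best candidate is accepted when its E-value
   (p times the number of candidates scored) clears `evalue_threshold`
   (default 0.05). Sites of the accepted pattern are collected, the PSWM is
   built from them (pseudocount 0.25/base), sites are masked, and the
   search repeats. Two guards matter on kilobase-scale sequences: the
   minimum width is 8 because the peak-level presence of shorter words
   saturates (nearly every 3 kb sequence contains any given 6-mer, so the
   presence test carries no signal), and candidates present in more than a
   third of the negative set are rejected as too promiscuous to be TF
   sites. Datasets yielding fewer than two motifs are dropped entirely
   (quality control; a single motif cannot form a pair).

3. **Supporting-peak evidence.** Exact pattern matching misses sites that
   carry substitutions, which deflates every peak-level co-occurrence
   statistic downstream. Each accepted motif is therefore re-scanned over
   its dataset with a smoothed log-odds matrix (pseudocount 4% of the site
   count per base, threshold half the maximum score — tolerances chosen so
   a sharp width-8 motif admits one substitution and rejects two). A peak
   supports a motif when a scan hit overlaps its *original* (unpadded)
   interval: binding evidence lives in the called peak, the padding is
   context. The exact-pattern sites remain the motif's projectable site
   list.

4. **Co-occurring pairs (CPs).** Within each dataset, every motif pair is
   scored Sc = o / min(|Mi|, |Mj|) over supporting-peak counts, where o
   counts peaks supporting both. Pairs with Sc ≥ α (default 0.7) become
   CPs. An automatic mode fits a Gaussian to the low-score background
   component and returns μ + 6σ (capped to [0.5, 0.9]); the fixed default
   is canonical.

5. **CP similarity graph and CPCs.** CPs from different datasets are
   compared by Ss ∈ [0, 2]: the best cross-dataset motif pairing's
   similarity plus the remaining pair's (anchoring on the single highest
   similarity first, per the pipeline's definition — this is not always the
   pairing with the larger sum). Edges where Ss ≥ β (default 1.36) form a
   multi-partite graph; Markov Chain Clustering (MCL, inflation 2.0) cuts
   it, and clusters with fewer than τ = 2 CPs are discarded. A knee-finding
   automatic mode for β is provided.

6. **CPC co-occurrence and CRM components.** Pairs of CP clusters are
   scored S_CPC: for each dataset contributing CPs to both, the mean over
   cross pairs of o / min(|Ps|, |Pt|) (peaks supporting both CPs),
   averaged over shared datasets. Edges at S_CPC ≥ γ (default 0.69; an
   automatic KDE-valley mode exists) and another MCL cut give CRM
   components (CRMCs) — recurring motif combinations. Singleton clusters
   are kept here (a lone CPC is still a combination), unlike the CP stage.

7. **Unique motifs (Umotifs).** Motifs inside CRMCs are merged iteratively:
   a similarity graph at edge > 0.7 is MCL-clustered; each cluster's member
   sites are padded by 5 bp and the common motif is re-discovered on them
   (the merged model); the loop repeats while any pair has similarity > 0.4
   together with site-overlap rate > 0.5 (such pairs also gain edges in
   repeat rounds — without this the loop cannot terminate with the
   invariant satisfied). Overlap is assessed on the substitution-tolerant
   evidence sites. The final Umotif carries the union of member pattern
   sites (overlapping intervals collapsed).

8. **Projection and CRM calls.** Umotif sites are projected onto the
   genome and overlapping projections merge into non-overlapping CREs
   labelled with all contributing Umotifs. Adjacent CREs are linked when
   their gap is below δ = 150 bp and the gap does not fully contain a
   CRE-free exon; maximal linked runs of ≥ 2 CREs are the predicted CRMs
   (singleton CREs are not CRMs). Each CRM can be assigned the gene with
   the nearest TSS (distance 0 inside the span; ties break
   lexicographically).

## CRE placement: the anchored-scan policy

Site placement must balance two failure modes. Exact pattern matches have
high precision but miss substituted sites (a width-8 site with 5% per-base
substitution is missed ~34% of the time), which breaks both pair
statistics and CRM spans. Substitution-tolerant scanning recovers those
sites but its Hamming-1 footprint (25 of 65,536 words) produces a dense
genome-wide noise floor that chains into spurious CRMs. The default
projection therefore uses both tiers: exact-pattern sites are anchors, and
a scan hit is added only when a non-overlapping anchor of a *different*
Umotif lies within δ. A mutated true site sits next to its grammar
partner's anchor and is rescued; isolated scan noise is not. The
alternatives (`projection="pattern-sites"` and `"scan-genome"`) are kept
for comparison.

## Motif similarity

The default metric (`column-l1-corrected`) aligns frequency matrices at
every ungapped offset in both orientations, scores aligned columns as
1 − ½·L1 distance, normalizes the best alignment by the larger width, then
subtracts a per-pair chance level — the mean best-alignment score against
cyclic column-shift decoys, which preserves composition while destroying
alignment — and rescales so unrelated motifs sit near 0 and identical
motifs at exactly 1. The correction matters: without it, two sharp 8-mers
score ~0.4–0.5 by chance (maximization over offsets), and any two CPs
sharing one true motif would clear β = 1.36. The uncorrected metric is
available as `column-l1`. The default cutoff values attached to
similarity thresholds (the 0.7 merge edge, the 0.4 stop rule, β = 1.36)
are kept at their conventional values, and all of them are exposed in
configuration because such thresholds are metric-scale dependent.

## The synthetic benchmark

The generator plants ground truth end to end: an i.i.d. genome at 45% GC;
eight width-8 high-information consensus motifs, pairwise separated by
Hamming distance ≥ 3 in both orientations; four grammars (two pairs, one
triple, one quadruple — three motifs shared between grammars); 40
non-overlapping instances per grammar with inter-CRE spacing uniform on
[20, 120] bp (below δ, so planted CRMs are linkable), each CRE written on
a random strand with i.i.d. 5% per-base substitution; and 12 datasets of
300 peaks each (one TF per dataset, round-robin over the motifs), half
signal peaks centered on that TF's planted sites with ±100 bp jitter and
lengths ~N(1000, 200²) truncated to [200, 4000] bp, half uniform noise
peaks. Pure-noise datasets (no TF) can be added. Everything is
deterministic under a seed; every stage of the pipeline can be scored
against the truth records. The canonical full-scale scenario runs in a few
minutes; tests that need many repetitions use a half-scale rendition
(1 Mb, 20 instances, 150 peaks) — dataset power analyses showed smaller
renditions lose motif discovery power entirely (the Fisher test cannot
clear its multiple-testing correction below ~150 peaks per dataset).

What passing tests on this benchmark do **not** show about real data: real
peaks have summit-position uncertainty and width structure correlated with
binding strength; real motifs are wider, softer and position-dependent;
real genomes have repeats, composition heterogeneity and conservation
structure none of which the i.i.d. background emulates; and the benchmark's
small genome makes chance word/instance co-location far more likely than
in a metazoan genome, which stresses the funnel's specificity beyond the
realistic regime (see limitations).

## Numerical choices

- Coordinates are 0-based half-open everywhere internally; reports print
  1-based inclusive spans.
- Motif scanning skips windows containing N; scan backgrounds are add-one
  smoothed and strand-symmetrized.
- Fisher tail probabilities are computed in log space from the
  hypergeometric log-pmf with a term recursion, truncated at 128 terms
  with a geometric remainder bound (exact to float precision for enriched
  candidates); an enrichment prefilter restricts exact evaluation to the
  2,000 most promising words per width, which cannot change the selected
  candidate; the E-value multiplier still counts every enumerated word.
- Ties everywhere break deterministically: candidate selection prefers the
  lexicographically smallest consensus; scan hits resolve overlaps to the
  higher score, then leftmost; MCL assigns contested nodes to the larger
  attraction, then the larger cluster, then lexicographic order.
- MCL adds self-loops at each node's maximum incident weight (1 for
  isolated nodes) for numerical stability; matrices are dense (the graphs
  here have at most a few thousand nodes); non-convergence returns the
  current clustering with a warning.
- The circular random baseline concatenates peak-covered segments in
  chromosome order, joins the ends, and drops same-length arcs uniformly;
  arcs crossing segment boundaries map back to split genomic pieces, and a
  split arc counts as one prediction when overlaps are scored.
- Conservation means average covered bases only; fully uncovered regions
  are excluded and counted.

## Known limitations

- The funnel cannot distinguish a genome word that genuinely co-locates
  with planted CRM instances from a grammar member: such words are
  enriched, co-occur with true motifs on the same peaks, and recur across
  datasets. On a 2 Mb genome with 40 instances per grammar these remnants
  survive to the Umotif stage (typically 1–4 per run, plus offset "shadow"
  variants of true motifs discovered from residual mutated instances after
  masking). On genome scales where instance neighborhoods are a vanishing
  sequence fraction this failure mode shrinks accordingly.
- Peak-level presence statistics are over-dispersed when few planted
  instances are resampled by many peaks; the Fisher test treats peaks as
  independent and is anticonservative in exactly the regime the canonical
  scenario creates for single-grammar TFs.
- The min-normalized co-occurrence score lets a rare motif ride on a
  common partner; the funnel relies on the cross-dataset similarity stage
  to remove such pairs.
- Auto threshold selection (α, β, γ) is heuristic and falls back to fixed
  defaults on degenerate inputs.
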