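# crmine

Genome-wide prediction of cis-regulatory modules (CRMs) and their
constituent elements (CREs) by integrating many transcription-factor (TF)
ChIP peak datasets.

Enhancers and other CRMs are clusters of closely spaced TF binding sites
(CREs). When ChIP datasets for many TFs are available, peaks of cooperative
TFs pile up over shared CRMs, and the motif *combinations* that recur
across datasets distinguish regulatory grammar from the large amount of
noise any single motif-finding run produces. `crmine` exploits this with a
graph-theoretic funnel:

1. filter and extend binding peaks (HOT-region removal, length filter,
   symmetric padding to ~CRM scale capped at exons);
2. discover overrepresented motifs per dataset with a DREME-style
   discriminative finder (Fisher exact test against an order-3 Markov
   negative set, E-value threshold, greedy site masking);
3. score within-dataset motif co-occurrence
   `Sc = o / min(|Mi|, |Mj|)` over supporting peaks and keep pairs with
   `Sc ≥ α` (CPs);
4. connect CPs across datasets whose motif content is similar
   (`Ss ≥ β`, the best cross-pairing similarity plus the remaining pair's)
   and cut the multi-partite graph with Markov Chain Clustering (MCL) into
   CP clusters (CPCs), discarding clusters smaller than τ;
5. score CPC co-occurrence on shared peaks (`S_CPC ≥ γ`) and cut again
   into CRM components (CRMCs) — recurring motif combinations;
6. merge redundant motifs into unique motifs (Umotifs), project their
   sites back onto the genome, and link CREs closer than δ = 150 bp
   (respecting exons) into predicted CRMs with nearest-TSS target genes.

Predictions are evaluated by half-length recovery of known CRMs, a
circular-genome random baseline (same number and lengths of segments drawn
uniformly on the circularized peak-covered sequence), and conservation
comparisons against matched random regions (two-sample KS test, with
highly-conserved ≥ 0.98 and non-conserved ≤ 0.02 classes).

A fully ground-truthed synthetic generator (random genome, motif library,
CRM grammars, planted instances with per-base mutation, per-TF peak
datasets) makes every stage testable without downloads. See
`docs/methods.md` for the model details and design decisions.

## Worked example

`examples/01_simulate_and_mine.py` plants two two-motif grammars (30
instances each) in a 500 kb genome, simulates four ChIP datasets of 100
peaks, and mines them end to end:

```text
planted motifs: ['AATCGGGA', 'CACTGAGA', 'TTTGTCAG', 'CGTCTACT']
n_motifs     32
n_cps        83
n_cpcs       6
n_crmcs      2
n_umotifs    7
n_cres       406
n_crms       121
recovery     0.983
baseline     0.063 +- 0.043
U1: AATCGGGAA  members=2 sites=57
U2: TCTCAGTG  members=2 sites=87
...
```

Reading this: 32 motifs were discovered across the four datasets (most
are noise), 83 within-dataset pairs passed α, clustering across datasets
left 6 CPCs and 2 recurring motif combinations — one per planted grammar.
The merged unique motifs recover the planted consensi (U2 = `TCTCAGTG` is
the reverse complement of planted `CACTGAGA`), and 98.3% of the planted
CRMs are covered at least half by a predicted CRM, against a 6.3%
random-placement baseline. The other examples demonstrate motif discovery
(`02`), similarity and MCL (`03`), and the evaluation primitives (`04`).

A thin command-line interface covers batch use
(`crmine simulate`, `crmine run-all`, `crmine evaluate`); the Python API
is the primary surface.

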