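# readthrough

Prediction of basal translational readthrough (BTR) from stop-codon
sequence context, and detection of functional C-terminal extensions —
in particular hidden peroxisomal targeting signals (PTS1).

Translation does not always terminate at the annotated stop codon: at a
low basal rate the ribosome decodes the stop as sense and continues in
frame to the next stop, appending a C-terminal extension to the protein.
How often this happens depends strongly on the stop codon itself and the
handful of nucleotides around it — the *stop-codon context* (SCC),
positions −6 to +9 with the stop at +1..+3.  When the appended extension
carries a targeting signal, readthrough produces a differently localised
protein isoform from the same gene (the textbook case being lactate
dehydrogenase B, whose 7-residue extension ends in the cryptic PTS1
tripeptide SRL).

This package is for computational biologists who want to score stop
contexts, rank transcriptomes for readthrough candidates, or analyse
dual-reporter readthrough assays.

## The model

An SCC is indicator-encoded: four binary entries per context position
(A/C/G/T at −6..−1 and +4..+9) plus three entries for the stop codon,
treated as one categorical position — 12 × 4 + 3 = 51 dimensions.
Feature vectors **x** are normalised to Euclidean unit length.  Given *n*
contexts with measured readthrough values **y**, the regression weights
solve the ridge closed form (no intercept)

    w = (XᵀX + k·I)⁻¹ Xᵀy

with k chosen by leave-one-out cross-validation over the grid
k = 10^i, i = −3, −2.7, …, 3 (default k = 10^0.3 ≈ 1.995).  Prediction
for a context is wᵀx; dividing by the Euclidean norm of the weight stack
gives the dimensionless, scale-free **readthrough propensity** (RTP).
Equivalently, the sum of matched raw weights can be divided by a single
shortcut constant (weight norm × √active-positions): 0.0317 for the
bundled full-context model `LINiter` and 0.0126 for the reduced model
`LINfs3` (stop + positions +4..+6, consensus **UGA CUA**).

On top of this sit:

* **feature selection** — backward elimination of context positions by
  minimum sum of squared coefficients, re-fitting with loo-CV at each
  step; the loo-error minima identify reduced models and the
  high-readthrough consensus motif;
* a **PTS1 classifier** — a regularised least-squares classifier (ridge
  on ±1 labels) over indicator-encoded 15-residue C-termini, with a
  Platt-calibrated posterior; the recoded stop is scored as an undefined
  residue `X` with no contribution;
* a **transcriptome scan** — filter and deduplicate CDS+downstream
  records, find the in-frame extension behind each stop (≤300 nt), and
  rank candidates by RTP⁺ × PTS1 posterior, where RTP⁺ is RTP min-max
  scaled to [0, 1] over the scanned set;
* **dual-reporter statistics** — luciferase/fluorescence ratios with
  first-order error propagation, percent-of-control normalisation,
  inverse-variance weighted means and induction factors.

## Worked example

Score three experimentally measured contexts with the bundled models:

```python
from readthrough import parse_scc, published_model, rtp_score
from readthrough.featsel import consensus_motif
from readthrough.synth import fixtures

tab = fixtures("table1")          # measured dual-reporter contexts
for name in ("LINiter", "LINfs3"):
    model = published_model(name)
    for gene in ("LDHB", "MDH1", "FBXL20"):
        row = tab[tab.context_id == gene].iloc[0]
        ctx = parse_scc(row.scc_text, flank=10)
        s = rtp_score(model, ctx)
        print(f"{name:8s} {gene:7s} measured={row.readthrough_pct:5.2f}%  RTP={s.rtp:+.3f}")
print("LINfs3 consensus:", consensus_motif(published_model("LINfs3")).as_rna())
```

prints

```
LINiter  LDHB    measured= 1.55%  RTP=+0.608
LINiter  MDH1    measured= 2.91%  RTP=+0.816
LINiter  FBXL20  measured= 0.10%  RTP=+0.245
LINfs3   LDHB    measured= 1.55%  RTP=+0.939
LINfs3   MDH1    measured= 2.91%  RTP=+0.939
LINfs3   FBXL20  measured= 0.10%  RTP=+0.646
LINfs3 consensus: UGA CUA
```

The high-readthrough contexts (LDHB, MDH1 — both UGA followed by CUA)
score near the top of the RTP scale, the low-readthrough FBXL20 context
scores much lower, and LDHB and MDH1 are indistinguishable to `LINfs3`
because they share the stop and the +4..+6 codon — the positions that
model retains.  RTP is a normalised propensity, not a percentage:
ranking, not absolute readthrough, is its job.

The same stack is scriptable from the shell — `readthrough rtp
fit/score/select`, `readthrough pts1 train/score`, `readthrough scan`,
`readthrough reporter`, `readthrough synth …` — see `readthrough --help`.

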