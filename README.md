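# splicepipe

Predicting whether a DNA variant disrupts pre-mRNA splicing — anywhere in a
gene, by any mechanism — from a single analysis.

Clinical variant interpretation has to consider that *any* nucleotide
change, exonic or intronic, can be pathogenic through splicing: it can
damage the donor (5'ss) or acceptor (3'ss) consensus, the branch point
(BP), the polypyrimidine tract (PPT), or an exonic splicing regulator
(ESR), and it can create or reinforce a splice site where none was used
before — causing exon skipping, splice-site shifts, pseudo-exon inclusion
or intron retention. Most single-purpose scores see only one of these
motifs. `splicepipe` cascades them: per-motif scores feed a logistic
metascore for splice-site use, and everything is combined by a random
forest whose tree-vote fraction is the final spliceogenicity score, with a
specificity-calibrated decision threshold, confidence intervals per score
bin, and a per-variant statement of which motif is probably hit.

## The models in brief

* **Consensus sites** — donor 9-mer (exon −3..intron +6) and acceptor
  23-mer (intron −20..exon +3), scored by a Shapiro–Senapathy-style percent
  PWM, `100·(Σf − Σmin)/(Σmax − Σmin)`, and by a trained log-odds model
  `log2 P_signal(s)/P_bg(s)` (order-0 or order-1 Markov signal; external
  maximum-entropy score tables can be plugged in).
* **ESRs** — Δ of hexamer score sums over the windows touching the edited
  bases (≤6 hexamers per allele).
* **BP / PPT** — best adenosine in intron −18..−44 scored by a 7-mer PWM
  plus a pyrimidine-context term; PPT as weighted pyrimidine content of
  intron −5..−17.
* **Site-use metascore** — for every GT/AG-anchored candidate,
  `p = σ(β₀ + β₁·MES + β₂·SSF + β₃·ESR_context)`, trained on annotated
  versus random GT/AG sites; scanning WT vs mutant sequence around the
  variant classifies natural-site shift / de novo / cryptic / combined
  site creation, plus deep-intronic pseudo-exon pairs (30–963 nt).
* **Classifier** — random forest over 16 motif/position predictors pruned
  by backward selection; score = fraction of trees voting spliceogenic;
  threshold set for 99% specificity on a position-keyed validation half.

See `docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Everything runs on generated data, so this is self-contained:

```python
from splicepipe import (simulate_reference, simulate_collection,
                        CollectionSpec, fit_spip_model, score_table)
from splicepipe.synthetic_data import collection_frame

ref = simulate_reference(n_transcripts=10, seed=7)
spec = CollectionSpec(n_curated=500, n_controls=4500, prevalence=0.0208, seed=7)
collection = collection_frame(simulate_collection(spec, ref))
model, report = fit_spip_model(
    ref.genome, ref.transcripts, ref.esr_table, collection, seed=7, n_trees=300
)
print(f"held-out ROC AUC: {report['valid'].roc_auc:.3f}")
print(f"decision threshold: {model.tau:.3f} "
      f"(specificity {model.achieved_specificity:.2%})")

hits = collection[collection.label == 1].head(3)
out = score_table(hits, model, ref.genome, ref.transcripts)
print(out[["transcript", "hgvs_c", "region", "spip_score",
           "decision", "interpretation"]].to_string(index=False))
```

prints

```
held-out ROC AUC: 0.966
decision threshold: 0.263 (specificity 99.02%)
transcript     hgvs_c                 region  spip_score decision       interpretation
     TX004 c.703+2T>A intronic_consensus_5ss    0.996667 positive consensus_alteration
     TX008   c.419C>G             exonic_esr    0.343333 positive      new_splice_site
     TX004   c.335A>C             exonic_esr    0.180000      NTR                  NTR
```

The first variant destroys a donor +2 and 99.7% of trees vote spliceogenic;
the second, an exonic change, is called positive via a created splice-site
candidate; the third scores below the 99%-specificity threshold and is
reported NTR (“nothing to report”), which is how this operating point
trades a few missed positives for a low false-discovery rate at 2%
prevalence.

The same pipeline is scriptable from the shell:

```
splicepipe simulate --out-dir bundle --seed 7 --n-transcripts 10
splicepipe train --genome bundle/genome.fa --transcripts bundle/transcripts.tsv \
    --esr-table bundle/esr_table.tsv --collection bundle/collection.tsv \
    --model model_dir --seed 7
splicepipe score --genome bundle/genome.fa --transcripts bundle/transcripts.tsv \
    --model model_dir --input bundle/collection.tsv --output scored.tsv --workers 4
```

Scoring accepts `transcript` + `hgvs_c` columns (e.g. `c.4096+3A>G`) or
`chrom/pos/ref/alt`, and VCF-derived tables; failures are row-scoped and
the output is byte-identical for any worker count.

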