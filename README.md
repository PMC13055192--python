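# embedrepeat

Detection of internal (tandem) repeats in protein sequences from
per-residue language-model embeddings, plus a light-attention classifier
that serves as a fast repeat/non-repeat pre-filter.

Classical repeat detectors align a protein against itself and look for
strong off-diagonal alignments. When repeat units have diverged beyond
recognizable sequence identity, amino-acid substitution scores lose the
signal, while per-residue embeddings from protein language models still
carry it: the cosine similarity between embedding rows acts as a
context-dependent substitution score. `embedrepeat` builds on that idea:

1. **Self-alignment.** The (L x D) embedding `E_fl` is compared against
   itself; cosine similarities form an L x L substitution matrix. A local
   dynamic program reports *all* significant suboptimal traces (paths), not
   just the best one — each trace is one candidate unit-vs-unit alignment.
2. **Transitivity.** If residues i–j are aligned in one trace and j–k in
   another (or in the same trace), the composed trace i–k is added after
   passing the same filters. One round only.
3. **Score matrix.** Traces are accumulated into a dot-plot-like matrix
   `M_s[i,j] = Σ_{t ∋ (i,j)} TraceScore(t)`.
4. **Repeat length.** Cell scores are summed per diagonal distance
   d = 1 … L/2; every distance with positive mass is a candidate unit
   length `l`.
5. **Representative repeat.** An l-column sliding window maximizes
   `Score_window(c) = Σ_i Σ_p w(p)·M_s[i, c+p−1]` with triangular weights
   `w(p) = min(p, l−p+1) − ½` (conserved positions concentrate mid-unit).
6. **Weighted embedding.** `E_repeat = M_sw^T · E_fl` stacks the embeddings
   of all positions aligned to each representative column, like building a
   profile from an MSA.
7. **Instances & MSA.** `E_repeat` is searched against the full-length
   embedding; accepted spans are globally aligned back to the
   representative, stitched into an A2M alignment, and the best length
   hypothesis is selected by mean coverage.
8. **Iteration.** Detected regions are masked out of `M_s` and steps 4–7
   repeat, so proteins with several distinct repeat regions yield several
   families.

A pluggable provider supplies embeddings. The built-in synthetic provider
and the planted-repeat generator make the whole pipeline testable offline
with controlled similarity structure; a real protein language model
(e.g. ProtT5, D = 1024) can be registered through the same interface.

## Worked example

```bash
# generate 3 planted-repeat proteins (unit 18, 4 copies) + 3 background ones
embedrepeat simulate --n-positive 3 --n-negative 3 --unit-length 18 \
    --n-copies 4 --seed 5 --out corpus/

# detect repeats in one of them
embedrepeat detect --embedding corpus/pos0000.emb.tsv --out detection/
```

which prints (stderr) and writes `detection/repeats.tsv`:

```
pos0000: 1 repeat families

sequence_id  iteration  family  instance_index  start  end  length  score
pos0000      0          0       0               11     28   18      0.958208
pos0000      0          0       1               29     46   18      0.968966
pos0000      0          0       2               47     64   18      0.934358
pos0000      0          0       3               65     82   18      0.968338
```

One family was found in the first masking iteration: the estimated unit
length is 18 (the planted truth), with four instances tiling the
repeat region; `start`/`end` are
1-based inclusive, and `score` is the mean per-aligned-pair cosine between
the instance and the representative profile (1.0 = identical). The MSA of
the family is written next to it in A2M convention (uppercase = match to a
representative column, lowercase = insertion, `-` = deletion), and
`report.json` records every parameter and seed needed to reproduce the run.

Training and using the pre-filter classifier:

```bash
embedrepeat simulate --n-positive 50 --n-negative 50 --seed 1 --out train/
embedrepeat train --data train/ --channels 32 --out model.npz
embedrepeat classify corpus/*.emb.tsv --model model.npz --out labels.tsv
```

`embedrepeat benchmark` scores a repeat table against ground-truth unit
annotations at the protein level (majority of predictions mutually aligned)
and the repeat level (reciprocal span overlap with an annotated unit).

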