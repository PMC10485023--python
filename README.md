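# crispract

Tools for measuring and predicting bacterial sgRNA on-target activity:

- **`guide_design`** — scan DNA for 5'-NGG-3' PAM target sites, flag upstream
  5'-CNNNG-3' dual-nuclease cleavage motifs, exclude guides with PAM-adjacent
  off-target k-mer matches, tile single/adjacent-double transversion variants
  into mismatch oligo pools, extract model input windows, one-hot encode.
- **`activity_scoring`** — turn guide read counts from paired
  induced/repressed (or pool-vs-endpoint depletion) screens into
  compositional activity scores via centred-log-ratio (CLR) transformed
  Dirichlet Monte-Carlo instances: per-guide `diff_btw`, `diff_win`,
  `rab_all`, effect sizes, BH-adjusted q-values, and the standardized score
  used as the regression target.  Also: exact-match amplicon demultiplexing
  and growth-curve phenotype classification by normalized trapezoidal AUC.
- **`model_core`** — a dual-branch regression network (shared convolution →
  multi-layer CNN branch + hybrid CNN-BGRU branch → dense head → scalar)
  trained with Adam/MSE, plus layer-freezing transfer learning from a large
  base dataset to small high-quality datasets.  The backend is pure NumPy
  (`crispract.nn`), so training is bit-deterministic given a seed and frozen
  layers are exactly untouched by fine-tuning.
- **`evaluation`** — Spearman rank metrics, 5-fold cross-validation with a
  leakage guard, input-window length sweeps, and dataset deduplication.
- **`synthetic_data`** — seeded generators for every fixture the test suite
  needs: planted sequence→activity functions with PAM-proximal (seed-region)
  dominance, multinomial paired-condition count tables with toxic guides,
  growth-curve cohorts, and large/small transfer-learning dataset pairs.

## CLI

One entry point, `crispract`, with five command groups:

```sh
# target-site design
crispract design scan --fasta plasmid.fasta --pam NGG --k-offtarget 15 \
    --circular --tev-min 13 --tev-max 17 --out sites.tsv --bed sites.bed
crispract design mpool --guides parents.tsv --map ACGT:CATG --out pool.tsv
crispract design encode --sites sites.tsv --upstream 0 --downstream 8 --out x.npz

# scoring
crispract score counts --fastq reads.fastq.gz --design design.yaml \
    --pool pool.tsv --out counts.tsv
crispract score clr --counts counts.tsv --design samples.yaml \
    --group-a repressed --group-b induced --instances 128 --seed 7 \
    --min-control 20 --standardize --out scores.tsv
crispract score growth --od plates.tsv --active 1.64 --toxic 0.121

# modeling
crispract model train-base --data large.tsv --epochs 25 --seed 1 --out base
crispract model transfer --base base --data small.tsv --freeze default \
    --epochs 8 --seed 1 --out final
crispract model predict --model final --sites sites28.tsv --out preds.tsv

# evaluation
crispract eval cv --data small.tsv --base base --k 5 --seed 1
crispract eval sweep --data contexts43.tsv --umax 10 --dmax 13 --seed 1 --out sweep.tsv
crispract eval dedupe --ref large.tsv --test small.tsv --out unique.tsv

# synthetic fixtures
crispract simulate screen --guides 1000 --toxic 120 --reps 10 \
    --depth 1000000 --seed 7 --out sim/
```

Scored-dataset TSVs have two columns, `sequence` (uniform-length target-site
window, protospacer first) and `target` (standardized activity score).
Count tables are guide × sample TSVs with a YAML sidecar listing per-sample
`condition` and `replicate`.

## Defaults worth knowing

- Model input window: 28 nt = 20-nt protospacer + NGG PAM + 5 downstream nt.
- One-hot rows are A, C, G, T; protospacer positions are numbered 1
  (PAM-proximal) to 20 (PAM-distal).
- CLR scoring: Dirichlet(counts + 0.5), 128 Monte-Carlo instances, Welch's t
  with BH correction (Wilcoxon optional); a seed is mandatory.
- Low-count filter: drop guides below 20 reads in *any* control replicate
  (strict `<`); dispersion filter: drop guides with `diff_win` strictly
  above 1.
- Transfer learning freeze plan (`default`): train the shared first
  convolution, the whole CNN-BGRU branch, and the final output layer; freeze
  the remaining CNN-branch and post-concatenation dense layers.
- Published layer sizes/epochs were tuned but not printed; the defaults in
  `ModelSpec` / `BASE_TRAIN` / `TRANSFER_TRAIN` are documented stand-ins and
  fully configurable.
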