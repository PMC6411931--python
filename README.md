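# berbp

Predicts whether a human RNA-binding protein (RBP) binds a given RNA
sequence, starting from the RBP's binding preference as a position weight
matrix (PWM).

Each candidate sequence is scanned against the PWM; the ten best-matching
putative sites are each described by four feature types:

* **MS** — matching score: plain sum of PWM frequencies over the site
  (N bases contribute 0.25).
* **CS** — clustering score: the five largest local matching-score maxima
  in a 50-nt window centered on the site, weighted 2^-r by rank.
* **Gacc** — accessibility: free-energy difference between a constrained
  fold (40-nt core forced unpaired) and an unconstrained fold of a 180-nt
  segment around the site.
* **Csrv** — conservation: mean of a user-supplied per-position
  conservation track over ten positions from the site start.

This yields a 40-entry vector (MS1..MS10, CS1..CS10, Gacc1..Gacc10,
Csrv1..Csrv10) per sequence. Two Random-Forest model flavors are trained
on such vectors:

* **specific** — one forest per PWM, raw features;
* **general** — one pooled forest over features z-standardized against a
  background sequence set per PWM (1:2 positive:negative ratio by
  default), applicable to PWMs with no known targets.

A synthetic-data module (seeded PWM, planted-motif positives, background
negatives, conservation tracks) makes the whole pipeline runnable and
testable offline.

## Test

```sh
python -m pytest -q tests/
```

## CLI

```sh
# generate a planted-motif dataset
berbp simulate --seed 1 --k 7 --n-pos 100 --n-neg 100 --out-dir sim/

# feature table (40 named columns per sequence)
berbp features --fasta sim/positives.fasta --pwm sim/pwm.tsv \
    --track sim/tracks.tsv --out features.tsv

# background stats for z-standardization
berbp background --fasta background.fasta --pwm sim/pwm.tsv --out stats.json

# per-PWM model on raw features
berbp train-specific --pos sim/positives.fasta --neg sim/negatives.fasta \
    --pwm sim/pwm.tsv --track sim/tracks.tsv --seed 0 --out model

# pooled general model (YAML lists one {pwm, pwm_id, pos, neg, background}
# entry per PWM)
berbp train-general --config general.yaml --seed 0 --out general_model

# predict and evaluate
berbp predict --model model --fasta query.fasta --pwm sim/pwm.tsv --out pred.tsv
berbp evaluate --model model --pos sim/positives.fasta \
    --neg sim/negatives.fasta --pwm sim/pwm.tsv --out eval.tsv
```

Every command writes a `<output>.runconfig.json` recording seeds, counts
and the tool version; identical configs reproduce byte-identical outputs.

PWM input is a tab-separated position-by-nucleotide table (header
`Pos A C G U`, a `T` column is accepted) or a minimal MEME motif file
(`--pwm-format meme`). Conservation tracks are TSVs of
`seq_id  pos(1-based)  score`; unlisted positions default to 0.

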