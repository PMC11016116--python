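# smafbi

Hybrid slime-mould / forensic-based-investigation metaheuristic for
continuous global optimization, with a binary variant for wrapper gene
selection on high-dimensional, small-sample expression data.

## Who this is for

Researchers doing feature (gene) selection on microarray-style matrices —
tens of samples, thousands of genes — who want a wrapper method that finds
small, highly discriminative gene subsets, and anyone who needs the
underlying continuous optimizer for box-bounded black-box minimization.

## The method

**FBI** (forensic-based investigation) evolves two groups of NP candidate
"suspect locations" sharing a global best `X_best`:

- *Investigation step A1*: `X'_i = X_i + (r1 − 0.5)·2 · (X_i − (X_k + X_h)/2)`
  with random peers k, h — a move relative to the peer midpoint.
- *Step A2* (applied to members whose selection probability
  `Prob_i = (p_worst − p_i)/(p_worst − p_best)` falls below a uniform draw):
  `X'_i = X_best + X_d + r2·(X_e − X_f)`.
- *Pursuit step B1*: `X'_i = r3·X_i + r4·(X_best − X_i)`.
- *Step B2*: interaction with a random partner `X_r`, moving from whichever
  of the pair is better toward `X_best`.

All FBI proposals are accepted greedily (keep the lower objective value).

**SMA_FBI** adds a third, slime-mould *inspector* group updated by

```
X(t+1) = rand·(ub−lb)+lb                  with prob. z = 0.03   (restart)
       = X_b + vb·(W·X_A − X_B)           if r < p             (approach)
       = vc·X(t)                          otherwise            (contract)
```

with `p = tanh|S(i) − DF|`, `vb ~ U[−a, a]`, `a = arctanh(1 − t/Max_t)`,
`vc ~ U[−c, c]` with c declining linearly 1 → 0, and fitness-ranked weights
`W = 1 ± r·log10((bF − S(i))/(bF − wF) + 1)` (+ for the superior half of the
ranking). The three groups exchange information only through the shared
global best, so the inspector phase can be switched off to recover plain FBI
exactly.

**BSMA_FBI** binarizes the hybrid for gene selection: each coordinate maps
to a selection probability through the V-shaped transfer `T(x) = |tanh x|`
(`bit_j = 1` iff `u_j < T(x_j)`), and masks are scored by

```
fitness = 0.95 · error + 0.05 · l/d
```

where `error` is the stratified ten-fold CV misclassification rate of a KNN
classifier on the selected genes, `l` the subset size and `d` the gene count.

## Worked example

Simulate a 60-sample x 500-gene expression matrix with 10 planted
informative genes (class mean shift 4 noise-SDs), then select genes:

```
$ smafbi simulate --samples 60 --features 500 --informative 10 --sep 4 \
      --seed 7 --out sim_demo
wrote 60x500 dataset with 10 informative genes to sim_demo

$ smafbi select --data sim_demo/X.csv --labels-file sim_demo/labels.csv \
      --runs 3 --folds 10 --evals 2000 --pop 20 --mode cv --seed 7 --out sel_demo
bsma_fbi: mean features 1.3 (of 500), mean error 0.0000, mean fitness 0.0001; report in sel_demo
```

The three runs selected subsets of 1, 1 and 2 genes with zero ten-fold CV
error; the run-0 subset is gene 103, which is indeed one of the ten planted
informative genes (`sim_demo/truth.json`). That is the intended behaviour of
the fitness above: it rewards the *smallest* zero-error subset, not recovery
of every informative gene (see `docs/methods.md`).

Continuous optimization uses the same registry:

```
$ smafbi optimize --algo sma_fbi --function rastrigin --dim 10 --pop 30 \
      --evals 30000 --seed 1 --repeats 3 --out opt_demo
sma_fbi on rastrigin D=10: best 0 over 3 run(s); report in opt_demo
```

`smafbi bench` compares registered algorithms across the battery and emits
mean/std tables, Wilcoxon +/=/− tallies and Friedman average ranks (ARV).

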