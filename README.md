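# midpipe

Decoding prior behavioral experience from sparse, low-rate neural
delay-period activity — and explaining *which* neurons and time bins carry
the information.

## The problem

During the delay between trials of a behavioral task, hippocampal
populations fire at low rates, yet a linear classifier can often predict
the previous binary choice (left vs right turn) from 100 ms population
vectors slightly — but significantly — above chance. The interesting
follow-up questions are the ones a black-box classifier cannot answer:
which neural ensembles support the prediction, and in which brief moments
of the delay does the information appear?

`midpipe` implements the full analysis chain for these questions:

1. **Population vectors** — spike counts per unit per time bin of width L
   inside the delay windows, z-scored per unit over the session
   (`patterns`).
2. **Decoding** — a linear softmax network O = σ(Wx) trained by gradient
   descent on cross-entropy; correct classification rate (CCR) over 100
   stratified 2-fold splits; per-bin prediction scores (PS); label-shuffle
   permutation p values (`decoder`).
3. **Boundary sampling** — doubly applied minimal-step FGSM adversarial
   attacks move every pattern onto the decision boundary, repeated over
   100 half-subsamples with retrained classifiers (`boundary`).
4. **Most informative directions (MIDs)** — local boundary normals from
   the smallest eigenvector of the neighbor-difference scatter, clustered
   with DBSCAN (eps 0.25, min 3%) within and across subsamples; each MID
   carries an amount α and a consistency χ (`mids`).
5. **Relevant time bins** — bins whose bias-corrected MID overlap
   q_t(c) = n(c)·(x_t − b(c)) escapes the central 95% of a
   neuron-index-shuffle null; plus rate/PS/sparseness statistics of
   relevant vs non-relevant bins (`relevance`).
6. **Session-level inference** — chi-squared homogeneity tests on
   significant-session fractions and exact binomial enrichment tests
   (`sessionstats`); an LFP band-power regression screen for the
   prediction scores (`lfp`).
7. **Synthetic ground truth** — generators for a linearly separable
   Gaussian task, a Poisson spiking task with planted binary patterns, and
   full synthetic sessions, so every stage is validated against known
   structure (`synthdata`).

## Worked example

```python
import numpy as np
from midpipe import (SpikingTaskSpec, gen_spiking_task, standardize_patterns,
                     DecoderConfig, AttackConfig, label_shuffle_pvalue,
                     sample_boundary, local_normals, cluster_mids,
                     relevance_mask)

# Poisson spiking at 0.1 spikes/bin, 30 neurons; a binary pattern over
# 6 neurons is added to half of the positive-label bins
raw, truth = gen_spiking_task(SpikingTaskSpec(
    n_neurons=30, rate_lambda=0.1, sparseness_s=0.2, p_fail=0.5,
    n_patterns=1000, seed=0))
patterns = standardize_patterns(raw)

dec = DecoderConfig(epochs=600, n_splits=20, n_label_shuffles=100, seed=1)
res = label_shuffle_pvalue(patterns, dec)
print(f"CCR {res.ccr:.3f}  p {res.p_value:.3f}")

cloud = sample_boundary(patterns, AttackConfig(
    n_subsamples=20, decoder=dec, seed=2))
midset = cluster_mids(local_normals(cloud), n_subsamples=20)
top = midset.representatives[0]
w = truth.weight_vector / np.linalg.norm(truth.weight_vector)
print(f"MIDs {midset.n_clusters}  top alpha {midset.amount[0]:.2f}  "
      f"chi {midset.consistency[0]:.2f}  |overlap with truth| {abs(top @ w):.3f}")

mask = relevance_mask(patterns, midset, n_shuffles=200, seed=3)
flagged = np.flatnonzero(mask.any_flag == 1)
planted = set(truth.planted_bin_indices)
tp = sum(1 for b in flagged if b in planted)
print(f"right-flagged bins {len(flagged)}  precision "
      f"{tp / len(flagged):.3f}  recall {tp / len(planted):.3f}")
```

Output:

```
CCR 0.746  p 0.000
MIDs 1  top alpha 1.00  chi 1.00  |overlap with truth| 0.983
right-flagged bins 216  precision 1.000  recall 0.864
```

The CCR of 0.746 sits near its ceiling for this task (only half of the
positive-label bins carry the planted pattern, so 0.75 is the best
possible), the permutation p value is below the shuffle resolution, a
single most-informative direction found in every subsample recovers the
planted 6-neuron ensemble almost perfectly, and the relevance flags find
86% of the planted bins with no false discoveries.

A command-line interface mirrors the library
(`midpipe simulate|decode|attack|mids|relevance|stats|lfp|run`); e.g.

```bash
midpipe simulate --out session/ --plant-sparseness 0.2 --seed 1
midpipe run --session session/ --out summary.json --subsamples 20 \
    --epochs 600 --splits 20 --shuffles 100 --seed 1
```

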