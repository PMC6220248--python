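# netrait

Graph-theoretic analysis of brain structural connectomes and their
association with a personality trait score.

Whole-brain tractography summarizes each subject's white-matter anatomy as a
weighted, symmetric 83×83 connectivity matrix **A** over the
Desikan–Killiany parcellation (41 regions per hemisphere plus the
brainstem). `netrait` implements the downstream analysis for a cohort of
such matrices:

1. **Entropy-optimal thresholding.** Each weighted network is binarized by
   keeping its K strongest edges, so all subjects have equal density. For a
   candidate K, every node pair gets an occurrence probability p(i,j) — the
   fraction of subjects whose binarized network contains that edge — and the
   cohort entropy is the sum of per-pair Bernoulli entropies
   H = Σ −[p log₂p + (1−p) log₂(1−p)]. The same entropy over an ensemble of
   degree-preserving rewirings (each seeded from one randomly chosen
   subject; 500 by default) gives H_null. The optimal K maximizes
   H_null − H_actual: the density at which the cohort is most predictable
   relative to its degree-matched null.
2. **Network measures** on the binarized graphs: characteristic path length
   (CPL, mean shortest-path length over reachable pairs), global clustering
   coefficient (GCC, mean nodal clustering by default; transitivity
   available), small-worldness
   SMW = (GCC_act/GCC_rand)/(CPL_act/CPL_rand) against a rewired ensemble,
   and unnormalized betweenness centrality (BET) per node.
3. **Trait association.** The 88 candidate predictors (age, sex, CPL, GCC,
   SMW, and BET of each of the 83 regions) are screened by L1-penalized
   least squares with a cross-validated penalty (one-SE rule by default);
   the selected terms — with age and sex always retained — enter an OLS fit
   of the standardized trait score. Subjects with Cook's distance above 3×
   the mean are removed in a single pass and the model refit. Associations
   are flagged at p < 0.01.

Because the MRI data this analysis was designed for are restricted, the
package ships a **synthetic cohort generator**: 51 subjects by default,
sharing a sparse connected backbone (343 edges) with subject-level
log-normal edge noise, covariates (age 20–65, sex), and a 12-item ordinal
trait scale calibrated to mean 23.5, SD 7.5 and internal consistency
α ≈ 0.81. A per-subject latent factor z scales all edges incident to
designated *effect nodes* by exp(γz) and loads on the trait score, planting
a betweenness→trait association with known sign; the full ground truth is
returned for recovery tests.

## Worked example

```python
from netrait import (GeneratorConfig, generate_cohort, scan_optimal_k,
                     binarize_top_k, compute_cohort_metrics,
                     run_association, AssociationConfig)

cfg = GeneratorConfig(n_subjects=51, seed=7)      # study-sized cohort
cohort, truth = generate_cohort(cfg)
# planted: lh_lateralorbitofrontal gamma=+0.8, rh_entorhinal gamma=-0.8

scan = scan_optimal_k(cohort.connectomes, k_grid=range(203, 404, 20),
                      n_random=100, rng=7)
print("optimal K:", scan.optimal_k)               # -> optimal K: 363

nets = [binarize_top_k(w, scan.optimal_k) for w in cohort.connectomes]
metrics = compute_cohort_metrics(nets, subject_ids=cohort.subject_ids,
                                 n_random=100, rng=7)
model = run_association(metrics, cohort, AssociationConfig(seed=7))
print(model.coefficient_table().round(4).to_string(index=False))
```

prints

```
                  predictor  standardized_beta  se_beta  t_value  p_value  significant
                (Intercept)            -0.0451   0.0824  -0.5466   0.5877        False
                        age             0.1207   0.0871   1.3856   0.1738        False
                        sex            -0.1048   0.0822  -1.2753   0.2098        False
bet_lh_lateralorbitofrontal             0.3756   0.0940   3.9945   0.0003         True
     bet_lh_parahippocampal             0.0862   0.1180   0.7308   0.4693        False
              bet_rh_cuneus            -0.1971   0.0841  -2.3439   0.0243        False
          bet_rh_entorhinal            -0.3936   0.0902  -4.3646   0.0001         True
  bet_rh_posteriorcingulate            -0.1899   0.0848  -2.2377   0.0310        False
          bet_rh_precentral            -0.3423   0.0822  -4.1628   0.0002         True
```

The entropy scan lands near the planted 343-edge backbone (K = 363, i.e.
mean degree ≈ 8.7), and the two planted effect nodes are the two strongest
selected terms, significant at p < 0.01 with signs matching their planted
γ (+0.8 and −0.8). Coefficients are standardized βs: SD change in trait
score per SD change in the predictor. (`bet_rh_precentral` is a false
positive of the selection-then-test procedure — at n = 51 these occur; the
package's null-cohort tests bound how often.)

The same pipeline is available from the shell:

```bash
netrait run-all --config run.yaml --out results/run1
netrait simulate --out cohort/ --seed 7     # cohort + ground_truth.json
```

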