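# symptomnet

Network psychometrics of mental distress: estimate and describe the
partial-correlation network of stress, anxiety and depression symptoms
measured by ordinal questionnaires such as the DASS-21 (21 items, four-point
scale 0–3, pre-assigned to the Stress / Anxiety / Depression subscales).

In the network view, symptoms are nodes and the edges are the associations
that remain between two symptoms after conditioning on all others. The
questions this package answers for a respondent × item matrix are the ones
symptom-network studies ask: which symptoms are most central, which ones
bridge the subscales (candidate routes by which one disorder activates
another), how much of each symptom the network itself explains, and whether
any of those conclusions survive resampling.

It is a library first (importable API plus `examples/` scripts), with a thin
`symptomnet` command-line wrapper for running the full pipeline on a CSV.

## Model and pipeline

1. **Nonparanormal transform.** Each ordinal item is mapped through its
   Winsorized empirical CDF and the standard-normal quantile function
   (truncation level `δ_n = 1/(4 n^{1/4} √(π log n))`); ties share average
   ranks, so the transform is invariant to monotone recoding.
2. **Gaussian graphical model.** On the Pearson correlations `R` of the
   transformed items, the sparse precision matrix solves the graphical
   lasso,

   `max_K  log det K − tr(RK) − λ Σ_{i≠j} |K_ij|`,

   along a descending 100-point log-spaced λ path. The penalty is chosen by
   the Extended Bayesian Information Criterion,
   `EBIC = −2ℓ + E log n + 4 E γ log p` with `γ = 0.50` by default, ties
   going to the sparser model. Edge weights are the partial correlations
   `w_ij = −K_ij / √(K_ii K_jj)`.
3. **Centrality.** Strength `s_i = Σ_j |w_ij|`; bridge strength restricts
   the sum to edges leaving item *i*'s subscale; bridge betweenness counts
   (fractionally, over ties) how often a node sits on shortest paths between
   nodes of different subscales, with edge length `1/|w|`. All indices are
   also reported as z-scores.
4. **Predictability.** Per node, the share of variance explained by all
   other nodes: an EBIC-selected (γ = 0.25) lasso regression with an
   unpenalized refit on the selected neighbours, `R² = 1 − RSS/TSS`.
5. **Stability.** A case-dropping bootstrap re-runs the *whole* pipeline on
   subsamples with 5%–75% of respondents removed. The CS-coefficient is the
   largest drop share at which the subsample index still correlates ≥ 0.7
   with the full-sample index with 95% probability (< 0.25 insufficient,
   \> 0.50 preferred).

Because survey data of this kind is typically available only on request, the
package ships a synthetic generator (`make_truth`, `sample_ordinal`) that
draws four-point items from a latent Gaussian copula with a known sparse,
block-structured partial-correlation network (3 × 7 communities, a few
cross-community bridges, right-skewed endorsement), so every stage can be
validated against ground truth.

## Worked example

`python examples/01_simulate_and_estimate.py`:

```
true network: 24 edges (3 communities x 7 items, 2 bridges per community pair)
estimated network: 17 edges at penalty lambda = 0.164 (EBIC-selected)
edge sensitivity  0.58   (share of true edges recovered)
edge specificity  0.98   (share of absent pairs kept absent)
strength rank corr 0.85   (ordering of node importance preserved)
```

At a survey-sized n = 318 with weak true edges (partial correlations
0.15–0.25) the regularized estimate is deliberately conservative: it keeps
98% of absent pairs absent, finds 58% of the true edges, and still preserves
the ordering of node importance (rank correlation 0.85). At n = 2000 the
same pipeline recovers essentially all edges (see
`tests/test_acceptance.py`). The other examples cover centrality and
bridges, predictability, bootstrap stability and descriptive sample tables.

The same pipeline runs from the shell:

```sh
symptomnet simulate --n 318 --seed 1 --out responses.csv
symptomnet all --input responses.csv --boots 250 --out run/
```

writing `edges.csv`, `node_metrics.csv`, `stability.csv` and `summary.json`.

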