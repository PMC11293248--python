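# dnbtip

Dynamic network biomarker (DNB) analysis of time-course gene expression:
detect the tipping point of a slowly driven biological system — the
motivating case is carcinogen-induced hepatocarcinogenesis in mice sampled
monthly, where a cirrhotic liver transitions abruptly to carcinoma — rank
the genes of the critical module, and characterise the correlation subnet
around a focal gene near the transition.

DNB theory holds that just before a critical transition a *dominant group*
of genes appears with (1) sharply increased standard deviations SD_i,
(2) sharply increased within-group absolute Pearson correlation PCC_i, and
(3) decreased correlation PCC_o to all other genes.  The package combines
these into the criticality index

```
CI(t) = SD_i(t) · PCC_i(t) / (PCC_o(t) + ε)
```

and reports the month at which the best group's CI peaks as the tipping
point, with a permutation p-value.  Downstream stages screen differentially
expressed genes (one-way ANOVA / Welch tests with Benjamini–Hochberg
control), soft-cluster temporal profiles into expression patterns (fuzzy
c-means), rank the detected module genes by four prioritization criteria
(DEG-neighbor ratio in a gene network, pathway-membership count, DEG
status, cluster membership), and quantify correlation-weight proportions
around the tipping months for a focal gene.  A synthetic-data generator
plants a known transition so the whole chain is testable end to end; see
`docs/methods.md` for the model, parameter defaults and limitations.

The intended users are computational biologists with replicated
time-course expression (T time points × r replicates, genes × samples TSV)
who want an early-warning analysis rather than ordinary differential
expression.

## Worked example

Simulate the default study conditions (500 genes, a 10-gene module, 8
months × 4 mice, tipping planted at month 6) and analyse them in one step:

```
$ dnbtip selftest --seed 11 --out selftest_out
{"tipping": 6, "permutation_p": 0.01,
 "recovery": {"tipping_hit": true, "dnb_jaccard": 0.6428571428571429, "top_gene_rank": 6}}
```

The detected tipping month is 6, matching the planted transition, with
permutation p = 0.01 (99 label shuffles).  The recovery block compares
the detected module with the planted truth: Jaccard overlap 0.64, and the
planted core gene landed at rank 6 of the priority table in this draw —
with four replicates per month the criteria are noisy (see the limitations
section of `docs/methods.md`).  The per-month CI table written to
`selftest_out/ci_series.tsv` shows the peak:

```
t  N   SD_i   PCC_i  PCC_o  CI
2  6   1.311  0.797  0.490  2.126
3  6   1.251  0.574  0.497  1.442
4  6   1.745  0.804  0.505  2.774
5  7   1.544  0.729  0.518  2.169
6  13  2.414  0.899  0.494  4.389   <- tipping
7  6   1.411  0.934  0.501  2.623
8  5   1.394  0.566  0.502  1.570
```

At month 6 the selected group is larger (N = 13), its mean SD roughly
doubles and its internal correlation rises to 0.9 while the correlation to
the background stays at the small-sample noise floor — the CI peak that
marks the critical state.

The same stages are available separately (`dnbtip simulate`, `dnbtip deg`,
`dnbtip dnb`, `dnbtip prioritize`, `dnbtip subnet`, `dnbtip metrics auc`)
or from one YAML config via `dnbtip run --config cfg.yaml`; every stage is
also an importable function (`dnbtip.dnb_core.scan_time_points`, ...).

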