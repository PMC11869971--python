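# brcaclass

Dual-framework classification of germline *BRCA1*/*BRCA2* variants: a standard
ACMG/AMP + SVI rule engine and an ENIGMA *BRCA1*/*BRCA2* VCEP (v1.1.0) rule
engine run over the same annotated variant records, combined through the
Bayesian point system, with cohort-level accounting of class transitions and
per-code deltas between the two reanalyses.

## The problem

Variants of uncertain significance (VUS) dominate the output of diagnostic
*BRCA1*/*BRCA2* sequencing.  Two complementary routes can resolve them:
reassessment with new annotation data under the generic ACMG/AMP system
(with current ClinGen SVI recommendations), or gene-specific expert-panel
specifications that redefine which evidence codes apply and at what strength.
This package implements both rule sets as deterministic engines over the same
inputs so the contribution of the *specifications themselves* — as opposed to
new data — can be isolated and audited, variant by variant and code by code.

Intended users are clinical-genetics analysts and method developers who want
a reproducible, table-driven implementation of both frameworks, not a
replacement for expert curation.

## The model

Each applied evidence code carries a strength mapped to exponentially
doubling points:

    supporting = 1, moderate = 2, strong = 4, very strong = 8
    (benign codes contribute negatively)

The signed sum over all applied codes — conflicting evidence is summed, never
short-circuited — maps to the five-tier class:

| points  | ≥ 10 | 6 … 9 | VUS band | LB band | ≤ −7 |
|---------|------|-------|----------|---------|------|
| standard | P   | LP    | 0 … 5    | −6 … −1 | B    |
| ENIGMA   | P   | LP    | −1 … 5   | −6 … −2 | B    |

The single boundary difference — likely benign from −1 (standard) versus −2
(ENIGMA) — is load-bearing: a lone supporting benign code (−1) is LB under
one framework and VUS under the other.

Key gene-specific rules in the ENIGMA engine: `BP1_STR` (−4) for missense
variants outside the clinically important domains (enough for LB on its own,
and still LB at −3 with `PM2_SUP`); `PM2_SUP` only for variants absent from
*both* gnomAD noncancer data sets; BayesDel-based `PP3`/`BP4` only for
missense variants *inside* domains, benign arm capped at supporting; SpliceAI
bands for splicing codes; `PS3`/`BS3`, `PM5_PTC`, PVS1 decision-tree
outcomes, `PP4`/`BP5` multifactorial-likelihood bands and `PP1`/`BS4`
cosegregation bands, all as table lookups.  The standard engine uses the
REVEL interval calibration (strengths beyond supporting in both directions),
allele-count ≤ 5 for `PM2_SUP`, proband counting (≥ 5) for `PS4_SUP`, and
`BP7`+`BP4` for synonymous/intronic variants without predicted splice impact.

All numeric cutoffs live in a shipped YAML
(`src/brcaclass/data/default_config.yaml`) and can be overridden per run.

## Worked example

Generate a seeded synthetic cohort shaped like a diagnostic VUS set
(121 variants: 40 *BRCA1*, 81 *BRCA2*), classify it under both frameworks,
and build the comparison:

```sh
brcaclass simulate --seed 1 --out-dir demo/sim
brcaclass classify --framework both \
    --cohort demo/sim/cohort.tsv --tables demo/sim/tables --out demo/out
```

`report_enigma.tsv` starts:

```
variant_id  framework  codes            total_points  classification
SYN0001     enigma     BP1_STR          -4            LB
SYN0002     enigma     BP1_STR,PM2_SUP  -3            LB
SYN0003     enigma     BP1_STR          -4            LB
```

`summary.json` reports, for this seed, 51/121 LB (42.1%) at t2 (standard
engine) versus 93/121 LB or B (66.9% + 9.9%) at t3 (ENIGMA engine): the
gene-specific specifications, on identical data, resolve far more VUS, and
`code_deltas.tsv` shows why:

```
code      step    added  removed
BP1_STR   t2->t3  93     0
BS3_STR   t2->t3  10     0
PM2_SUP   t2->t3  0      45
PS4_SUP   t2->t3  0      20
```

93 variants gain `BP1_STR`; `PM2_SUP` is withdrawn from 45 variants by the
stricter absence requirement, and `PS4_SUP` from 20 because proband counting
is not part of the ENIGMA rule set.  The per-variant JSON reports carry the
rationale for every assigned code and a log of rules skipped for unknown
annotations.

The generator also emits `ground_truth.json`, the ledger of codes each engine
is expected to assign per record — the engines must reproduce it exactly,
which the test suite verifies.

## Scope

The engines consume REVEL/BayesDel/SpliceAI scores, reviewed assay verdicts
and combined likelihood ratios as annotations; computing those scores, HGVS
to genome mapping, and re-derivation of the PVS1 decision trees are out of
scope.  Baseline (t1) classes are consumed as given labels.
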