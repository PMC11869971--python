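# Methods

## Evidence combination

Both engines share one point scale: supporting/moderate/strong/very-strong
evidence maps to 1/2/4/8 points, benign codes negated, and the report total
is the plain arithmetic sum over all applied codes.  Conflicting evidence is
always summed, never short-circuited; a duplicate base code within one
framework is an error (at most one assignment per code per variant).  The
five-tier class is a pure function of the total and the framework's boundary
table: P ≥ 10, LP 6…9, B ≤ −7 in both frameworks; likely benign spans
−6…−1 under the standard boundaries and −6…−2 under ENIGMA, so VUS covers
0…5 and −1…5 respectively.  The two printed likely-benign boundaries are
primary; the P/LP/B cutpoints follow the point-band scheme the boundaries
derive from and are declared in `data/default_config.yaml` so they can be
corrected against the specification tables without a code change.  Only the
integer point system is implemented; no posterior-probability output.

## Rule sets

**Standard (ACMG/AMP + SVI).**  `PM2_SUP` for gnomAD noncancer v2.1.1
allele count ≤ 5 (the ceiling is set one below the most frequently described
pathogenic missense variant, at allele count 6).  `PS4_SUP` for ≥ 5 described
breast/ovarian-cancer probands, withheld when the variant is flagged as too
frequent in population databases — the flag is an explicit curated
annotation, not a frequency computation, since no numeric rule exists for
it.  `PP3`/`BP4` for missense variants from the REVEL interval calibration
with strengths beyond supporting in both directions (first-match threshold
list in config).  Synonymous/intronic variants with no predicted splice
impact (curated flag, or SpliceAI ≤ 0.10) receive `BP7_SUP` together with
`BP4_SUP` as computational no-impact evidence; this pairing is what lets an
intronic variant reach −2 (LB) under the standard arm while the ENIGMA arm,
which has no BP7, stops at −1 (VUS).  `BP5_SUP` for any recorded in-trans
observation with a pathogenic variant, including the BRCA1 + BRCA2 pair
scenario.  The engine deliberately never emits the gene-specific codes
(BP1, PM5, PVS1-tree outcomes, PP4, PP1/BS4, PS3/BS3): in this design the
standard arm carries no functional codes, which reflects how the reanalysis
it models was operationalized and keeps the two alphabets cleanly separable
in the delta accounting.

**ENIGMA VCEP.**  `BP1_STR` for missense variants outside every
(potentially) clinically important domain.  BP1 is additionally withheld
when SpliceAI flags the variant (≥ 0.20): a missense change acting through
splicing is outside the missense-outside-domain argument — without this gate
the flagged-missense discordant case could not return to VUS.  An unknown
SpliceAI score does not withhold BP1 (no prediction contradicts it).
`PM2_SUP` only when the variant is absent from both gnomAD noncancer v2.1.1
and v3.1.2.  Computational evidence emits at most one code with splicing
precedence: SpliceAI ≥ 0.20 → `PP3_SUP` (splicing); otherwise, for missense
inside domains, BayesDel bands (≥ 0.30 → `PP3_SUP`, ≤ 0.15 → `BP4_SUP`,
benign arm capped at supporting by construction and validated at config
load); otherwise, for synonymous/intronic variants, SpliceAI ≤ 0.10 →
`BP4_SUP`.  Missense variants outside domains never receive a BayesDel code;
BP1 carries the benign signal there, which also makes BP1 and in-domain BP4
mutually exclusive on any record.  `PS3`/`BS3`, `PM5_PTC` exon weights and
PVS1 decision-tree outcomes are pure lookups against the packaged miniature
tables (direct per-record annotations win over the table, logged on
conflict); `PP4`/`BP5` and `PP1`/`BS4` come from likelihood-ratio bands.
BP7 is absent from the ENIGMA alphabet.

**Observation-based BP5.**  The narrative around the pair-scenario case
admits two readings: either the ENIGMA arm granted the same −1 through BP5
and the class difference is purely the boundary, or it withheld BP5
entirely.  The default policy (`bp5_cooccurrence_policy: withhold_all`)
never grants observation-based BP5 — cooccurrence information enters only
through the combined multifactorial LR, which integrates it with segregation
and pathology data.  The hand-encoded case 1 therefore carries a combined LR
in the weakest benign band: both engines total −1 (standard via the
observation, ENIGMA via the LR band) and the classes diverge on the
boundary, consistent with both statements.  `withhold_pair` and `allow` are
available for laboratories that grant observational BP5.

## Numeric cutoffs and provenance

The REVEL interval table (0.644/0.773/0.932 pathogenic; 0.290/0.183/0.016/
0.003 benign), the BayesDel and SpliceAI cutoffs, and the LR→strength bands
(2.08/4.3/18.7/350 and their reciprocals 0.48/0.23/0.053/0.00285) are
transcribed from the published calibrations into the default config; they
are data, not code, and every engine test is table-relative, so a corrected
transcription changes results without touching the engines.  Band tables are
validated at load: `ge` thresholds strictly decreasing, `le` strictly
increasing, benign and pathogenic zones disjoint; scores matching no band
are uninformative.  Scores are validated to their declared ranges (REVEL and
SpliceAI in [0, 1], LRs > 0, allele counts non-negative integers).  Unknown
(`None`) is distinct from zero/false everywhere; an unknown annotation skips
its rule and is logged as not-evaluated, never treated as evidence.

## Synthetic cohorts

The generator emulates the evidence structure of a diagnostic VUS cohort,
not its sequence content: mutational spectra, haplotypes and population
genetics are out of scope, and HGVS strings are syntactically valid but
positionally arbitrary within the transcript.  Defaults are the study
conditions: 121 variants (40 *BRCA1*, 81 *BRCA2*) partitioned into four
archetypes — 93 missense outside domains, 10 in-domain *BRCA2* missense with
benign BayesDel, 12 intronic with negative splice prediction, 6
splice-flagged missense — with overlays of 10 benign functional verdicts and
12 benign multifactorial LRs (1 very strong, 1 strong, 4 moderate, 6
supporting) planted on the missense-outside group, 20 variants absent from
both gnomAD sets, 45 at low (1–5) v2.1.1 counts, and 20 with ≥ 5 probands.
All planting is by exact count (shuffle-then-slice under a single seeded
generator), so aggregate expectations are exact rather than binomial;
annotation values are drawn strictly inside the intended band.  Each record
gets a ground-truth ledger entry listing the tokens each engine must assign,
derived from the planted choices by the generator's own bookkeeping; the
test suite re-evaluates every record through the engines and requires exact
agreement.  Synthetic domain intervals mirror the real architecture (BRCA1
RING and BRCT regions, BRCA2 C-terminal DNA-binding domain) and are labelled
synthetic stand-ins.  Because the per-variant joint distribution of evidence
in a real cohort is richer than four archetypes plus independent overlays,
passing cohort-level tests demonstrates the engines' and accounting's
correctness on the planted structure, not calibration against any real
patient series; the real cohort's per-patient appendix is not reproduced.

The three discordant cases are hand-encoded from their printed variant
descriptions and narrative evidence profiles and bypass the random
machinery entirely.

## Determinism and I/O

All randomness flows through one `numpy` Generator seeded from the cohort
spec; identical spec + seed is byte-identical output.  Writers emit stable
column orders with a trailing newline and write atomically (temp file +
rename).  Every CLI run serializes its effective configuration and a
provenance block (config SHA-256, resource-table checksums, specification
version label) next to the outputs.  TSV is the canonical dialect; the
minimal-VCF reader maps only the documented INFO keys and treats CHROM/POS
as passthrough.  Percentages in summaries are rounded half-away-from-zero to
one decimal; raw counts are always retained.

## Problem sizes

Default test and acceptance runs use the 121-variant cohort, exhaustive
enumeration of all 794 assignment sets of size ≤ 4 over a 12-code alphabet
for the point-arithmetic oracle, and boundary scans over the ±20-point
range; the full suite completes in a few seconds.

## Known limitations

- The standard arm's t1 (original, heterogeneous) classifications are
  consumed as labels; no 2015-era engine is implemented.
- PVS1 and PM5_PTC are table lookups; the decision trees themselves are not
  re-derived, and PTC-type variants do not appear in the default synthetic
  cohort (a diagnostic VUS set rarely retains unresolved truncating
  variants); they are covered by fixture-table unit tests.
- Whether the standard arm should ever carry PS3/BS3 is an open
  interpretation; this implementation excludes functional codes from the
  standard alphabet.
- BayesDel cutoffs apply only inside domains; no calibration is attempted
  for out-of-domain missense predictions.
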