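# Default configuration: point/boundary tables and threshold tables for both
# rule engines.  All numeric cutoffs live here, not in code, so they can be
# corrected against the source calibration documents without a code change.
#
# Threshold-band schema: an ordered list of {op, threshold, code, strength}
# entries evaluated first-match.  "ge" entries (score >= threshold) must be
# listed with strictly decreasing thresholds, "le" entries (score <= threshold)
# with strictly increasing thresholds, and every "le" threshold must lie below
# every "ge" threshold; scores matching no entry are uninformative (no code).

spec_version_label: "ENIGMA v1.1.0"

point_scale:
  # Lower-inclusive cutoffs; below lb_min is B.  The two frameworks differ
  # only in where likely benign begins: -1 (standard) vs -2 (ENIGMA).
  boundaries:
    standard: {p_min: 10, lp_min: 6, vus_min: 0, lb_min: -6}
    enigma: {p_min: 10, lp_min: 6, vus_min: -1, lb_min: -6}

standard:
  pm2_max_allele_count: 5       # gnomAD noncancer v2.1.1 allele count ceiling
  ps4_min_probands: 5           # described breast/ovarian-cancer probands
  bp7_enabled: true
  splice_negative_max: 0.10     # SpliceAI max score treated as "no splice impact"
  # REVEL calibration with strengths beyond supporting in both directions
  # (published interval calibration of missense meta-predictors).
  revel_bands:
    - {op: ge, threshold: 0.932, code: PP3, strength: STR}
    - {op: ge, threshold: 0.773, code: PP3, strength: MOD}
    - {op: ge, threshold: 0.644, code: PP3, strength: SUP}
    - {op: le, threshold: 0.003, code: BP4, strength: VSTR}
    - {op: le, threshold: 0.016, code: BP4, strength: STR}
    - {op: le, threshold: 0.183, code: BP4, strength: MOD}
    - {op: le, threshold: 0.290, code: BP4, strength: SUP}

enigma:
  # SpliceAI cutoffs: flagging (PP3 for splicing) and negative (BP4) zones.
  spliceai_pp3_min: 0.20
  spliceai_bp4_max: 0.10
  # BayesDel cutoffs for missense variants inside clinically important
  # domains; the benign arm is restricted to supporting strength.
  bayesdel_bands:
    - {op: ge, threshold: 0.30, code: PP3, strength: SUP}
    - {op: le, threshold: 0.15, code: BP4, strength: SUP}
  # Combined multifactorial likelihood-ratio bands -> PP4 / BP5, exponential
  # strength scale away from LR = 1.
  lr_bands_pp4_bp5:
    - {op: ge, threshold: 350.0, code: PP4, strength: VSTR}
    - {op: ge, threshold: 18.7, code: PP4, strength: STR}
    - {op: ge, threshold: 4.3, code: PP4, strength: MOD}
    - {op: ge, threshold: 2.08, code: PP4, strength: SUP}
    - {op: le, threshold: 0.00285, code: BP5, strength: VSTR}
    - {op: le, threshold: 0.053, code: BP5, strength: STR}
    - {op: le, threshold: 0.23, code: BP5, strength: MOD}
    - {op: le, threshold: 0.48, code: BP5, strength: SUP}
  # Cosegregation likelihood-ratio bands -> PP1 / BS4 (same exponential scale).
  lr_bands_pp1_bs4:
    - {op: ge, threshold: 350.0, code: PP1, strength: VSTR}
    - {op: ge, threshold: 18.7, code: PP1, strength: STR}
    - {op: ge, threshold: 4.3, code: PP1, strength: MOD}
    - {op: ge, threshold: 2.08, code: PP1, strength: SUP}
    - {op: le, threshold: 0.00285, code: BS4, strength: VSTR}
    - {op: le, threshold: 0.053, code: BS4, strength: STR}
    - {op: le, threshold: 0.23, code: BS4, strength: MOD}
    - {op: le, threshold: 0.48, code: BS4, strength: SUP}
  # BP5 from a cooccurrence observation (as opposed to the LR bands above):
  # withhold_all (default) never grants observation-based BP5 — the
  # cooccurrence signal enters only through the combined multifactorial LR;
  # withhold_pair grants it except for the BRCA1+BRCA2 pathogenic pair
  # scenario; allow grants BP5_SUP for any in-trans pathogenic observation.
  bp5_cooccurrence_policy: withhold_all
  # When SpliceAI flags a variant and a missense BayesDel code would also
  # fire, the splicing PP3 takes precedence (at most one computational code).
  splice_pp3_precedence: true
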