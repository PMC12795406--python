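# Verb-final archetype with optional accusative-like case on P, flexible
# order and frequent A-omission (PV is the most common surface pattern).
name: verb_final_case
lexicon_sizes: {noun: 48, verb: 12, pronoun: 5, function: 6}
zipf_exponent: 1.0
order_distribution: {APV: 0.60, PAV: 0.08, AVP: 0.12, PVA: 0.05, VAP: 0.08, VPA: 0.07}
omission_prob: {A: 0.40, P: 0.13}
marking:
  kind: case_suffix
  case_markers: {P: "yu"}
  case_marker_prob: {P: 0.80}
pronoun_prob_by_role:
  A: {prob: 0.40, dist: {1SG: 0.45, 2SG: 0.30, OTHER: 0.25}}
  P: {prob: 0.12, dist: {1SG: 0.15, 2SG: 0.20, OTHER: 0.65}}
length_noise: {dist: poisson, mean: 0.4}
verb_noun_association: 0.5
n_verb_classes: 6
adu_length_scale: 3.0
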