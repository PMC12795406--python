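# Learnability preset: both roles always carry a unique case-marker token,
# so marker -> role is a deterministic function regardless of order.
name: deterministic_cue
lexicon_sizes: {noun: 48, verb: 12, pronoun: 4, function: 6}
zipf_exponent: 1.0
order_distribution: {APV: 0.25, AVP: 0.20, PAV: 0.15, PVA: 0.15, VAP: 0.15, VPA: 0.10}
omission_prob: {A: 0.20, P: 0.20}
marking:
  kind: case_suffix
  case_markers: {A: "ko", P: "su"}
  case_marker_prob: {A: 1.0, P: 1.0}
pronoun_prob_by_role:
  A: {prob: 0.30, dist: {1SG: 0.40, 2SG: 0.30, OTHER: 0.30}}
  P: {prob: 0.10, dist: {1SG: 0.15, 2SG: 0.20, OTHER: 0.65}}
length_noise: {dist: poisson, mean: 0.3}
verb_noun_association: 0.3
n_verb_classes: 6
adu_length_scale: 3.0
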