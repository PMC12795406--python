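# Verb-initial archetype with symmetrical voice marking on the verb and
# phrase markers on arguments; patient voice dominant, A-initial bias
# stronger in the patient voice; heavy A-pronoun skew.
name: verb_initial_voice
lexicon_sizes: {noun: 48, verb: 12, pronoun: 5, function: 6}
zipf_exponent: 1.0
order_distribution: null
omission_prob: {A: 0.10, P: 0.35}
marking:
  kind: voice_affix
  voices:
    av: {affix: "um", prominent: A}
    pv: {affix: "in", prominent: P}
  prominent_marker: "ang"
  nonprominent_marker: "ng"
voice_distribution: {av: 0.40, pv: 0.60}
order_by_voice:
  av: {VAP: 0.45, VPA: 0.15, AVP: 0.25, APV: 0.05, PVA: 0.05, PAV: 0.05}
  pv: {VAP: 0.40, VPA: 0.10, AVP: 0.35, APV: 0.05, PVA: 0.05, PAV: 0.05}
pronoun_prob_by_role:
  A: {prob: 0.70, dist: {1SG: 0.40, 2SG: 0.45, OTHER: 0.15}}
  P: {prob: 0.15, dist: {1SG: 0.10, 2SG: 0.20, OTHER: 0.70}}
length_noise: {dist: poisson, mean: 0.4}
verb_noun_association: 0.5
n_verb_classes: 6
adu_length_scale: 3.0
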