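# Verb-medial archetype with rigid order and no nominal marking; a rare
# passive-like voice fronts the patient and marks the verb with an affix.
name: verb_medial_rigid
lexicon_sizes: {noun: 48, verb: 12, pronoun: 5, function: 6}
zipf_exponent: 1.0
order_distribution: null
omission_prob: {A: 0.08, P: 0.35}
marking:
  kind: voice_affix
  voices:
    active: {affix: "", prominent: A}
    passive: {affix: "bep", prominent: P}
  prominent_marker: null
  nonprominent_marker: null
voice_distribution: {active: 0.92, passive: 0.08}
order_by_voice:
  active: {AVP: 0.80, PAV: 0.12, APV: 0.04, VAP: 0.04}
  passive: {PVA: 1.0}
pronoun_prob_by_role:
  A: {prob: 0.60, dist: {1SG: 0.40, 2SG: 0.40, OTHER: 0.20}}
  P: {prob: 0.20, dist: {1SG: 0.10, 2SG: 0.20, OTHER: 0.70}}
length_noise: {dist: poisson, mean: 0.4}
verb_noun_association: 0.5
n_verb_classes: 6
adu_length_scale: 3.0
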