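# Emergence preset: 75% A-initial actives (AVP) vs 25% patient-initial
# passive analogs (PVA) cued only by a verbal affix; arguments are bare
# nouns with no role-informative lexical statistics, so the initial
# argument is cue-ambiguous until the verb arrives.  The passive affix is
# optional (as passive cues are probabilistic in natural input), which
# forces the learner to fall back on the A-dominant base rate whenever no
# passive cue has been observed — the substrate of the agent preference.
name: agent_preference
lexicon_sizes: {noun: 40, verb: 10, pronoun: 3, function: 6}
zipf_exponent: 0.6
order_distribution: null
omission_prob: {A: 0.03, P: 0.40}
marking:
  kind: voice_affix
  voices:
    active: {affix: "", prominent: A}
    passive: {affix: "bek", prominent: P, affix_prob: 0.7}
  prominent_marker: null
  nonprominent_marker: null
voice_distribution: {active: 0.75, passive: 0.25}
order_by_voice:
  active: {AVP: 1.0}
  passive: {PVA: 1.0}
pronoun_prob_by_role:
  A: {prob: 0.0, dist: {OTHER: 1.0}}
  P: {prob: 0.0, dist: {OTHER: 1.0}}
length_noise: {dist: poisson, mean: 1.2}
verb_noun_association: 0.0
n_verb_classes: 4
adu_length_scale: 2.0
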