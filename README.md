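# rolepred

Incremental semantic-role predictability: how early, and on what contextual
evidence, can the agent (A) and patient (P) roles of a clause be predicted?

The package provides the full analysis stack:

1. **`rolepred.corpus`** — data model for annotated utterances (tokens, verb
   span, up to two role-labeled argument spans, verb class, language tag),
   JSONL/TSV readers/writers with strict validation, and descriptive
   statistics (surface word-order patterns, Shannon order entropy, role
   proportions, 1st/2nd-person pronoun rates by role).
2. **`rolepred.synth`** — seeded generators for artificial-language corpora.
   A `LanguageSpec` fixes a Zipfian lexicon, a distribution over A/P/V
   orders, per-role argument omission, a marking system (case suffixes or
   verbal voice affixes with phrase markers), role-conditioned pronoun usage
   and adjunct noise. Five presets ship with the package: three typological
   archetypes (verb-initial + voice, verb-medial + rigid order, verb-final +
   case + frequent A-omission), an agent-preference emergence preset, and a
   deterministic-cue learnability preset. Factorial experimental stimuli
   (`StimulusDesign`) and unannotated pretraining text are generated from
   the same grammar.
3. **`rolepred.model`** — the incremental role prediction model: token
   embedding (seeded hashing / character CNN / external word vectors), an
   LSTM *sequential encoder* that reduces multi-token arguments to one
   element, an LSTM *sentence processor*, a role classifier that
   (re)classifies every already-seen argument at every time point, and a
   next-word predictor. Training is two-stage (next-word pretraining, then
   joint training with the role error at the final sentence position), with
   a 10-fold cross-validation harness that returns each utterance's
   trajectory from the fold where it was held out. Everything runs on a
   small self-contained numpy autodiff engine — no GPU or deep-learning
   framework required.
4. **`rolepred.predictability`** — converts trajectories into
   position-conditioned records: one row per argument per informative event
   (own occurrence, other argument, verb) with `after_argument`/`after_verb`
   flags, plus the proportional baseline and the stimulus final-position
   path.
5. **`rolepred.bayes`** — hierarchical Bayesian beta regression of
   P(correct role) on position, role, language and covariates: treatment-
   coded design construction, a self-contained NUTS sampler (numba-
   accelerated likelihood kernel), convergence gates (split R-hat < 1.01,
   bulk/tail ESS > 400), posterior cell means with 66%/95% intervals,
   pairwise language contrasts, PSIS-LOO model comparison with stacking
   weights (via ArviZ), and stimulus-condition regressions.
6. **`rolepred.pipeline` / CLI** — YAML-driven end-to-end orchestration with
   content-hashed manifests.

## CLI

```bash
rolepred generate verb_final_case -n 2000 --seed 1 -o verbfinal.jsonl --adu-words 20000
rolepred pretrain verbfinal.jsonl.adu.txt -o pre.npz --seed 1
rolepred train verbfinal.jsonl --checkpoint pre.npz -o model.npz --seed 1
rolepred cv verbfinal.jsonl -k 10 --checkpoint pre.npz -o records.tsv
rolepred extract stimuli.jsonl model.npz -o stim_records.tsv --final-only
rolepred regress records.tsv -o fit --chains 4 --draws 1000
rolepred run-all -c pipeline.yaml
```

A minimal pipeline config:

```yaml
presets: [verb_initial_voice, verb_medial_rigid, verb_final_case]
out_dir: artifacts
n_cdu: 2000
n_adu_words: 20000
k_folds: 10
seed: 1
regression: {chains: 4, draws: 1000, warmup: 1000, group_slopes: []}
```

## Data formats

Corpora are JSONL: a header line
`{"schema": "rolepred-corpus-v1", "metadata": {...}}` followed by one
utterance per line:

```json
{"id": "u000001", "language": "verb_final_case",
 "tokens": ["hepa", "tizu", "yu", "ruka"],
 "verb": [3, 4], "verb_class": "motion",
 "arguments": [{"span": [0, 1], "role": "A", "nominality": "OTHER"},
               {"span": [1, 3], "role": "P", "nominality": "OTHER"}]}
```

Spans are 0-based half-open token-index pairs; arguments never overlap each
other or the verb span. A CoNLL-style TSV alternative (one token per row,
`# key = value` comment block per utterance) is supported by
`read_corpus(..., format="tsv")`. Predictability records are TSV with the
fixed column order `sentence_id, language, role, after_argument,
after_verb, nominality, verb_class, p_correct` plus optional `cond_*`
columns for stimulus conditions.
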