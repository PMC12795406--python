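"""Seeded generators for artificial-language corpora and stimuli.

A :class:`LanguageSpec` describes a small generative grammar: a Zipfian
lexicon, a distribution over full A/P/V orders, per-role omission
probabilities, a marking system (none, case suffixes, or verbal voice
affixes with phrase markers), role-conditioned pronoun usage and adjunct
length noise.  From a spec the module fabricates:

* annotated child-directed-style corpora (:func:`generate_cdu_corpus`),
* unannotated pretraining text (:func:`generate_adu_text`),
* factorial experimental stimuli (:func:`generate_stimuli`).

All outputs are pure functions of ``(spec, n, seed)``.  Corpus generation
logs every latent draw (full order before omission, voice, omission
outcomes) so tests can use the log as an exact oracle.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus import (
    AnnotatedUtterance,
    ArgumentSpan,
    Corpus,
    DEFAULT_VERB_CLASSES,
    Nominality,
    Role,
)

__all__ = [
    "LanguageSpec",
    "Marking",
    "VoiceSpec",
    "StimulusDesign",
    "Lexicon",
    "generate_lexicon",
    "generate_cdu_corpus",
    "generate_adu_text",
    "generate_stimuli",
    "load_preset",
    "preset_path",
    "PRESET_NAMES",
]

_FULL_PATTERNS = {"".join(p) for p in itertools.permutations("APV")}

PRESET_NAMES = (
    "verb_initial_voice",
    "verb_medial_rigid",
    "verb_final_case",
    "agent_preference",
    "deterministic_cue",
)


class SpecError(ValueError):
    pass


def _check_dist(d: Mapping[str, float], what: str, tol: float = 1e-8) -> None:
    if not d:
        raise SpecError(f"{what}: empty distribution")
    if any(v < 0 for v in d.values()):
        raise SpecError(f"{what}: negative probability")
    if abs(sum(d.values()) - 1.0) > tol:
        raise SpecError(f"{what}: probabilities sum to {sum(d.values())}, not 1")


@dataclass
class VoiceSpec:
    affix: str          # verbal affix token; empty string = unmarked voice
    prominent: str      # which role ("A"/"P") the prominent phrase marker attaches to
    affix_prob: float = 1.0  # probability the affix is overt (optional marking)


@dataclass
class Marking:
    kind: str = "none"  # none | case_suffix | voice_affix
    case_markers: dict[str, str] = field(default_factory=dict)
    case_marker_prob: dict[str, float] = field(default_factory=dict)
    voices: dict[str, VoiceSpec] = field(default_factory=dict)
    prominent_marker: str | None = None
    nonprominent_marker: str | None = None

    def marker_strings(self) -> list[str]:
        out = list(self.case_markers.values())
        out += [v.affix for v in self.voices.values() if v.affix]
        if self.prominent_marker:
            out.append(self.prominent_marker)
        if self.nonprominent_marker:
            out.append(self.nonprominent_marker)
        return out


@dataclass
class LanguageSpec:
    name: str
    lexicon_sizes: dict[str, int]
    zipf_exponent: float
    order_distribution: dict[str, float] | None
    omission_prob: dict[str, float]
    marking: Marking
    pronoun_prob_by_role: dict[str, dict]
    length_noise: dict = field(default_factory=lambda: {"dist": "poisson", "mean": 0.5})
    voice_distribution: dict[str, float] | None = None
    order_by_voice: dict[str, dict[str, float]] | None = None
    verb_noun_association: float = 0.0
    n_verb_classes: int = 6
    adu_length_scale: float = 3.0

    def __post_init__(self):
        for cat in ("noun", "verb", "pronoun", "function"):
            if self.lexicon_sizes.get(cat, 0) < 1:
                raise SpecError(f"lexicon size for {cat!r} must be >= 1")
        if self.zipf_exponent < 0:
            raise SpecError("zipf_exponent must be >= 0")
        if self.marking.kind == "voice_affix":
            if not self.voice_distribution or not self.marking.voices:
                raise SpecError("voice_affix marking requires voices and voice_distribution")
            _check_dist(self.voice_distribution, "voice_distribution")
            if set(self.voice_distribution) != set(self.marking.voices):
                raise SpecError("voice_distribution keys must match marking.voices")
            orders = self.order_by_voice or {}
            if set(orders) != set(self.marking.voices):
                raise SpecError("order_by_voice must cover every voice")
            for v, d in orders.items():
                self._check_orders(d, f"order_by_voice[{v}]")
        else:
            if self.order_distribution is None:
                raise SpecError("order_distribution required without voice marking")
            self._check_orders(self.order_distribution, "order_distribution")
        for role in ("A", "P"):
            p = self.omission_prob.get(role, 0.0)
            if not (0.0 <= p <= 1.0):
                raise SpecError(f"omission_prob[{role}] out of [0, 1]")
            pr = self.pronoun_prob_by_role.get(role)
            if pr is None:
                raise SpecError(f"pronoun_prob_by_role missing role {role}")
            if not (0.0 <= pr["prob"] <= 1.0):
                raise SpecError(f"pronoun prob for {role} out of [0, 1]")
            _check_dist(pr["dist"], f"pronoun subtype dist for {role}")
            if set(pr["dist"]) - {"1SG", "2SG", "OTHER"}:
                raise SpecError("pronoun subtypes must be 1SG/2SG/OTHER")
        markers = self.marking.marker_strings()
        if len(markers) != len(set(markers)):
            raise SpecError("marker strings must be unique per role/voice")
        if not (0.0 <= self.verb_noun_association <= 1.0):
            raise SpecError("verb_noun_association out of [0, 1]")
        if not (1 <= self.n_verb_classes <= len(DEFAULT_VERB_CLASSES)):
            raise SpecError("n_verb_classes out of range")

    @staticmethod
    def _check_orders(d: Mapping[str, float], what: str) -> None:
        _check_dist(d, what)
        bad = set(d) - _FULL_PATTERNS
        if bad:
            raise SpecError(f"{what}: keys must be permutations of 'APV', got {sorted(bad)}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "lexicon_sizes": dict(self.lexicon_sizes),
            "zipf_exponent": self.zipf_exponent,
            "order_distribution": self.order_distribution,
            "omission_prob": dict(self.omission_prob),
            "marking": {
                "kind": self.marking.kind,
                "case_markers": dict(self.marking.case_markers),
                "case_marker_prob": dict(self.marking.case_marker_prob),
                "voices": {
                    k: {"affix": v.affix, "prominent": v.prominent, "affix_prob": v.affix_prob}
                    for k, v in self.marking.voices.items()
                },
                "prominent_marker": self.marking.prominent_marker,
                "nonprominent_marker": self.marking.nonprominent_marker,
            },
            "pronoun_prob_by_role": self.pronoun_prob_by_role,
            "length_noise": dict(self.length_noise),
            "voice_distribution": self.voice_distribution,
            "order_by_voice": self.order_by_voice,
            "verb_noun_association": self.verb_noun_association,
            "n_verb_classes": self.n_verb_classes,
            "adu_length_scale": self.adu_length_scale,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LanguageSpec":
        m = d.get("marking", {}) or {}
        marking = Marking(
            kind=m.get("kind", "none"),
            case_markers=dict(m.get("case_markers") or {}),
            case_marker_prob=dict(m.get("case_marker_prob") or {}),
            voices={k: VoiceSpec(**v) for k, v in (m.get("voices") or {}).items()},
            prominent_marker=m.get("prominent_marker"),
            nonprominent_marker=m.get("nonprominent_marker"),
        )
        return cls(
            name=d["name"],
            lexicon_sizes=dict(d["lexicon_sizes"]),
            zipf_exponent=float(d["zipf_exponent"]),
            order_distribution=dict(d["order_distribution"]) if d.get("order_distribution") else None,
            omission_prob=dict(d.get("omission_prob") or {"A": 0.0, "P": 0.0}),
            marking=marking,
            pronoun_prob_by_role={k: dict(v) for k, v in d["pronoun_prob_by_role"].items()},
            length_noise=dict(d.get("length_noise") or {"dist": "poisson", "mean": 0.5}),
            voice_distribution=dict(d["voice_distribution"]) if d.get("voice_distribution") else None,
            order_by_voice={k: dict(v) for k, v in d["order_by_voice"].items()} if d.get("order_by_voice") else None,
            verb_noun_association=float(d.get("verb_noun_association", 0.0)),
            n_verb_classes=int(d.get("n_verb_classes", 6)),
            adu_length_scale=float(d.get("adu_length_scale", 3.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LanguageSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, ensure_ascii=False).encode()
        ).hexdigest()[:16]


def preset_path(name: str) -> Path:
    from importlib import resources

    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    return Path(str(resources.files("rolepred.data.presets").joinpath(f"{name}.yaml")))


def load_preset(name: str) -> LanguageSpec:
    return LanguageSpec.from_yaml(preset_path(name))


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

_CONSONANTS = "ptkbdgmnslrh"
_VOWELS = "aeiou"


@dataclass
class Lexicon:
    words: dict[str, list[str]]                  # category -> word list (rank order)
    weights: dict[str, np.ndarray]               # category -> normalized Zipf weights
    verb_class_of: list[str]                     # aligned with words["verb"]
    noun_pools: dict[tuple[str, str], np.ndarray]  # (verb_class, role) -> noun indices

    def pronoun_for(self, subtype: str, rng: np.random.Generator) -> tuple[str, Nominality]:
        prons = self.words["pronoun"]
        if subtype == "1SG":
            return prons[0], Nominality.PRON_1SG
        if subtype == "2SG":
            return prons[1 % len(prons)], Nominality.PRON_2SG
        others = prons[2:] or prons
        return others[int(rng.integers(len(others)))], Nominality.PRON_OTHER


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-s)
    return w / w.sum()


def generate_lexicon(spec: LanguageSpec, seed: int) -> Lexicon:
    """Deterministically build a lexicon of unique pseudo-words.

    Frequency weights within each category are proportional to
    ``rank ** -zipf_exponent``.  Marker strings from the spec are excluded
    from the generated word forms so cues stay unambiguous.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    reserved = set(spec.marking.marker_strings())
    used: set[str] = set(reserved)
    words: dict[str, list[str]] = {}
    for cat in ("noun", "verb", "pronoun", "function"):
        n = spec.lexicon_sizes[cat]
        out: list[str] = []
        while len(out) < n:
            k = 1 + int(rng.integers(1, 3))  # 2-3 syllables
            w = "".join(syllables[int(rng.integers(len(syllables)))] for _ in range(k))
            if w in used:
                continue
            used.add(w)
            out.append(w)
        words[cat] = out
    weights = {cat: _zipf_weights(len(ws), spec.zipf_exponent) for cat, ws in words.items()}

    classes = list(DEFAULT_VERB_CLASSES[: spec.n_verb_classes])
    verb_class_of = [classes[i % len(classes)] for i in range(len(words["verb"]))]

    # disjoint plausible-filler pools per (verb class, role): round-robin split
    noun_idx = np.arange(len(words["noun"]))
    buckets = 2 * len(classes)
    noun_pools: dict[tuple[str, str], np.ndarray] = {}
    for ci, cls_name in enumerate(classes):
        noun_pools[(cls_name, "A")] = noun_idx[noun_idx % buckets == 2 * ci]
        noun_pools[(cls_name, "P")] = noun_idx[noun_idx % buckets == 2 * ci + 1]
    return Lexicon(words=words, weights=weights, verb_class_of=verb_class_of, noun_pools=noun_pools)


# ---------------------------------------------------------------------------
# utterance generation
# ---------------------------------------------------------------------------

def _weighted_choice(rng: np.random.Generator, items: Sequence[str], probs: Sequence[float]) -> str:
    return items[int(rng.choice(len(items), p=np.asarray(probs, dtype=float)))]


def _draw_noun(rng, spec: LanguageSpec, lex: Lexicon, verb_class: str, role: str) -> str:
    nouns = lex.words["noun"]
    pool = lex.noun_pools.get((verb_class, role))
    if pool is not None and len(pool) and rng.random() < spec.verb_noun_association:
        w = lex.weights["noun"][pool]
        return nouns[int(pool[int(rng.choice(len(pool), p=w / w.sum()))])]
    return nouns[int(rng.choice(len(nouns), p=lex.weights["noun"]))]


def _draw_length_noise(rng, spec: LanguageSpec, scale: float = 1.0) -> int:
    noise = spec.length_noise
    if noise.get("dist", "poisson") == "poisson":
        return int(rng.poisson(noise.get("mean", 0.5) * scale))
    return int(round(noise.get("mean", 0) * scale))


def _realize_utterance(
    rng: np.random.Generator,
    spec: LanguageSpec,
    lex: Lexicon,
    uid: str,
    language: str,
    adjunct_scale: float = 1.0,
    force_pattern: str | None = None,
    force_voice: str | None = None,
    force_nouns: dict[str, str] | None = None,
    deterministic_marking: bool = False,
):
    """Draw and realize one utterance; returns (utterance, log_entry)."""
    voice = None
    if spec.marking.kind == "voice_affix":
        voice = force_voice or _weighted_choice(
            rng, sorted(spec.voice_distribution), [spec.voice_distribution[k] for k in sorted(spec.voice_distribution)]
        )
        orders = spec.order_by_voice[voice]
    else:
        orders = spec.order_distribution
    if force_pattern is not None:
        full = force_pattern
    else:
        keys = sorted(orders)
        full = _weighted_choice(rng, keys, [orders[k] for k in keys])

    # omission: independent per role, resampled until >= 1 argument is overt
    while True:
        omitted = [r for r in ("A", "P") if rng.random() < spec.omission_prob.get(r, 0.0)]
        if force_nouns is not None:
            omitted = []
        if len(omitted) < 2:
            break
    realized = "".join(ch for ch in full if ch not in omitted)

    # verb draw
    vi = int(rng.choice(len(lex.words["verb"]), p=lex.weights["verb"]))
    verb_word = lex.words["verb"][vi]
    verb_class = lex.verb_class_of[vi]

    # argument realization (word + nominality), before linearization
    arg_parts: dict[str, tuple[list[str], Nominality]] = {}
    for role in ("A", "P"):
        if role in omitted or role not in realized:
            continue
        if force_nouns is not None:
            word, nom = force_nouns[role], Nominality.OTHER
        else:
            pr = spec.pronoun_prob_by_role[role]
            if rng.random() < pr["prob"]:
                subtypes = sorted(pr["dist"])
                sub = _weighted_choice(rng, subtypes, [pr["dist"][k] for k in subtypes])
                word, nom = lex.pronoun_for(sub, rng)
            else:
                word, nom = _draw_noun(rng, spec, lex, verb_class, role), Nominality.OTHER
        toks = [word]
        if spec.marking.kind == "case_suffix":
            marker = spec.marking.case_markers.get(role)
            mp = 1.0 if deterministic_marking else spec.marking.case_marker_prob.get(role, 1.0)
            if marker and rng.random() < mp:
                toks = [word, marker]
        elif spec.marking.kind == "voice_affix":
            vs = spec.marking.voices[voice]
            marker = (
                spec.marking.prominent_marker if role == vs.prominent else spec.marking.nonprominent_marker
            )
            if marker:
                toks = [marker, word]
        arg_parts[role] = (toks, nom)

    verb_tokens = [verb_word]
    if spec.marking.kind == "voice_affix" and spec.marking.voices[voice].affix:
        vs = spec.marking.voices[voice]
        if deterministic_marking or rng.random() < vs.affix_prob:
            verb_tokens = [vs.affix, verb_word]

    # linearize
    tokens: list[str] = []
    verb_span = None
    arguments: list[ArgumentSpan] = []
    for ch in realized:
        start = len(tokens)
        if ch == "V":
            tokens.extend(verb_tokens)
            verb_span = (start, len(tokens))
        else:
            toks, nom = arg_parts[ch]
            tokens.extend(toks)
            arguments.append(ArgumentSpan(start, len(tokens), Role(ch), nom))
    n_adj = _draw_length_noise(rng, spec, adjunct_scale)
    for _ in range(n_adj):
        tokens.append(lex.words["function"][int(rng.choice(len(lex.words["function"]), p=lex.weights["function"]))])

    utt = AnnotatedUtterance(
        id=uid,
        language=language,
        tokens=tokens,
        verb_span=verb_span,
        verb_class=verb_class,
        arguments=arguments,
    )
    log = {
        "id": uid,
        "full_pattern": full,
        "realized_pattern": realized,
        "voice": voice,
        "omitted": sorted(omitted),
        "n_adjuncts": n_adj,
    }
    return utt, log


def generate_cdu_corpus(
    spec: LanguageSpec, n: int, seed: int, return_log: bool = False
) -> Corpus | tuple[Corpus, list[dict]]:
    """Generate ``n`` annotated utterances from ``spec`` under ``seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    lex = generate_lexicon(spec, seed)
    utts, logs = [], []
    for i in range(n):
        utt, log = _realize_utterance(rng, spec, lex, uid=f"u{i:06d}", language=spec.name)
        utts.append(utt)
        logs.append(log)
    corpus = Corpus(
        utterances=utts,
        metadata={"generator": {"spec": spec.name, "spec_hash": spec.spec_hash(), "n": n, "seed": seed}},
    )
    if return_log:
        return corpus, logs
    return corpus


def generate_adu_text(spec: LanguageSpec, n_words: int, seed: int) -> list[list[str]]:
    """Unannotated token sequences from the same grammar, longer utterances.

    Stops at the first utterance boundary at or past ``n_words`` total tokens.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    lex = generate_lexicon(spec, seed)
    sequences: list[list[str]] = []
    total = 0
    i = 0
    while total < n_words:
        utt, _ = _realize_utterance(
            rng, spec, lex, uid=f"a{i:06d}", language=spec.name, adjunct_scale=spec.adu_length_scale
        )
        sequences.append(list(utt.tokens))
        total += len(utt.tokens)
        i += 1
    return sequences


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusDesign:
    """Full-factorial stimulus specification.

    ``realization`` maps each cell (factor levels joined with ``|`` in factor
    order) to ``{"pattern": <APV permutation>, "voice": <voice name>?}``.
    """

    language: LanguageSpec
    factors: dict[str, list[str]]
    items_per_cell: int
    realization: dict[str, dict]

    def cells(self) -> list[tuple[str, ...]]:
        return list(itertools.product(*self.factors.values()))

    @classmethod
    def from_yaml(cls, path: str | Path, language: LanguageSpec | None = None) -> "StimulusDesign":
        """Load a design; ``language`` may be inline (dict), a preset name, or passed in."""
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if language is None:
            lang = d["language"]
            language = LanguageSpec.from_dict(lang) if isinstance(lang, dict) else load_preset(lang)
        return cls(
            language=language,
            factors={k: list(v) for k, v in d["factors"].items()},
            items_per_cell=int(d["items_per_cell"]),
            realization={k: dict(v) for k, v in d["realization"].items()},
        )

    def __post_init__(self):
        if self.items_per_cell < 1:
            raise SpecError("items_per_cell must be >= 1")
        for levels in self.factors.values():
            if len(levels) != len(set(levels)):
                raise SpecError("duplicate factor levels")
        for cell in self.cells():
            key = "|".join(cell)
            if key not in self.realization:
                raise SpecError(f"realization missing cell {key!r}")
            r = self.realization[key]
            if r["pattern"] not in _FULL_PATTERNS:
                raise SpecError(f"cell {key!r}: pattern must be a permutation of APV")
            if "voice" in r and r["voice"] is not None:
                if self.language.marking.kind != "voice_affix":
                    raise SpecError(f"cell {key!r}: voice given but language has no voice marking")
                if r["voice"] not in self.language.marking.voices:
                    raise SpecError(f"cell {key!r}: unknown voice {r['voice']!r}")
            elif self.language.marking.kind == "voice_affix":
                raise SpecError(f"cell {key!r}: voice required for voice-marking language")


def generate_stimuli(design: StimulusDesign, seed: int) -> Corpus:
    """Lexically matched factorial stimuli with per-utterance condition labels.

    Every item uses the same content words across all cells; each item has two
    full lexical arguments.  Case markers are applied deterministically.
    """
    spec = design.language
    lex = generate_lexicon(spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    # draw item lexicalizations first, independent of cell enumeration order
    items = []
    for i in range(design.items_per_cell):
        vi = int(rng.choice(len(lex.words["verb"]), p=lex.weights["verb"]))
        verb_class = lex.verb_class_of[vi]
        noun_a = _draw_noun(rng, spec, lex, verb_class, "A")
        noun_p = _draw_noun(rng, spec, lex, verb_class, "P")
        while noun_p == noun_a:
            noun_p = _draw_noun(rng, spec, lex, verb_class, "P")
        items.append((lex.words["verb"][vi], verb_class, noun_a, noun_p))

    factor_names = list(design.factors)
    utts = []
    for i, (verb_word, verb_class, noun_a, noun_p) in enumerate(items):
        for cell in design.cells():
            key = "|".join(cell)
            r = design.realization[key]
            sub_rng = np.random.default_rng(np.random.SeedSequence([seed, 4, i]))
            utt, _ = _realize_utterance(
                sub_rng,
                spec,
                lex,
                uid=f"item{i:03d}|{key}",
                language=spec.name,
                adjunct_scale=0.0,
                force_pattern=r["pattern"],
                force_voice=r.get("voice"),
                force_nouns={"A": noun_a, "P": noun_p},
                deterministic_marking=True,
            )
            # pin the item's verb (the free draw inside _realize_utterance is discarded)
            utt = _replace_verb(utt, verb_word, verb_class, spec, r.get("voice"))
            utt.conditions = dict(zip(factor_names, cell))
            utts.append(utt)
    return Corpus(
        utterances=utts,
        metadata={"stimuli": {"spec": spec.name, "seed": seed, "factors": design.factors}},
    )


def _replace_verb(utt: AnnotatedUtterance, verb_word: str, verb_class: str, spec: LanguageSpec, voice):
    tokens = list(utt.tokens)
    vs, ve = utt.verb_span
    affix = None
    if spec.marking.kind == "voice_affix" and spec.marking.voices[voice].affix:
        affix = spec.marking.voices[voice].affix
    new_verb = ([affix] if affix else []) + [verb_word]
    tokens[vs:ve] = new_verb
    shift = len(new_verb) - (ve - vs)
    args = [
        ArgumentSpan(
            a.start + (shift if a.start >= ve else 0),
            a.end + (shift if a.start >= ve else 0),
            a.role,
            a.nominality,
        )
        for a in utt.arguments
    ]
    return AnnotatedUtterance(
        id=utt.id,
        language=utt.language,
        tokens=tokens,
        verb_span=(vs, vs + len(new_verb)),
        verb_class=verb_class,
        arguments=args,
        conditions=utt.conditions,
    )
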