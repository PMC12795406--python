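"""Incremental semantic role prediction model.

Architecture (four components, all trained jointly unless frozen):

* a token embedder (seeded hashing, character convolution, or externally
  supplied pretrained vectors),
* a *sequential encoder* LSTM that reduces a multi-token argument (or any
  single element) to one vector,
* a *sentence processor* LSTM consuming one element at a time — argument
  spans count as a single element,
* two one-hidden-layer classifiers reading the processor state: a role
  classifier over {A, P} and a next-word predictor over the vocabulary.

The role classifier input is the concatenation
``[argument representation; current processor state; verb
representation-or-zeros]`` where the argument and verb representations are
the processor states at their own time points (so they carry the left
context that distinguishes a first from a second argument); each
already-seen argument is (re)classified independently at every time point,
which is what makes reanalysis of early arguments possible.

Training happens in two stages: next-word-only pretraining on unannotated
text, then joint training on annotated utterances where the role error is
evaluated at the final sentence position and the next-word error at every
position (mixed with weight ``loss_mix``).

Next-word target granularity: when an element spans several tokens, the
target at the previous step is the *first* token of that element; the
end-of-utterance target is a reserved EOS symbol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotatedUtterance, Corpus
from .nn import Adam, LSTMCell, Linear, ParameterStore, Tensor, concat, gather_rows, no_grad, softmax_cross_entropy
from .nn.autodiff import softmax_np

__all__ = [
    "ModelConfig",
    "SRPModel",
    "RoleTrajectory",
    "KFoldResult",
    "make_vocab",
    "elements_of",
    "incremental_forward",
    "evaluate_role_accuracy",
    "training_loss",
    "pretrain",
    "train_main",
    "kfold_evaluate",
]

PAD, UNK, EOS = "<pad>", "<unk>", "<eos>"


@dataclass
class ModelConfig:
    embedding_mode: str = "hash_random"  # hash_random | char_conv | pretrained_vectors
    embedding_dim: int = 24
    encoder_hidden_dim: int = 32
    processor_hidden_dim: int = 48
    classifier_hidden_dim: int = 32
    learning_rate: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 15
    patience: int = 3
    loss_mix: float = 1.0  # weight on the next-word loss during the joint stage
    seed: int = 0
    vectors_path: str | None = None

    def __post_init__(self):
        for name in ("embedding_dim", "encoder_hidden_dim", "processor_hidden_dim", "classifier_hidden_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loss_mix < 0:
            raise ValueError("loss_mix must be >= 0")
        if self.embedding_mode not in ("hash_random", "char_conv", "pretrained_vectors"):
            raise ValueError(f"unknown embedding_mode {self.embedding_mode!r}")


def make_vocab(sequences: Iterable[Sequence[str]]) -> dict[str, int]:
    """Token -> index map with reserved PAD/UNK/EOS entries."""
    vocab = {PAD: 0, UNK: 1, EOS: 2}
    for seq in sequences:
        for tok in seq:
            if tok not in vocab:
                vocab[tok] = len(vocab)
    return vocab


# ---------------------------------------------------------------------------
# element segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Element:
    tokens: tuple[str, ...]
    kind: str            # "arg", "verb", "plain"
    role: str | None = None  # for kind == "arg"


def elements_of(utt: AnnotatedUtterance) -> list[Element]:
    """Segment an utterance into processor elements in surface order.

    Argument spans and the verb span are consumed as single elements;
    all other tokens are elements of their own.
    """
    spans: list[tuple[int, int, str, str | None]] = [
        (utt.verb_span[0], utt.verb_span[1], "verb", None)
    ]
    for a in utt.arguments:
        spans.append((a.start, a.end, "arg", a.role.value))
    spans.sort()
    out: list[Element] = []
    pos = 0
    for s, e, kind, role in spans:
        for i in range(pos, s):
            out.append(Element((utt.tokens[i],), "plain"))
        out.append(Element(tuple(utt.tokens[s:e]), kind, role))
        pos = e
    for i in range(pos, len(utt.tokens)):
        out.append(Element((utt.tokens[i],), "plain"))
    return out


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class RoleTrajectory:
    """Per-time-point role distributions for every argument seen so far.

    ``points[t]`` maps each argument's role label (its identity) to the
    probability distribution ``(p_A, p_P)`` the classifier assigns at time
    ``t`` (after consuming element ``t``); arguments appear from their own
    element onward.  ``next_word[t]``, when requested, is the model's
    distribution over the vocabulary for the upcoming element.
    """

    utterance_id: str
    element_kinds: list[str]
    arg_elements: dict[str, int]
    verb_element: int
    points: list[dict[str, tuple[float, float]]]
    next_word: list[np.ndarray] | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    def p_correct(self, role: str, t: int) -> float:
        pa, pp = self.points[t][role]
        return pa if role == "A" else pp

    def validate(self, tol: float = 1e-6) -> None:
        seen: set[str] = set()
        for t, point in enumerate(self.points):
            for role, (pa, pp) in point.items():
                if abs(pa + pp - 1.0) > tol:
                    raise ValueError(f"role distribution at t={t} sums to {pa + pp}")
            new = set(point)
            if not seen <= new:
                raise ValueError("an argument disappeared from the trajectory")
            seen = new
        expected = set(self.arg_elements)
        if seen != expected:
            raise ValueError("final time point does not cover all arguments")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _hash_vector(token: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(f"{seed}:{token}".encode("utf-8"), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim) / np.sqrt(dim)


def load_word_vectors(path: str | Path, dim: int) -> dict[str, np.ndarray]:
    """Read word2vec-style text vectors (``word v1 v2 ...`` per line)."""
    vecs: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) != 2:  # no count header
            vecs[first[0]] = np.asarray(first[1:], dtype=float)
        for line in fh:
            parts = line.rstrip().split(" ")
            vecs[parts[0]] = np.asarray(parts[1:], dtype=float)
    for w, v in vecs.items():
        if v.shape[0] != dim:
            raise ValueError(f"vector for {w!r} has dim {v.shape[0]}, expected {dim}")
    return vecs


class SRPModel:
    """Parameter store plus forward passes for training and inference."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int]):
        if UNK not in vocab:
            raise ValueError("vocab must contain the UNK symbol")
        self.config = config
        self.vocab = dict(vocab)
        self.provenance: list[str] = []
        self.store = ParameterStore()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        d, He, Hp, Hc = (
            config.embedding_dim,
            config.encoder_hidden_dim,
            config.processor_hidden_dim,
            config.classifier_hidden_dim,
        )
        self._emb_cache: dict[str, np.ndarray] = {}
        self._vectors: dict[str, np.ndarray] | None = None
        if config.embedding_mode == "char_conv":
            chars = sorted({c for tok in vocab for c in tok})
            self.char_index = {c: i + 1 for i, c in enumerate(chars)}  # 0 = pad/unknown
            self.char_emb = self.store.add(
                "char_conv.emb", rng.standard_normal((len(chars) + 1, 16)) * 0.1
            )
            self.conv = Linear(self.store, "char_conv.w", 3 * 16, d, rng)
        elif config.embedding_mode == "pretrained_vectors":
            if not config.vectors_path:
                raise ValueError("pretrained_vectors mode requires vectors_path")
            self._vectors = load_word_vectors(config.vectors_path, d)
        self.encoder = LSTMCell(self.store, "encoder", d, He, rng)
        self.processor = LSTMCell(self.store, "processor", He, Hp, rng)
        self.role_h = Linear(self.store, "role_clf.h", 3 * Hp, Hc, rng)
        self.role_out = Linear(self.store, "role_clf.out", Hc, 2, rng, zero_init=True)
        self.nw_h = Linear(self.store, "next_word.h", Hp, Hc, rng)
        self.nw_out = Linear(self.store, "next_word.out", Hc, len(vocab), rng, zero_init=True)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "vocab": self.vocab,
            "provenance": self.provenance,
        }
        arrays = {f"param::{n}": v for n, v in self.store.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SRPModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]), meta["vocab"])
            model.provenance = list(meta["provenance"])
            model.store.load_state_dict(
                {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
            )
        return model

    def clone(self) -> "SRPModel":
        m = SRPModel(self.config, self.vocab)
        m.store.load_state_dict(self.store.state_dict())
        m.provenance = list(self.provenance)
        return m

    # -- embeddings ---------------------------------------------------------
    def _token_vector(self, token: str) -> np.ndarray:
        """Fixed (non-learned) token vector for hash/pretrained modes."""
        cached = self._emb_cache.get(token)
        if cached is not None:
            return cached
        if self.config.embedding_mode == "hash_random":
            v = _hash_vector(token, self.config.embedding_dim, self.config.seed)
        else:
            v = self._vectors.get(token)
            if v is None:
                v = np.zeros(self.config.embedding_dim)
        self._emb_cache[token] = v
        return v

    def _char_conv_graph(self, tokens: list[str]) -> Tensor:
        """Character-CNN embeddings for ``tokens`` (graph-tracked), (n, d)."""
        L = max(len(t) for t in tokens) + 2  # pad for width-3 windows
        idx = np.zeros((len(tokens), L), dtype=np.intp)
        for r, tok in enumerate(tokens):
            for j, ch in enumerate(tok[: L - 2]):
                idx[r, j + 1] = self.char_index.get(ch, 0)
        emb = gather_rows(self.char_emb, idx.ravel()).reshape(len(tokens), L * 16)
        windows = []
        for j in range(L - 2):
            w = self.conv(emb.slice_cols(j * 16, (j + 3) * 16))
            windows.append(w)
        out = windows[0]
        for w in windows[1:]:  # running elementwise max: max(a,b) = a + relu(b-a)
            out = out + (w - out).relu()
        return out.tanh()

    def embed_element(self, tokens: Sequence[str]) -> np.ndarray:
        """Encoder representation of one element (inference path)."""
        if len(tokens) == 0:
            raise ValueError("cannot embed an empty element")
        with no_grad():
            if self.config.embedding_mode == "char_conv":
                X = self._char_conv_graph(list(tokens)).data
            else:
                X = np.stack([self._token_vector(t) for t in tokens])
            h = np.zeros((1, self.config.encoder_hidden_dim))
            c = np.zeros_like(h)
            for j in range(X.shape[0]):
                h, c = _np_lstm_step(self.encoder, X[j: j + 1], h, c)
        return h[0]

    # -- batched training forward ------------------------------------------
    def _encode_elements(self, element_lists: list[tuple[str, ...]]) -> Tensor:
        """Encode many elements in parallel; returns (n_elements, He)."""
        n = len(element_lists)
        Lmax = max(len(e) for e in element_lists)
        mode = self.config.embedding_mode
        if mode == "char_conv":
            uniq = sorted({t for e in element_lists for t in e})
            uniq_idx = {t: i + 1 for i, t in enumerate(uniq)}  # 0 = padding row
            tok_emb = self._char_conv_graph([""] + uniq)  # row 0 ~ empty token
            step_idx = np.zeros((Lmax, n), dtype=np.intp)
            for r, e in enumerate(element_lists):
                for j, t in enumerate(e):
                    step_idx[j, r] = uniq_idx[t]
        else:
            X = np.zeros((Lmax, n, self.config.embedding_dim))
            for r, e in enumerate(element_lists):
                for j, t in enumerate(e):
                    X[j, r] = self._token_vector(t)
        mask = np.zeros((Lmax, n, 1))
        for r, e in enumerate(element_lists):
            mask[: len(e), r, 0] = 1.0
        h = Tensor(np.zeros((n, self.config.encoder_hidden_dim)))
        c = Tensor(np.zeros_like(h.data))
        for j in range(Lmax):
            if mode == "char_conv":
                x = gather_rows(tok_emb, step_idx[j])
            else:
                x = Tensor(X[j])
            h, c = self.encoder.step_masked(x, h, c, mask[j])
        return h

    def batch_loss(
        self, batch: list[list[Element]], role_targets: list[list[tuple[int, int, int]]] | None,
        stage: str, lam: float | None = None,
    ) -> tuple[Tensor, dict[str, float]]:
        """Joint loss for a bucket of utterances with equal element counts.

        ``role_targets[b]`` lists ``(arg_element, verb_element, role_index)``
        per argument (role index: A=0, P=1); ``None`` for the pretrain stage.
        """
        if not batch:
            raise ValueError("empty batch")
        T = len(batch[0])
        if any(len(els) != T for els in batch):
            raise ValueError("batch_loss requires equal element counts (bucketed batches)")
        B = len(batch)
        lam = self.config.loss_mix if lam is None else lam
        flat = [els[t].tokens for b in range(B) for t in range(T) for els in (batch[b],)]
        enc = self._encode_elements(flat)  # row b*T + t

        h, c = self.processor.init_state(B)
        states = []
        for t in range(T):
            x = gather_rows(enc, np.arange(B) * T + t)
            h, c = self.processor.step(x, h, c)
            states.append(h)

        # next-word loss at every position
        nw_targets = np.zeros(B * T, dtype=np.intp)
        unk = self.vocab[UNK]
        for b in range(B):
            for t in range(T):
                if t + 1 < T:
                    nw_targets[b * T + t] = self.vocab.get(batch[b][t + 1].tokens[0], unk)
                else:
                    nw_targets[b * T + t] = self.vocab[EOS]
        all_states = concat(states, axis=0)  # rows t*B + b
        perm = np.concatenate([np.arange(T) * B + b for b in range(B)])  # -> b*T + t order
        nw_logits = self.nw_out(self.nw_h(gather_rows(all_states, perm)).tanh())
        nw_loss = softmax_cross_entropy(nw_logits, nw_targets)

        parts = {"next_word": float(nw_loss.data)}
        if stage == "pretrain":
            return nw_loss, parts

        if role_targets is None:
            raise ValueError("main stage requires role labels")
        pairs = [(b, ta, tv, y) for b in range(B) for (ta, tv, y) in role_targets[b]]
        if not pairs:
            raise ValueError("main stage batch contains no arguments")
        # argument/verb representations = processor states at their time points
        arg_rows = gather_rows(all_states, np.array([ta * B + b for b, ta, _, _ in pairs]))
        verb_rows = gather_rows(all_states, np.array([tv * B + b for b, _, tv, _ in pairs]))
        state_rows = gather_rows(states[T - 1], np.array([b for b, _, _, _ in pairs]))
        logits = self.role_out(self.role_h(concat([arg_rows, state_rows, verb_rows], axis=1)).tanh())
        targets = np.array([y for _, _, _, y in pairs])
        role_loss = softmax_cross_entropy(logits, targets) * (len(pairs) / B)
        parts["role"] = float(role_loss.data)
        total = role_loss if lam == 0 else role_loss + nw_loss * lam
        return total, parts


def _np_lstm_step(cell: LSTMCell, x: np.ndarray, h: np.ndarray, c: np.ndarray):
    z = x @ cell.Wx.data + h @ cell.Wh.data + cell.b.data
    H = cell.n_hidden
    sig = lambda v: 0.5 * (np.tanh(0.5 * v) + 1.0)
    i, f, g, o = sig(z[:, :H]), sig(z[:, H: 2 * H]), np.tanh(z[:, 2 * H: 3 * H]), sig(z[:, 3 * H:])
    c_new = f * c + i * g
    return o * np.tanh(c_new), c_new


def _np_linear(layer: Linear, x: np.ndarray) -> np.ndarray:
    return x @ layer.W.data + layer.b.data


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def incremental_forward(
    utt: AnnotatedUtterance, model: SRPModel, include_next_word: bool = False
) -> RoleTrajectory:
    """Run the model incrementally over one utterance.

    Gold spans delimit elements, but role labels are never consulted.  Each
    already-seen argument is reclassified at every time point, independently
    of the other argument; the verb slot of the classifier input is a zero
    vector until the verb element has been consumed.
    """
    els = elements_of(utt)
    if not any(e.kind == "verb" for e in els):
        raise ValueError(f"utterance {utt.id} has no verb element")
    Hp = model.config.processor_hidden_dim
    with no_grad():
        reps = [model.embed_element(e.tokens) for e in els]
        verb_t = next(t for t, e in enumerate(els) if e.kind == "verb")
        arg_elements = {e.role: t for t, e in enumerate(els) if e.kind == "arg"}
        h = np.zeros((1, Hp))
        c = np.zeros_like(h)
        h_states: list[np.ndarray] = []
        points: list[dict[str, tuple[float, float]]] = []
        next_word: list[np.ndarray] | None = [] if include_next_word else None
        zeros_verb = np.zeros(Hp)
        for t, rep in enumerate(reps):
            h, c = _np_lstm_step(model.processor, rep[None, :], h, c)
            h_states.append(h[0].copy())
            point: dict[str, tuple[float, float]] = {}
            verb_rep = h_states[verb_t] if t >= verb_t else zeros_verb
            for role, ta in arg_elements.items():
                if ta <= t:
                    x = np.concatenate([h_states[ta], h[0], verb_rep])[None, :]
                    logits = _np_linear(model.role_out, np.tanh(_np_linear(model.role_h, x)))
                    pa, pp = softmax_np(logits)[0]
                    point[role] = (float(pa), float(pp))
            points.append(point)
            if include_next_word:
                nw = _np_linear(model.nw_out, np.tanh(_np_linear(model.nw_h, h)))
                next_word.append(softmax_np(nw)[0])
    return RoleTrajectory(
        utterance_id=utt.id,
        element_kinds=[e.kind + (f":{e.role}" if e.role else "") for e in els],
        arg_elements=arg_elements,
        verb_element=verb_t,
        points=points,
        next_word=next_word,
    )


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _utt_batch_inputs(utts: list[AnnotatedUtterance]):
    batch, targets = [], []
    for u in utts:
        els = elements_of(u)
        batch.append(els)
        tv = next(t for t, e in enumerate(els) if e.kind == "verb")
        targets.append(
            [(t, tv, 0 if e.role == "A" else 1) for t, e in enumerate(els) if e.kind == "arg"]
        )
    return batch, targets


def training_loss(
    batch: list[AnnotatedUtterance] | list[list[str]], model: SRPModel, stage: str
) -> float:
    """Loss of one batch without updating parameters.

    ``pretrain``: mean per-position next-word cross-entropy over token
    sequences.  ``main``: final-position role cross-entropy summed over
    arguments (mean per utterance) plus ``loss_mix`` times the next-word term.
    """
    if not batch:
        raise ValueError("empty batch")
    if stage == "pretrain":
        seqs = [list(b.tokens) if isinstance(b, AnnotatedUtterance) else list(b) for b in batch]
        total, weight = 0.0, 0
        for T, group in _buckets(seqs, key=len).items():
            els = [[Element((t,), "plain") for t in s] for s in group]
            with no_grad():
                loss, _ = model.batch_loss(els, None, "pretrain")
            total += float(loss.data) * len(group) * T
            weight += len(group) * T
        return total / weight
    if stage == "main":
        if any(not isinstance(b, AnnotatedUtterance) for b in batch):
            raise ValueError("main stage requires annotated utterances")
        if any(not b.arguments for b in batch):
            raise ValueError("main stage requires every utterance to have >= 1 argument")
        total, n = 0.0, 0
        for _, group in _buckets(batch, key=lambda u: len(elements_of(u))).items():
            els, tgt = _utt_batch_inputs(group)
            with no_grad():
                loss, _ = model.batch_loss(els, tgt, "main")
            total += float(loss.data) * len(group)
            n += len(group)
        return total / n
    raise ValueError(f"unknown stage {stage!r}")


def _buckets(items, key):
    out: dict[int, list] = {}
    for it in items:
        out.setdefault(key(it), []).append(it)
    return out


def _iter_minibatches(rng, items, key, batch_size):
    order = rng.permutation(len(items))
    buckets = _buckets([items[i] for i in order], key)
    chunks = []
    for _, group in sorted(buckets.items()):
        for i in range(0, len(group), batch_size):
            chunks.append(group[i: i + batch_size])
    chunk_order = rng.permutation(len(chunks))
    for ci in chunk_order:
        yield chunks[ci]


def pretrain(
    adu: list[list[str]], config: ModelConfig, vocab: dict[str, int] | None = None,
    log: list[dict] | None = None,
) -> SRPModel:
    """Next-word-only training on unannotated token sequences.

    The role classifier's parameters are excluded from the optimizer and are
    left at their initialization.
    """
    if not adu:
        raise ValueError("empty pretraining corpus")
    vocab = vocab if vocab is not None else make_vocab(adu)
    model = SRPModel(config, vocab)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 21]))
    n_val = max(1, len(adu) // 10)
    order = rng.permutation(len(adu))
    val = [adu[i] for i in order[:n_val]]
    train = [adu[i] for i in order[n_val:]] or val
    params = [t for n, t in model.store.items() if not n.startswith("role_clf")]
    opt = Adam(params, lr=config.learning_rate)
    best, best_state, patience = np.inf, None, 0
    for epoch in range(config.max_epochs):
        for chunk in _iter_minibatches(rng, train, key=len, batch_size=config.batch_size):
            els = [[Element((t,), "plain") for t in seq] for seq in chunk]
            opt.zero_grad()
            loss, _ = model.batch_loss(els, None, "pretrain")
            loss.backward()
            opt.step()
        val_loss = training_loss(val, model, "pretrain")
        if log is not None:
            log.append({"stage": "pretrain", "epoch": epoch, "val_next_word_loss": val_loss})
        if val_loss < best - 1e-6:
            best, best_state, patience = val_loss, model.store.state_dict(), 0
        else:
            patience += 1
            if patience >= config.patience:
                break
    if best_state is not None:
        model.store.load_state_dict(best_state)
    model.provenance.append("pretrained")
    return model


def evaluate_role_accuracy(model: SRPModel, corpus: Iterable[AnnotatedUtterance]) -> float:
    """Final-position argmax accuracy over all arguments."""
    correct = total = 0
    for u in corpus:
        traj = incremental_forward(u, model)
        for role in traj.arg_elements:
            total += 1
            pa, pp = traj.points[-1][role]
            if (pa >= pp) == (role == "A"):
                correct += 1
    return correct / total if total else float("nan")


def train_main(
    model: SRPModel, train: Corpus | list[AnnotatedUtterance],
    val: Corpus | list[AnnotatedUtterance], config: ModelConfig | None = None,
    from_scratch: bool = False, log: list[dict] | None = None,
) -> SRPModel:
    """Joint role + next-word training with early stopping on validation
    role accuracy; returns the model restored to its best epoch."""
    config = config or model.config
    train = list(train)
    val = list(val)
    if not train:
        raise ValueError("empty training set")
    if not from_scratch and "pretrained" not in model.provenance:
        model.provenance.append("main-from-scratch")
    model = model.clone()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    opt = Adam(model.store.tensors(), lr=config.learning_rate)
    best_acc, best_state, patience = -np.inf, model.store.state_dict(), 0
    for epoch in range(config.max_epochs):
        part_sums = {"role": 0.0, "next_word": 0.0}
        n_batches = 0
        for chunk in _iter_minibatches(
            rng, train, key=lambda u: len(elements_of(u)), batch_size=config.batch_size
        ):
            els, tgt = _utt_batch_inputs(chunk)
            opt.zero_grad()
            loss, parts = model.batch_loss(els, tgt, "main")
            loss.backward()
            opt.step()
            for k in part_sums:
                part_sums[k] += parts.get(k, 0.0)
            n_batches += 1
        val_acc = evaluate_role_accuracy(model, val) if val else float("nan")
        if log is not None:
            log.append(
                {
                    "stage": "main", "epoch": epoch, "val_role_accuracy": val_acc,
                    "train_role_loss": part_sums["role"] / n_batches,
                    "train_next_word_loss": part_sums["next_word"] / n_batches,
                }
            )
        if val and val_acc > best_acc + 1e-9:
            best_acc, best_state, patience = val_acc, model.store.state_dict(), 0
        elif val:
            patience += 1
            if patience >= config.patience:
                break
        else:
            best_state = model.store.state_dict()
    model.store.load_state_dict(best_state)
    model.provenance.append("main-trained")
    return model


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class KFoldResult:
    trajectories: dict[str, RoleTrajectory]
    fold_table: pd.DataFrame        # columns: fold, n_test, accuracy
    assignments: dict[str, int]     # utterance id -> fold


def kfold_evaluate(
    corpus: Corpus, k: int, config: ModelConfig, pretrained: SRPModel | None = None,
    log: list[dict] | None = None,
) -> KFoldResult:
    """k-fold cross-validation: each utterance's trajectory comes from the
    fold where it was held out; the non-test portion is split 90/10 into
    train/validation."""
    utts = list(corpus)
    if len(utts) < k:
        raise ValueError(f"corpus of size {len(utts)} smaller than k={k}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    order = rng.permutation(len(utts))
    folds = [order[i::k] for i in range(k)]
    assignments = {utts[i].id: f for f, idx in enumerate(folds) for i in idx}
    trajectories: dict[str, RoleTrajectory] = {}
    rows = []
    for f, test_idx in enumerate(folds):
        test = [utts[i] for i in test_idx]
        rest = [utts[i] for fo, idx in enumerate(folds) if fo != f for i in idx]
        n_val = max(1, len(rest) // 10)
        val, train = rest[:n_val], rest[n_val:]
        if pretrained is not None:
            base = pretrained.clone()
        else:
            vocab = make_vocab([u.tokens for u in train + val])
            base = SRPModel(config, vocab)
        fitted = train_main(base, train, val, config, from_scratch=pretrained is None, log=log)
        correct = total = 0
        for u in test:
            traj = incremental_forward(u, fitted)
            trajectories[u.id] = traj
            for role in traj.arg_elements:
                total += 1
                pa, pp = traj.points[-1][role]
                if (pa >= pp) == (role == "A"):
                    correct += 1
        rows.append({"fold": f, "n_test": len(test), "accuracy": correct / total if total else np.nan})
    return KFoldResult(
        trajectories=trajectories,
        fold_table=pd.DataFrame(rows),
        assignments=assignments,
    )
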