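"""Character-level LSTM SMILES language model, in pure NumPy.

The model is trained to predict the next token of a SMILES string (teacher
forcing, cross-entropy), pretrained on a broad corpus of drug-like molecules
and then *fine-tuned* by transfer learning on a small focused set to bias
sampling toward a chemical series. Sampling draws tokens autoregressively at
a temperature, starting from BEGIN and stopping at END.

Implementation notes. Forward/backward passes (BPTT) and the Adam optimizer
are written out explicitly against NumPy arrays in float32; gates are fused
into a single ``(input+hidden) x 4*hidden`` matrix per layer in [i, f, g, o]
order, with the forget-gate bias initialized to +1. All randomness
(initialization, shuffling, sampling) flows through seeded
``numpy.random.Generator`` instances, so training and sampling are exactly
reproducible, and a saved checkpoint reloads to bit-identical samples.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from . import chem
from .chem import FingerprintKind, SimilarityMeasure
from .errors import VocabularyError

# Two-letter elements and bracket atoms are single tokens; '%nn' ring-closure
# indices likewise. The trailing '.' matches any remaining single character,
# so findall() partitions every string exactly (round-trip by construction).
_TOKEN_RE = re.compile(r"Cl|Br|\[[^\[\]]+\]|%\d{2}|.")

PAD, BEGIN, END = "<pad>", "^", "$"


class TokenVocabulary:
    """Ordered token set with PAD/BEGIN/END specials at indices 0/1/2."""

    def __init__(self, tokens: Iterable[str]):
        specials = [PAD, BEGIN, END]
        self.tokens = specials + sorted(set(tokens) - set(specials))
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_corpus(cls, corpus: Iterable[str]) -> "TokenVocabulary":
        seen: set[str] = set()
        for smiles in corpus:
            seen.update(cls.tokenize(smiles))
        return cls(seen)

    @staticmethod
    def tokenize(smiles: str) -> list[str]:
        return _TOKEN_RE.findall(smiles)

    def encode(self, smiles: str) -> np.ndarray:
        """BEGIN + token ids + END; unknown tokens raise, naming the token."""
        ids = [1]
        for tok in self.tokenize(smiles):
            if tok not in self.index:
                raise VocabularyError(f"token {tok!r} not in vocabulary (in {smiles!r})")
            ids.append(self.index[tok])
        ids.append(2)
        return np.asarray(ids, dtype=np.int32)

    def decode(self, ids: Sequence[int]) -> str:
        out = []
        for i in ids:
            tok = self.tokens[int(i)]
            if tok == END:
                break
            if tok in (PAD, BEGIN):
                continue
            out.append(tok)
        return "".join(out)

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other) -> bool:
        return isinstance(other, TokenVocabulary) and self.tokens == other.tokens


def build_vocabulary(corpus: Sequence[str]) -> TokenVocabulary:
    """Vocabulary covering every token of a non-empty corpus, deterministic order."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    return TokenVocabulary.from_corpus(corpus)


@dataclass
class GeneratorConfig:
    """Architecture and optimizer hyperparameters (desk-scale defaults)."""

    n_layers: int = 2
    hidden_size: int = 256
    embedding_size: int = 64
    learning_rate: float = 2e-3
    batch_size: int = 32
    grad_clip: float = 5.0
    val_fraction: float = 0.1
    max_length: int = 100


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SmilesGenerator:
    """LSTM next-token model over a :class:`TokenVocabulary`."""

    def __init__(
        self,
        vocab: TokenVocabulary,
        config: GeneratorConfig | None = None,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.config = config or GeneratorConfig()
        self.history: list[dict] = []
        rng = np.random.default_rng(seed)
        V, E, H = len(vocab), self.config.embedding_size, self.config.hidden_size
        self.params: dict[str, np.ndarray] = {
            "emb": (rng.standard_normal((V, E)) * 0.1).astype(np.float32),
            "Wout": (rng.standard_normal((H, V)) / np.sqrt(H)).astype(np.float32),
            "bout": np.zeros(V, dtype=np.float32),
        }
        for layer in range(self.config.n_layers):
            in_dim = E if layer == 0 else H
            w = rng.standard_normal((in_dim + H, 4 * H)) / np.sqrt(in_dim + H)
            b = np.zeros(4 * H, dtype=np.float32)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"W{layer}"] = w.astype(np.float32)
            self.params[f"b{layer}"] = b
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------

    def _step(self, layer: int, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        """One LSTM cell step for a batch; returns new (h, c) and the cache."""
        H = self.config.hidden_size
        xh = np.concatenate([x, h], axis=1)
        z = xh @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        hc = np.tanh(c_new)
        h_new = o * hc
        return h_new, c_new, (xh, i, f, g, o, c, hc)

    def _forward(self, batch: np.ndarray, compute_cache: bool = True):
        """Teacher-forced forward pass over a padded id batch (B, T).

        Returns (mean loss over non-pad targets, n_tokens, cache).
        """
        cfg = self.config
        B, T = batch.shape
        inputs, targets = batch[:, :-1], batch[:, 1:]
        mask = targets != 0
        n_tokens = int(mask.sum())
        X = self.params["emb"][inputs]  # (B, T-1, E)
        layer_inputs = X
        caches: list[list] = []
        hs_top = None
        for layer in range(cfg.n_layers):
            H = cfg.hidden_size
            h = np.zeros((B, H), dtype=np.float32)
            c = np.zeros((B, H), dtype=np.float32)
            outs = np.empty((B, T - 1, H), dtype=np.float32)
            layer_cache = []
            for t in range(T - 1):
                h, c, cache_t = self._step(layer, layer_inputs[:, t], h, c)
                outs[:, t] = h
                if compute_cache:
                    layer_cache.append(cache_t)
            caches.append(layer_cache)
            layer_inputs = outs
            hs_top = outs
        logits = hs_top @ self.params["Wout"] + self.params["bout"]
        probs = _softmax(logits)
        eps = np.float32(1e-9)
        tgt_prob = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        loss = float(-(np.log(tgt_prob + eps) * mask).sum() / max(n_tokens, 1))
        cache = (batch, inputs, targets, mask, X, caches, hs_top, probs) if compute_cache else None
        return loss, n_tokens, cache

    def _backward(self, cache) -> dict[str, np.ndarray]:
        cfg = self.config
        batch, inputs, targets, mask, X, caches, hs_top, probs = cache
        B, Tm1 = inputs.shape
        H = cfg.hidden_size
        n_tokens = max(int(mask.sum()), 1)
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits,
            targets[..., None],
            np.take_along_axis(dlogits, targets[..., None], axis=-1) - 1.0,
            axis=-1,
        )
        dlogits *= mask[..., None] / n_tokens
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wout"] = hs_top.reshape(-1, H).T @ dlogits.reshape(-1, dlogits.shape[-1])
        grads["bout"] = dlogits.sum(axis=(0, 1))
        d_layer_out = dlogits @ self.params["Wout"].T  # gradient w.r.t. top hidden states
        for layer in reversed(range(cfg.n_layers)):
            W = self.params[f"W{layer}"]
            in_dim = W.shape[0] - H
            dW = np.zeros_like(W)
            db = np.zeros_like(self.params[f"b{layer}"])
            d_below = np.empty((B, Tm1, in_dim), dtype=np.float32)
            dh_next = np.zeros((B, H), dtype=np.float32)
            dc_next = np.zeros((B, H), dtype=np.float32)
            for t in reversed(range(Tm1)):
                xh, i, f, g, o, c_prev, hc = caches[layer][t]
                dh = d_layer_out[:, t] + dh_next
                do = dh * hc
                dc = dc_next + dh * o * (1.0 - hc * hc)
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc_next = dc * f
                dz = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g * g),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                dW += xh.T @ dz
                db += dz.sum(axis=0)
                dxh = dz @ W.T
                d_below[:, t] = dxh[:, :in_dim]
                dh_next = dxh[:, in_dim:]
            grads[f"W{layer}"] = dW
            grads[f"b{layer}"] = db
            d_layer_out = d_below
        demb = np.zeros_like(self.params["emb"])
        np.add.at(demb, inputs, d_layer_out)
        grads["emb"] = demb
        return grads

    def _adam_update(self, grads: dict[str, np.ndarray], lr: float) -> None:
        norm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
        scale = min(1.0, self.config.grad_clip / (norm + 1e-12))
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for key, g in grads.items():
            g = g * scale
            self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * g
            self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * g * g
            m_hat = self._adam_m[key] / (1 - b1**t)
            v_hat = self._adam_v[key] / (1 - b2**t)
            self.params[key] -= (lr * m_hat / (np.sqrt(v_hat) + eps)).astype(np.float32)

    # -- training ----------------------------------------------------------

    def _pad_batch(self, encoded: list[np.ndarray]) -> np.ndarray:
        T = max(len(e) for e in encoded)
        out = np.zeros((len(encoded), T), dtype=np.int32)
        for row, e in enumerate(encoded):
            out[row, : len(e)] = e
        return out

    def fit(
        self,
        corpus: Sequence[str],
        epochs: int,
        seed: int = 0,
        learning_rate: float | None = None,
        val_fraction: float | None = None,
    ) -> list[dict]:
        """Train on a SMILES corpus; returns the per-epoch loss history.

        ``val_fraction`` > 0 holds out that share of the corpus (at least one
        molecule) and records a held-out next-token cross-entropy per epoch.
        ``epochs=0`` is a no-op that leaves the parameters untouched.
        """
        if not corpus:
            raise ValueError("training corpus must be non-empty")
        if epochs == 0:
            return self.history
        lr = learning_rate if learning_rate is not None else self.config.learning_rate
        vf = self.config.val_fraction if val_fraction is None else val_fraction
        rng = np.random.default_rng(seed)
        encoded = [self.vocab.encode(s) for s in corpus]
        order = rng.permutation(len(encoded))
        n_val = int(round(vf * len(encoded))) if vf > 0 and len(encoded) >= 10 else 0
        val = [encoded[i] for i in order[:n_val]]
        train = [encoded[i] for i in order[n_val:]]
        bs = self.config.batch_size
        for epoch in range(epochs):
            perm = rng.permutation(len(train))
            total, total_tokens = 0.0, 0
            for start in range(0, len(train), bs):
                batch = self._pad_batch([train[i] for i in perm[start : start + bs]])
                loss, n_tok, cache = self._forward(batch)
                if not np.isfinite(loss):
                    raise ArithmeticError(
                        f"non-finite training loss at epoch {epoch}, batch "
                        f"{start // bs} (lr={lr}, grad_clip={self.config.grad_clip})"
                    )
                grads = self._backward(cache)
                self._adam_update(grads, lr)
                total += loss * n_tok
                total_tokens += n_tok
            record = {"epoch": len(self.history) + 1, "train_loss": total / max(total_tokens, 1)}
            if val:
                vloss, vtok, _ = self._forward(self._pad_batch(val), compute_cache=False)
                record["val_loss"] = vloss
            self.history.append(record)
        return self.history

    def log_likelihood(self, smiles_list: Sequence[str]) -> float:
        """Mean per-token natural-log likelihood of the given molecules."""
        encoded = [self.vocab.encode(s) for s in smiles_list]
        loss, _, _ = self._forward(self._pad_batch(encoded), compute_cache=False)
        return -loss

    # -- sampling ----------------------------------------------------------

    def sample(
        self,
        n: int,
        temperature: float = 1.0,
        seed: int = 0,
        max_length: int | None = None,
    ) -> list[str]:
        """Draw exactly ``n`` SMILES strings (validity assessed downstream).

        Generation of each string stops at the END token or ``max_length``
        tokens. Fixed (n, temperature, seed) reproduces the same list.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if not temperature > 0:
            raise ValueError("temperature must be > 0")
        cfg = self.config
        max_length = max_length or cfg.max_length
        rng = np.random.default_rng(seed)
        H, L = cfg.hidden_size, cfg.n_layers
        h = [np.zeros((n, H), dtype=np.float32) for _ in range(L)]
        c = [np.zeros((n, H), dtype=np.float32) for _ in range(L)]
        prev = np.full(n, 1, dtype=np.int32)  # BEGIN
        finished = np.zeros(n, dtype=bool)
        rows: list[np.ndarray] = []
        for _ in range(max_length):
            x = self.params["emb"][prev]
            for layer in range(L):
                h[layer], c[layer], _ = self._step(layer, x, h[layer], c[layer])
                x = h[layer]
            logits = x @ self.params["Wout"] + self.params["bout"]
            logits[:, 0] = -np.inf  # never sample PAD
            logits[:, 1] = -np.inf  # never sample BEGIN
            probs = _softmax(logits.astype(np.float64) / temperature)
            cdf = np.cumsum(probs, axis=1)
            u = rng.random((n, 1)) * cdf[:, -1:]
            nxt = (cdf < u).sum(axis=1).astype(np.int32)
            nxt[finished] = 2  # keep feeding END once a row is done
            rows.append(nxt.copy())
            finished |= nxt == 2
            prev = nxt
            if finished.all():
                break
        ids = np.stack(rows, axis=1)
        return [self.vocab.decode(ids[row]) for row in range(n)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: vocabulary + config + weights (.npz).

        Optimizer state is not checkpointed; a reloaded model samples
        identically and can be fine-tuned with a fresh optimizer.
        """
        meta = {
            "vocab": self.vocab.tokens,
            "config": asdict(self.config),
            "history": self.history,
        }
        np.savez(path, __meta__=np.str_(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SmilesGenerator":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(TokenVocabulary(meta["vocab"]), GeneratorConfig(**meta["config"]))
        for key in model.params:
            model.params[key] = data[key]
        model.history = meta["history"]
        return model

    def clone(self) -> "SmilesGenerator":
        return copy.deepcopy(self)


# -- module-level operations ------------------------------------------------


def pretrain(
    corpus: Sequence[str],
    epochs: int,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> SmilesGenerator:
    """Train a fresh model on a broad corpus (>= 10 molecules)."""
    if len(corpus) < 10:
        raise ValueError("pretraining corpus must contain at least 10 molecules")
    vocab = build_vocabulary(corpus)
    model = SmilesGenerator(vocab, config, seed=seed)
    model.fit(corpus, epochs, seed=seed)
    return model


def fine_tune(
    model: SmilesGenerator,
    focused: Sequence[str],
    epochs: int,
    seed: int = 0,
    learning_rate: float = 1e-3,
) -> SmilesGenerator:
    """Transfer-learn a copy of ``model`` on a focused set; original untouched.

    The focused set must be covered by the pretrained vocabulary. No
    held-out split is used (focused sets are small).
    """
    if not focused:
        raise ValueError("focused set must be non-empty")
    tuned = model.clone()
    tuned.fit(focused, epochs, seed=seed, learning_rate=learning_rate, val_fraction=0.0)
    return tuned


def sample(
    model: SmilesGenerator,
    n: int,
    temperature: float = 1.0,
    seed: int = 0,
    max_length: int | None = None,
) -> list[str]:
    return model.sample(n, temperature=temperature, seed=seed, max_length=max_length)


@dataclass
class GenerationReport:
    """MOSES-style generation-quality metrics on canonical SMILES.

    validity = valid / sampled; uniqueness = unique canonical among valid /
    valid; novelty = unique valid not in the training set / unique valid;
    internal diversity = 1 - mean pairwise circular-fingerprint Tanimoto over
    the unique valid set; scaffold_overlap = fraction of unique-valid
    Bemis-Murcko frameworks that also occur in a reference set. Undefined
    metrics (e.g. uniqueness with zero valid samples) are None.
    """

    n_sampled: int
    validity: float
    uniqueness: float | None
    novelty: float | None
    internal_diversity: float | None
    scaffold_overlap: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_generation(
    samples: Sequence[str],
    training_corpus: Sequence[str],
    reference_actives: Sequence[str] | None = None,
    seed: int = 0,
    diversity_subsample: int = 500,
) -> GenerationReport:
    """Compute the generation-quality report for a sample batch."""
    if not samples:
        raise ValueError("samples must be non-empty")
    valid = []
    for smi in samples:
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol))
    validity = len(valid) / len(samples)
    if not valid:
        return GenerationReport(len(samples), 0.0, None, None, None, None)
    unique = sorted(set(valid))
    uniqueness = len(unique) / len(valid)
    train_canonical = {chem.canonicalize(s) for s in training_corpus}
    novel = [s for s in unique if s not in train_canonical]
    novelty = len(novel) / len(unique)
    internal_diversity = _internal_diversity(unique, seed, diversity_subsample)
    scaffold_overlap = None
    if reference_actives is not None:
        ref_scaffolds = {
            MurckoScaffold.MurckoScaffoldSmiles(smiles=s) for s in reference_actives
        }
        scaffolds = [MurckoScaffold.MurckoScaffoldSmiles(smiles=s) for s in unique]
        scaffold_overlap = (
            sum(sc in ref_scaffolds for sc in scaffolds) / len(scaffolds)
            if scaffolds
            else None
        )
    return GenerationReport(
        n_sampled=len(samples),
        validity=validity,
        uniqueness=uniqueness,
        novelty=novelty,
        internal_diversity=internal_diversity,
        scaffold_overlap=scaffold_overlap,
    )


def _internal_diversity(unique_smiles: list[str], seed: int, subsample: int) -> float | None:
    if len(unique_smiles) < 2:
        return None
    rng = np.random.default_rng(seed)
    if len(unique_smiles) > subsample:
        idx = rng.choice(len(unique_smiles), subsample, replace=False)
        unique_smiles = [unique_smiles[i] for i in sorted(idx)]
    fps = [chem.fingerprint(s, FingerprintKind.CIRCULAR) for s in unique_smiles]
    stacked = np.array(fps)
    # pairwise Tanimoto via popcount arithmetic on the bool matrix
    inter = stacked.astype(np.int32) @ stacked.T.astype(np.int32)
    counts = stacked.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tani = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    iu = np.triu_indices(len(unique_smiles), k=1)
    return float(1.0 - tani[iu].mean())


def focused_shift(
    before: Sequence[str],
    after: Sequence[str],
    focused: Sequence[str],
) -> tuple[float, float]:
    """Mean nearest-analog circular Tanimoto of two sample batches to a focused set.

    Diagnostic for transfer learning: the 'after' batch of a fine-tuned model
    should sit closer to the focused series than the 'before' batch.
    """
    focused_fps = [chem.fingerprint(s, FingerprintKind.CIRCULAR) for s in focused]

    def mean_nearest(batch: Sequence[str]) -> float:
        sims = []
        for smi in batch:
            if not chem.is_valid_smiles(smi):
                continue
            fp = chem.fingerprint(smi, FingerprintKind.CIRCULAR)
            sims.append(
                max(
                    chem.similarity(fp, ffp, SimilarityMeasure.TANIMOTO)
                    for ffp in focused_fps
                )
            )
        return float(np.mean(sims)) if sims else 0.0

    return mean_nearest(before), mean_nearest(after)
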