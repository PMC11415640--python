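"""Character-level recurrent SMILES language model.

A stacked GRU or LSTM next-character model over SMILES strings, used to
propose novel natural-product-like structures.  The network (embedding →
recurrent stack → softmax) is implemented directly on numpy with
full-sequence backpropagation through time and an Adam optimizer; all
randomness (initialization, batching, sampling, augmentation) flows from
explicit seeds, so training and sampling are exactly reproducible.

Defaults follow the reference configuration (3 recurrent layers of 512
units, 128-dimensional embedding, Adam with beta1=0.9/beta2=0.999, batch
128, learning rate 1e-3); tests and the desk-scale corpus use far smaller
settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdMolDescriptors, QED

RDLogger.DisableLog("rdApp.*")

from .errors import ConfigurationError, ParseError

PAD, START, END = 0, 1, 2
SPECIALS = ["<pad>", "^", "$"]


@dataclass
class GeneratorConfig:
    cell: str = "gru"  # "gru" | "lstm"
    layers: int = 3
    hidden: int = 512
    embedding: int = 128
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 128
    learning_rate: float = 1e-3
    epochs: int = 10
    seed: int = 0
    max_len: int = 200
    temperature: float = 1.0

    def __post_init__(self):
        if self.cell not in ("gru", "lstm"):
            raise ConfigurationError("cell must be 'gru' or 'lstm'")


def build_vocabulary(corpus: list[str]) -> dict[str, int]:
    chars = sorted({ch for smi in corpus for ch in smi})
    vocab = {tok: i for i, tok in enumerate(SPECIALS)}
    for ch in chars:
        vocab[ch] = len(vocab)
    return vocab


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


class SmilesLanguageModel:
    """Stacked GRU/LSTM next-character model with manual BPTT."""

    def __init__(self, vocab: dict[str, int], config: GeneratorConfig):
        self.vocab = vocab
        self.inv_vocab = {i: t for t, i in vocab.items()}
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self._init_params(np.random.default_rng(config.seed))

    # -- parameters --------------------------------------------------------
    def _init_params(self, rng):
        V, E, H = len(self.vocab), self.config.embedding, self.config.hidden
        n_gates = 3 if self.config.cell == "gru" else 4

        def mat(shape):
            return (rng.standard_normal(shape) * 0.1).astype(np.float64)

        self.params["emb"] = mat((V, E))
        for layer in range(self.config.layers):
            d_in = E if layer == 0 else H
            self.params[f"W{layer}"] = mat((d_in, n_gates * H))
            self.params[f"U{layer}"] = mat((H, n_gates * H))
            self.params[f"b{layer}"] = np.zeros(n_gates * H)
        self.params["Wout"] = mat((H, V))
        self.params["bout"] = np.zeros(V)
        for k, v in self.params.items():
            self._adam_m[k] = np.zeros_like(v)
            self._adam_v[k] = np.zeros_like(v)

    # -- cells -------------------------------------------------------------
    def _step(self, layer, x, h_prev, c_prev):
        """One recurrent step; returns (h, c, cache)."""
        H = self.config.hidden
        W, U, b = (
            self.params[f"W{layer}"],
            self.params[f"U{layer}"],
            self.params[f"b{layer}"],
        )
        if self.config.cell == "gru":
            zr = x @ W[:, : 2 * H] + h_prev @ U[:, : 2 * H] + b[: 2 * H]
            z = _sigmoid(zr[:, :H])
            r = _sigmoid(zr[:, H:])
            hh = np.tanh(
                x @ W[:, 2 * H :] + (r * h_prev) @ U[:, 2 * H :] + b[2 * H :]
            )
            h = (1 - z) * h_prev + z * hh
            return h, c_prev, (x, h_prev, z, r, hh)
        gates = x @ W + h_prev @ U + b
        i = _sigmoid(gates[:, :H])
        f = _sigmoid(gates[:, H : 2 * H])
        o = _sigmoid(gates[:, 2 * H : 3 * H])
        g = np.tanh(gates[:, 3 * H :])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return h, c, (x, h_prev, c_prev, i, f, o, g, c)

    def _step_back(self, layer, cache, dh, dc, grads):
        """Backward through one step; returns (dx, dh_prev, dc_prev)."""
        H = self.config.hidden
        W, U = self.params[f"W{layer}"], self.params[f"U{layer}"]
        if self.config.cell == "gru":
            x, h_prev, z, r, hh = cache
            dz = dh * (hh - h_prev) * z * (1 - z)
            dhh = dh * z * (1 - hh * hh)
            dr = (dhh @ U[:, 2 * H :].T) * h_prev * r * (1 - r)
            d_gates = np.concatenate([dz, dr], axis=1)
            dx = d_gates @ W[:, : 2 * H].T + dhh @ W[:, 2 * H :].T
            dh_prev = (
                dh * (1 - z)
                + d_gates @ U[:, : 2 * H].T
                + (dhh @ U[:, 2 * H :].T) * r
            )
            grads[f"W{layer}"][:, : 2 * H] += x.T @ d_gates
            grads[f"W{layer}"][:, 2 * H :] += x.T @ dhh
            grads[f"U{layer}"][:, : 2 * H] += h_prev.T @ d_gates
            grads[f"U{layer}"][:, 2 * H :] += (r * h_prev).T @ dhh
            grads[f"b{layer}"][: 2 * H] += d_gates.sum(axis=0)
            grads[f"b{layer}"][2 * H :] += dhh.sum(axis=0)
            return dx, dh_prev, dc
        x, h_prev, c_prev, i, f, o, g, c = cache
        tanh_c = np.tanh(c)
        do = dh * tanh_c * o * (1 - o)
        dc_total = dc + dh * o * (1 - tanh_c * tanh_c)
        di = dc_total * g * i * (1 - i)
        df = dc_total * c_prev * f * (1 - f)
        dg = dc_total * i * (1 - g * g)
        d_gates = np.concatenate([di, df, do, dg], axis=1)
        dx = d_gates @ W.T
        dh_prev = d_gates @ U.T
        dc_prev = dc_total * f
        grads[f"W{layer}"] += x.T @ d_gates
        grads[f"U{layer}"] += h_prev.T @ d_gates
        grads[f"b{layer}"] += d_gates.sum(axis=0)
        return dx, dh_prev, dc_prev

    # -- training ----------------------------------------------------------
    def _encode_batch(self, batch: list[str]) -> np.ndarray:
        max_len = max(len(s) for s in batch) + 2
        arr = np.full((len(batch), max_len), PAD, dtype=np.int64)
        for bi, smi in enumerate(batch):
            arr[bi, 0] = START
            for k, ch in enumerate(smi):
                arr[bi, k + 1] = self.vocab[ch]
            arr[bi, len(smi) + 1] = END
        return arr

    def _forward_batch(self, tokens: np.ndarray):
        """Teacher-forced forward pass; returns (mean loss, caches)."""
        B, T = tokens.shape
        H, L = self.config.hidden, self.config.layers
        h = [np.zeros((B, H)) for _ in range(L)]
        c = [np.zeros((B, H)) for _ in range(L)]
        caches, logits_list = [], []
        for t in range(T - 1):
            x = self.params["emb"][tokens[:, t]]
            step_caches = []
            for layer in range(L):
                h[layer], c[layer], cache = self._step(layer, x, h[layer], c[layer])
                step_caches.append(cache)
                x = h[layer]
            logits = x @ self.params["Wout"] + self.params["bout"]
            caches.append(step_caches)
            logits_list.append(logits)
        mask = tokens[:, 1:] != PAD
        loss = 0.0
        probs_list = []
        for t, logits in enumerate(logits_list):
            shifted = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(shifted)
            probs /= probs.sum(axis=1, keepdims=True)
            probs_list.append(probs)
            target = tokens[:, t + 1]
            m = mask[:, t]
            loss -= np.sum(np.log(probs[np.arange(B), target] + 1e-12) * m)
        n_tokens = mask.sum()
        return loss / max(n_tokens, 1), caches, probs_list, mask

    def _backward_batch(self, tokens, caches, probs_list, mask):
        B, T = tokens.shape
        H, L = self.config.hidden, self.config.layers
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dh = [np.zeros((B, H)) for _ in range(L)]
        dc = [np.zeros((B, H)) for _ in range(L)]
        n_tokens = max(mask.sum(), 1)
        for t in reversed(range(T - 1)):
            probs = probs_list[t].copy()
            target = tokens[:, t + 1]
            probs[np.arange(B), target] -= 1.0
            probs *= (mask[:, t] / n_tokens)[:, None]
            # top hidden state at time t is recomputable from its cache
            top_cache = caches[t][L - 1]
            if self.config.cell == "gru":
                x_c, h_prev_c, z_c, _r, hh_c = top_cache
                h_top = (1 - z_c) * h_prev_c + z_c * hh_c
            else:
                _x, _hp, _cp, _i, _f, o_c, _g, c_c = top_cache
                h_top = o_c * np.tanh(c_c)
            grads["Wout"] += h_top.T @ probs
            grads["bout"] += probs.sum(axis=0)
            d_from_out = probs @ self.params["Wout"].T
            d_x = None
            for layer in reversed(range(L)):
                d_hidden = dh[layer] + (d_from_out if layer == L - 1 else d_x)
                d_x, dh[layer], dc[layer] = self._step_back(
                    layer, caches[t][layer], d_hidden, dc[layer], grads
                )
            emb_idx = tokens[:, t]
            np.add.at(grads["emb"], emb_idx, d_x)
        return grads

    def _adam_step(self, grads):
        cfg = self.config
        self._adam_t += 1
        lr_t = cfg.learning_rate * (
            np.sqrt(1 - cfg.beta2**self._adam_t) / (1 - cfg.beta1**self._adam_t)
        )
        for k, g in grads.items():
            np.clip(g, -5.0, 5.0, out=g)
            self._adam_m[k] = cfg.beta1 * self._adam_m[k] + (1 - cfg.beta1) * g
            self._adam_v[k] = cfg.beta2 * self._adam_v[k] + (1 - cfg.beta2) * g * g
            self.params[k] -= (
                lr_t * self._adam_m[k] / (np.sqrt(self._adam_v[k]) + 1e-8)
            )

    def fit(self, corpus: list[str], epochs: int | None = None) -> list[float]:
        """Train on a SMILES corpus; returns per-epoch mean losses."""
        if not corpus:
            raise ConfigurationError("training corpus is empty")
        unknown = {ch for smi in corpus for ch in smi} - set(self.vocab)
        if unknown:
            raise ConfigurationError(
                f"corpus characters outside vocabulary: {sorted(unknown)}"
            )
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        losses = []
        for _epoch in range(epochs if epochs is not None else cfg.epochs):
            order = rng.permutation(len(corpus))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(corpus), cfg.batch_size):
                batch = [corpus[i] for i in order[start : start + cfg.batch_size]]
                tokens = self._encode_batch(batch)
                loss, caches, probs_list, mask = self._forward_batch(tokens)
                grads = self._backward_batch(tokens, caches, probs_list, mask)
                self._adam_step(grads)
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / n_batches)
        return losses

    def loss_on(self, corpus: list[str]) -> float:
        tokens = self._encode_batch(corpus)
        loss, _, _, _ = self._forward_batch(tokens)
        return float(loss)

    # -- sampling ----------------------------------------------------------
    def sample(self, n: int, seed: int = 0, temperature: float | None = None,
               max_len: int | None = None) -> list[str]:
        """Draw ``n`` SMILES strings autoregressively (seeded, batched)."""
        cfg = self.config
        temp = temperature if temperature is not None else cfg.temperature
        cap = max_len if max_len is not None else cfg.max_len
        rng = np.random.default_rng(seed)
        H, L = cfg.hidden, cfg.layers
        h = [np.zeros((n, H)) for _ in range(L)]
        c = [np.zeros((n, H)) for _ in range(L)]
        token = np.full(n, START, dtype=np.int64)
        finished = np.zeros(n, dtype=bool)
        out: list[list[str]] = [[] for _ in range(n)]
        for _t in range(cap):
            x = self.params["emb"][token]
            for layer in range(L):
                h[layer], c[layer], _ = self._step(layer, x, h[layer], c[layer])
                x = h[layer]
            logits = (x @ self.params["Wout"] + self.params["bout"]) / max(temp, 1e-6)
            logits[:, PAD] = -np.inf
            logits[:, START] = -np.inf
            shifted = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(shifted)
            probs /= probs.sum(axis=1, keepdims=True)
            cdf = probs.cumsum(axis=1)
            u = rng.random((n, 1))
            token = (u > cdf).sum(axis=1).astype(np.int64)
            for bi in range(n):
                if finished[bi]:
                    continue
                if token[bi] == END:
                    finished[bi] = True
                else:
                    out[bi].append(self.inv_vocab[int(token[bi])])
            if finished.all():
                break
        return ["".join(chars) for chars in out]

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: v for k, v in self.params.items()}
        arrays["_meta"] = np.frombuffer(
            json.dumps(
                {"vocab": self.vocab, "config": asdict(self.config)}
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SmilesLanguageModel":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        model = cls(meta["vocab"], GeneratorConfig(**meta["config"]))
        for k in model.params:
            model.params[k] = data[k]
        return model


def train_lm(
    corpus: list[str], config: GeneratorConfig | None = None
) -> SmilesLanguageModel:
    """Build the vocabulary from the corpus and fit a language model."""
    cfg = config or GeneratorConfig()
    model = SmilesLanguageModel(build_vocabulary(corpus), cfg)
    model.fit(corpus)
    return model


def sample_lm(model: SmilesLanguageModel, n: int, seed: int = 0) -> list[str]:
    return model.sample(n, seed=seed)


# ---------------------------------------------------------------------------
# Augmentation


def augment_smiles(smiles: str, k: int, seed: int = 0) -> list[str]:
    """``k`` randomized-atom-order SMILES variants of one structure.

    Every variant canonicalizes back to the input's canonical form.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    rng = np.random.default_rng(seed)
    out = []
    n = mol.GetNumAtoms()
    for _ in range(k):
        perm = rng.permutation(n).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


# ---------------------------------------------------------------------------
# Evaluation


DESCRIPTORS = {
    "molecular_weight": Descriptors.MolWt,
    "logp": Descriptors.MolLogP,
    "tpsa": Descriptors.TPSA,
    "fraction_sp3_carbons": rdMolDescriptors.CalcFractionCSP3,
    "fraction_heteroatoms": lambda m: sum(
        1 for a in m.GetAtoms() if a.GetSymbol() not in ("C", "H")
    )
    / max(m.GetNumAtoms(), 1),
    "ring_count": rdMolDescriptors.CalcNumRings,
    "qed": QED.qed,
    "bertz_ct": Descriptors.BertzCT,
}


@dataclass
class GenerationReport:
    n_samples: int
    pct_valid: float
    pct_unique: float
    pct_novel: float
    descriptor_summaries: dict[str, dict[str, float]] = field(default_factory=dict)


def evaluate_generation(
    samples: list[str], training_corpus: list[str]
) -> GenerationReport:
    """%valid / %unique / %novel and descriptor summaries of sampled SMILES.

    %novel is the fraction of *valid* molecules whose canonical form does
    not occur in the training corpus; descriptor summaries cover the
    valid molecules only.
    """
    if not samples:
        raise ConfigurationError("no samples to evaluate")
    train_canonical = set()
    for smi in training_corpus:
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            train_canonical.add(Chem.MolToSmiles(mol))
    valid_mols, valid_canonical = [], []
    for smi in samples:
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is not None:
            valid_mols.append(mol)
            valid_canonical.append(Chem.MolToSmiles(mol))
    n = len(samples)
    n_valid = len(valid_mols)
    pct_valid = 100.0 * n_valid / n
    pct_unique = 100.0 * len(set(valid_canonical)) / n_valid if n_valid else 0.0
    novel = [c for c in valid_canonical if c not in train_canonical]
    pct_novel = 100.0 * len(novel) / n_valid if n_valid else 0.0
    summaries = {}
    if valid_mols:
        for name, fn in DESCRIPTORS.items():
            values = np.array([fn(m) for m in valid_mols], dtype=float)
            summaries[name] = {
                "mean": float(values.mean()),
                "std": float(values.std()),
                "median": float(np.median(values)),
            }
    return GenerationReport(
        n_samples=n,
        pct_valid=pct_valid,
        pct_unique=pct_unique,
        pct_novel=pct_novel,
        descriptor_summaries=summaries,
    )


def descriptor_wasserstein(
    samples: list[str], reference: list[str]
) -> dict[str, float]:
    """Per-descriptor Wasserstein distance between two SMILES sets."""
    from scipy.stats import wasserstein_distance

    def values(smiles_list, fn):
        out = []
        for smi in smiles_list:
            mol = Chem.MolFromSmiles(smi) if smi else None
            if mol is not None:
                out.append(fn(mol))
        return np.array(out, dtype=float)

    result = {}
    for name, fn in DESCRIPTORS.items():
        a, b = values(samples, fn), values(reference, fn)
        if len(a) and len(b):
            result[name] = float(wasserstein_distance(a, b))
    return result
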