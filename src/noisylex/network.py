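"""Deep bimodal autoencoder mapping phonological forms and semantics.

The architecture has a phonological pathway (292-bit input -> P0 -> P1) and
a semantic pathway (300-bit input -> S1) meeting in a shared bottleneck
layer PS2, from which two decoder branches reconstruct phonology
(PS2 -> P3 -> phonology output) and semantics (PS2 -> S3 -> S4 -> semantics
output).  All units are logistic sigmoids and outputs are trained with
binary cross-entropy against clean binary targets.

Training combines greedy layerwise pretraining of the encoder stack with
denoising fine-tuning in which each presentation draws one of three mapping
types — phonology-to-phonology, semantics-to-semantics, or both presented
simultaneously — corrupts the presented input(s) with Gaussian noise, and
updates the weights toward the uncorrupted target(s).  Word presentations
are drawn under an exposure ratio between the two languages (e.g. 3:1),
which differentiates "native" from "non-native" model versions while
keeping the total number of presentations identical.

The network never receives explicit phonology-to-semantics training; the
cross-modal mapping used to model spoken-word recognition emerges through
the shared bottleneck.  At test time the semantic input is zeroed and the
semantics generated at the output layer is read out.

Implemented directly in NumPy (batched forward/backward passes, SGD with
momentum); the model is small enough that no GPU framework is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .lexicon import BilingualLexicon, PHON_BITS, SEM_BITS

__all__ = ["ArchitectureSpec", "Model", "build_model", "pretrain", "finetune",
           "forward", "save_checkpoint", "load_checkpoint"]

SNAPSHOT_LAYERS = ("input_phon", "P0", "PS2", "S4", "output_sem")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizes and initialization seed for the autoencoder."""

    phon_dim: int = PHON_BITS
    sem_dim: int = SEM_BITS
    p0: int = 200
    p1: int = 120
    ps2: int = 80
    s1: int = 200
    p3: int = 200
    s3: int = 120
    s4: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (self.phon_dim, self.sem_dim, self.p0, self.p1, self.ps2,
                 self.s1, self.p3, self.s3, self.s4)
        if any(s <= 0 for s in sizes):
            raise ValueError("all layer sizes must be positive")
        if not (self.ps2 < self.phon_dim and self.ps2 < self.sem_dim):
            raise ValueError(
                f"bottleneck size {self.ps2} must be smaller than both input "
                f"sizes ({self.phon_dim}, {self.sem_dim})"
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


# weight names: (input size key, output size key)
_LAYER_DEFS = {
    "p0": ("phon_dim", "p0"),
    "p1": ("p0", "p1"),
    "s1": ("sem_dim", "s1"),
    "ps2_p": ("p1", "ps2"),
    "ps2_s": ("s1", "ps2"),
    "p3": ("ps2", "p3"),
    "phon_out": ("p3", "phon_dim"),
    "s3": ("ps2", "s3"),
    "s4": ("s3", "s4"),
    "sem_out": ("s4", "sem_dim"),
}
# ps2_p and ps2_s share the single ps2 bias
_BIAS_DIMS = {
    "p0": "p0", "p1": "p1", "s1": "s1", "ps2": "ps2", "p3": "p3",
    "phon_out": "phon_dim", "s3": "s3", "s4": "s4", "sem_out": "sem_dim",
}


@dataclass
class Model:
    """Autoencoder weights plus training provenance.

    ``training_log`` holds one dict per fine-tuning epoch (losses by mapping
    type, per-language presentation counts); ``pretrain_log`` one dict per
    layerwise pretraining stage.
    """

    arch: ArchitectureSpec
    W: dict[str, np.ndarray]
    b: dict[str, np.ndarray]
    exposure_ratio: tuple[float, float] | None = None
    seed: int | None = None
    training_log: list[dict] = field(default_factory=list)
    pretrain_log: list[dict] = field(default_factory=list)

    def copy(self) -> "Model":
        return Model(
            arch=self.arch,
            W={k: v.copy() for k, v in self.W.items()},
            b={k: v.copy() for k, v in self.b.items()},
            exposure_ratio=self.exposure_ratio,
            seed=self.seed,
            training_log=[dict(d) for d in self.training_log],
            pretrain_log=[dict(d) for d in self.pretrain_log],
        )

    @property
    def total_presentations(self) -> int:
        return int(sum(d["n_presentations"] for d in self.training_log))

    def forward(self, phon: np.ndarray, sem: np.ndarray) -> dict[str, np.ndarray]:
        return forward(self, phon, sem)


def build_model(arch: ArchitectureSpec) -> Model:
    """Initialize an untrained model reproducibly from ``arch.seed``."""
    rng = np.random.default_rng(arch.seed)
    sizes = asdict(arch)
    W = {name: _glorot(rng, sizes[i], sizes[o]) for name, (i, o) in _LAYER_DEFS.items()}
    b = {name: np.zeros(sizes[dim]) for name, dim in _BIAS_DIMS.items()}
    return Model(arch=arch, W=W, b=b, seed=arch.seed)


def forward(model: Model, phon: np.ndarray, sem: np.ndarray) -> dict[str, np.ndarray]:
    """Deterministic forward pass; returns activations for every layer.

    ``phon`` and ``sem`` may be single vectors or (batch, dim) matrices and
    may be real-valued (noisified binary).  Zeroing one input pathway is
    the test regime for cross-modal readout.
    """
    phon = np.atleast_2d(np.asarray(phon, dtype=float))
    sem = np.atleast_2d(np.asarray(sem, dtype=float))
    if phon.shape[-1] != model.arch.phon_dim:
        raise ValueError(f"phon input must have {model.arch.phon_dim} entries")
    if sem.shape[-1] != model.arch.sem_dim:
        raise ValueError(f"sem input must have {model.arch.sem_dim} entries")
    W, b = model.W, model.b
    a_p0 = _sigmoid(phon @ W["p0"] + b["p0"])
    a_p1 = _sigmoid(a_p0 @ W["p1"] + b["p1"])
    a_s1 = _sigmoid(sem @ W["s1"] + b["s1"])
    a_ps2 = _sigmoid(a_p1 @ W["ps2_p"] + a_s1 @ W["ps2_s"] + b["ps2"])
    a_p3 = _sigmoid(a_ps2 @ W["p3"] + b["p3"])
    out_phon = _sigmoid(a_p3 @ W["phon_out"] + b["phon_out"])
    a_s3 = _sigmoid(a_ps2 @ W["s3"] + b["s3"])
    a_s4 = _sigmoid(a_s3 @ W["s4"] + b["s4"])
    out_sem = _sigmoid(a_s4 @ W["sem_out"] + b["sem_out"])
    return {
        "input_phon": phon, "input_sem": sem,
        "P0": a_p0, "P1": a_p1, "S1": a_s1, "PS2": a_ps2,
        "P3": a_p3, "S3": a_s3, "S4": a_s4,
        "output_phon": out_phon, "output_sem": out_sem,
    }


def _bce(pred: np.ndarray, target: np.ndarray) -> float:
    eps = 1e-9
    return float(-np.mean(target * np.log(pred + eps) + (1 - target) * np.log(1 - pred + eps)))


class _SGD:
    def __init__(self, lr: float, momentum: float):
        self.lr, self.momentum = lr, momentum
        self.vel: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            v = self.vel.get(k)
            v = self.momentum * v - self.lr * g if v is not None else -self.lr * g
            self.vel[k] = v
            params[k] += v


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            m = self.m.get(k, 0.0) * self.b1 + (1 - self.b1) * g
            v = self.v.get(k, 0.0) * self.b2 + (1 - self.b2) * g * g
            self.m[k], self.v[k] = m, v
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _backward(model: Model, acts: Mapping[str, np.ndarray],
              phon_target: np.ndarray, sem_target: np.ndarray,
              mask_phon: np.ndarray, mask_sem: np.ndarray
              ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Gradients of masked BCE w.r.t. all weights and biases.

    ``mask_phon``/``mask_sem`` are per-sample 0/1 indicators of which output
    pathways carry loss for that presentation.
    """
    W = model.W
    n = acts["input_phon"].shape[0]
    gW: dict[str, np.ndarray] = {}
    gb: dict[str, np.ndarray] = {}

    # sigmoid + BCE: delta at outputs is (pred - target)
    d_out_phon = (acts["output_phon"] - phon_target) * mask_phon[:, None] / n
    d_out_sem = (acts["output_sem"] - sem_target) * mask_sem[:, None] / n

    gW["phon_out"] = acts["P3"].T @ d_out_phon
    gb["phon_out"] = d_out_phon.sum(0)
    d_p3 = (d_out_phon @ W["phon_out"].T) * acts["P3"] * (1 - acts["P3"])
    gW["p3"] = acts["PS2"].T @ d_p3
    gb["p3"] = d_p3.sum(0)

    gW["sem_out"] = acts["S4"].T @ d_out_sem
    gb["sem_out"] = d_out_sem.sum(0)
    d_s4 = (d_out_sem @ W["sem_out"].T) * acts["S4"] * (1 - acts["S4"])
    gW["s4"] = acts["S3"].T @ d_s4
    gb["s4"] = d_s4.sum(0)
    d_s3 = (d_s4 @ W["s4"].T) * acts["S3"] * (1 - acts["S3"])
    gW["s3"] = acts["PS2"].T @ d_s3
    gb["s3"] = d_s3.sum(0)

    d_ps2_in = d_p3 @ W["p3"].T + d_s3 @ W["s3"].T
    d_ps2 = d_ps2_in * acts["PS2"] * (1 - acts["PS2"])
    gW["ps2_p"] = acts["P1"].T @ d_ps2
    gW["ps2_s"] = acts["S1"].T @ d_ps2
    gb["ps2"] = d_ps2.sum(0)

    d_p1 = (d_ps2 @ W["ps2_p"].T) * acts["P1"] * (1 - acts["P1"])
    gW["p1"] = acts["P0"].T @ d_p1
    gb["p1"] = d_p1.sum(0)
    d_p0 = (d_p1 @ W["p1"].T) * acts["P0"] * (1 - acts["P0"])
    gW["p0"] = acts["input_phon"].T @ d_p0
    gb["p0"] = d_p0.sum(0)

    d_s1 = (d_ps2 @ W["ps2_s"].T) * acts["S1"] * (1 - acts["S1"])
    gW["s1"] = acts["input_sem"].T @ d_s1
    gb["s1"] = d_s1.sum(0)
    return gW, gb


# -- layerwise pretraining -------------------------------------------------

def _pretrain_layer(rng: np.random.Generator, X: np.ndarray, W: np.ndarray,
                    b: np.ndarray, epochs: int, lr: float
                    ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Train one encoder layer as a shallow autoencoder on data X, in place.

    Returns (hidden activations of X, updated bias, initial loss, final loss).
    """
    n_in, n_hid = W.shape
    W_dec = _glorot(rng, n_hid, n_in)
    b_dec = np.zeros(n_in)
    opt = _SGD(lr=lr, momentum=0.9)
    first = last = np.nan
    n = X.shape[0]
    batch = 32
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            xb = X[order[start : start + batch]]
            h = _sigmoid(xb @ W + b)
            rec = _sigmoid(h @ W_dec + b_dec)
            losses.append(_bce(rec, xb))
            d_rec = (rec - xb) / xb.shape[0]
            d_h = (d_rec @ W_dec.T) * h * (1 - h)
            grads = {"W": xb.T @ d_h, "b": d_h.sum(0),
                     "W_dec": h.T @ d_rec, "b_dec": d_rec.sum(0)}
            opt.step({"W": W, "b": b, "W_dec": W_dec, "b_dec": b_dec}, grads)
        loss = float(np.mean(losses))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite pretraining loss at epoch {epoch}")
        if epoch == 0:
            first = loss
        last = loss
    H = _sigmoid(X @ W + b)
    return H, b, first, last


def pretrain(model: Model, lexicon: BilingualLexicon, epochs: int = 50,
             lr: float = 0.1, seed: int = 0) -> Model:
    """Greedy layerwise pretraining of the encoder stack.

    Successive encoder layers (P0, P1, S1, then the shared PS2 on the
    concatenated penultimate activations) are each trained as shallow
    autoencoders on the activations produced by the layers below.  The
    temporary decoders are discarded.  ``epochs=0`` is a no-op.
    """
    model = model.copy()
    if epochs == 0:
        return model
    rng = np.random.default_rng(seed)
    P = np.concatenate([lexicon.phon_matrix("A"), lexicon.phon_matrix("B")]).astype(float)
    S = np.concatenate([lexicon.sem_matrix("A"), lexicon.sem_matrix("B")]).astype(float)

    H_p0, _, f0, l0 = _pretrain_layer(rng, P, model.W["p0"], model.b["p0"], epochs, lr)
    H_p1, _, f1, l1 = _pretrain_layer(rng, H_p0, model.W["p1"], model.b["p1"], epochs, lr)
    H_s1, _, f2, l2 = _pretrain_layer(rng, S, model.W["s1"], model.b["s1"], epochs, lr)
    # shared bottleneck: one weight matrix over [P1, S1], then split back
    W_cat = np.concatenate([model.W["ps2_p"], model.W["ps2_s"]])
    H_cat = np.concatenate([H_p1, H_s1], axis=1)
    _, _, f3, l3 = _pretrain_layer(rng, H_cat, W_cat, model.b["ps2"], epochs, lr)
    model.W["ps2_p"] = W_cat[: model.arch.p1]
    model.W["ps2_s"] = W_cat[model.arch.p1 :]

    for name, first, last in [("P0", f0, l0), ("P1", f1, l1),
                              ("S1", f2, l2), ("PS2", f3, l3)]:
        model.pretrain_log.append(
            {"layer": name, "epochs": epochs, "loss_first": first, "loss_last": last}
        )
    return model


# -- denoising fine-tuning -------------------------------------------------

PHASES = ("p", "s", "ps")  # phon->phon, sem->sem, both->both

# default fine-tuning budget in total word presentations (= 1500 epochs on
# the default 121-pair / 242-lexeme vocabulary)
DEFAULT_PRESENTATIONS = 1500 * 242


def finetune(
    model: Model,
    lexicon: BilingualLexicon,
    exposure_ratio: tuple[float, float] = (1.0, 1.0),
    phases_schedule: str = "interleaved",
    corruption_sd: float = 0.1,
    sem_mask_frac: float = 0.9,
    epochs: int | None = None,
    lr: float = 0.03,
    lr_decay: float = 0.3,
    momentum: float = 0.9,
    optimizer: str = "sgd",
    batch_size: int = 64,
    seed: int = 0,
) -> Model:
    """Denoising fine-tuning under an exposure ratio between the languages.

    Each presentation draws a word with probability proportional to its
    language's exposure weight (uniform within language), draws one of the
    three mapping types, corrupts the presented input(s), and updates all
    weights toward reconstructing the uncorrupted target(s).  One epoch
    comprises as many presentations as there are lexemes, so the total
    presentation count is identical across exposure-ratio settings at fixed
    ``epochs``.  When ``epochs`` is None the default budget is a fixed
    total of ``DEFAULT_PRESENTATIONS`` word presentations (at least 1500
    epochs), so small lexicons are trained as thoroughly as large ones.

    Corruption is additive Gaussian noise of ``corruption_sd`` on every
    presented input, plus masking noise on the semantic input: each
    presented semantic entry is zeroed with probability ``sem_mask_frac``.
    The masking component is what makes the bottleneck robust to an absent
    semantic pathway and thereby lets the phonology-to-semantics mapping
    emerge without ever being trained explicitly: the network learns to
    reproduce full semantics from presentations in which the semantic
    evidence is almost entirely removed, so at test time (semantic input
    all zero) the shared-bottleneck states still decode to the right
    semantics.

    ``phases_schedule``: "interleaved" cycles the three mapping types every
    presentation (exactly 1/3 each); "blocked" runs them in three
    consecutive blocks of epochs.
    """
    wa, wb = float(exposure_ratio[0]), float(exposure_ratio[1])
    for lang, w in (("A", wa), ("B", wb)):
        if lexicon.words(lang) and w <= 0:
            raise ValueError(f"zero exposure weight for language {lang} present in lexicon")
    if phases_schedule not in ("interleaved", "blocked"):
        raise ValueError(f"unknown phases_schedule {phases_schedule!r}")

    model = model.copy()
    model.exposure_ratio = (wa, wb)
    model.seed = seed
    rng = np.random.default_rng(seed)

    P_A, P_B = lexicon.phon_matrix("A").astype(float), lexicon.phon_matrix("B").astype(float)
    S_A, S_B = lexicon.sem_matrix("A").astype(float), lexicon.sem_matrix("B").astype(float)
    P = np.concatenate([P_A, P_B])
    S = np.concatenate([S_A, S_B])
    n_a, n_b = P_A.shape[0], P_B.shape[0]
    p_lang_a = wa / (wa + wb)

    n_per_epoch = n_a + n_b
    if epochs is None:
        epochs = max(1500, round(DEFAULT_PRESENTATIONS / n_per_epoch))
    if optimizer == "sgd":
        opt: _SGD | _Adam = _SGD(lr=lr, momentum=momentum)
    elif optimizer == "adam":
        opt = _Adam(lr=lr)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    pres_index = 0
    best_loss = np.inf
    n_bad, n_decays = 0, 0
    for epoch in range(epochs):
        # draw this epoch's presentations
        from_a = rng.random(n_per_epoch) < p_lang_a
        idx = np.where(
            from_a,
            rng.integers(0, n_a, size=n_per_epoch),
            n_a + rng.integers(0, n_b, size=n_per_epoch),
        )
        if phases_schedule == "interleaved":
            phase_ids = (pres_index + np.arange(n_per_epoch)) % 3
        else:
            phase_ids = np.full(n_per_epoch, min(epoch * 3 // max(epochs, 1), 2))
        pres_index += n_per_epoch

        epoch_losses: dict[str, list[float]] = {ph: [] for ph in PHASES}
        for start in range(0, n_per_epoch, batch_size):
            sl = slice(start, start + batch_size)
            rows, phases = idx[sl], phase_ids[sl]
            phon_t, sem_t = P[rows], S[rows]
            use_phon = (phases != 1).astype(float)  # phases 0 ('p') and 2 ('ps')
            use_sem = (phases != 0).astype(float)   # phases 1 ('s') and 2 ('ps')
            phon_in = phon_t * use_phon[:, None]
            sem_in = sem_t * use_sem[:, None]
            if corruption_sd > 0:
                phon_in = phon_in + rng.normal(0, corruption_sd, phon_in.shape) \
                    * use_phon[:, None]
                sem_in = sem_in + rng.normal(0, corruption_sd, sem_in.shape) \
                    * use_sem[:, None]
            if sem_mask_frac > 0:
                sem_in = sem_in * (rng.random(sem_in.shape) >= sem_mask_frac)
            acts = forward(model, phon_in, sem_in)
            gW, gb = _backward(model, acts, phon_t, sem_t, use_phon, use_sem)
            params = {f"W.{k}": v for k, v in model.W.items()}
            params.update({f"b.{k}": v for k, v in model.b.items()})
            grads = {f"W.{k}": v for k, v in gW.items()}
            grads.update({f"b.{k}": v for k, v in gb.items()})
            opt.step(params, grads)
            for ph_id, name in enumerate(PHASES):
                m = phases == ph_id
                if not m.any():
                    continue
                loss = 0.0
                if name in ("p", "ps"):
                    loss += _bce(acts["output_phon"][m], phon_t[m])
                if name in ("s", "ps"):
                    loss += _bce(acts["output_sem"][m], sem_t[m])
                epoch_losses[name].append(loss)

        mean_losses = {ph: float(np.mean(v)) if v else np.nan
                       for ph, v in epoch_losses.items()}
        if any(not np.isfinite(l) for l in mean_losses.values() if not np.isnan(l)):
            raise RuntimeError(f"non-finite fine-tuning loss at epoch {epoch}")
        # adaptive step decay: long runs can destabilize late in training;
        # back the learning rate off when the epoch loss deteriorates
        total = float(np.nansum(list(mean_losses.values())))
        if total < best_loss:
            best_loss, n_bad = total, 0
        elif total > 1.3 * best_loss:
            n_bad += 1
            if n_bad >= 3 and n_decays < 3 and lr_decay != 1.0 \
                    and isinstance(opt, _SGD):
                opt.lr *= lr_decay
                n_decays += 1
                n_bad = 0
        model.training_log.append({
            "epoch": epoch,
            "n_presentations": n_per_epoch,
            **{f"loss_{ph}": mean_losses[ph] for ph in PHASES},
            "n_lang_a": int(from_a.sum()),
            "n_lang_b": int(n_per_epoch - from_a.sum()),
        })
    return model


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: Model, path: str | Path) -> None:
    """Write weights + architecture + provenance to an .npz container."""
    path = Path(path)
    meta = {
        "arch": asdict(model.arch),
        "exposure_ratio": model.exposure_ratio,
        "seed": model.seed,
        "training_log": model.training_log,
        "pretrain_log": model.pretrain_log,
    }
    arrays = {f"W.{k}": v for k, v in model.W.items()}
    arrays.update({f"b.{k}": v for k, v in model.b.items()})
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> Model:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        W = {k[2:]: data[k] for k in data.files if k.startswith("W.")}
        b = {k[2:]: data[k] for k in data.files if k.startswith("b.")}
    ratio = meta["exposure_ratio"]
    return Model(
        arch=ArchitectureSpec(**meta["arch"]),
        W=W, b=b,
        exposure_ratio=tuple(ratio) if ratio else None,
        seed=meta["seed"],
        training_log=meta["training_log"],
        pretrain_log=meta["pretrain_log"],
    )
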