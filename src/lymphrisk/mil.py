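"""Gated-attention multiple-instance learning for slide-level classification.

A slide is a bag ``X = {x_1, ..., x_M}`` of 256-d patch features carrying a
single binary label. Each instance is compressed through two
fully-connected + ReLU + dropout blocks to ``h_i in R^128``; a gated
attention module scores each instance,

    A_i = softmax_i( w_a ( tanh(V_a h_i^T) (*) sigmoid(U_a h_i^T) ) ),

with ``U_a, V_a in R^{64x128}`` and ``w_a in R^{1x64}``; the slide embedding
is the attention-weighted average ``H = sum_i A_i h_i``, classified by an
affine 128->2 head with softmax. Training minimises slide-level
cross-entropy by backpropagation, one bag per step, with early stopping on
validation AUROC.

The forward and backward passes are written explicitly in NumPy; the
analytic gradients are validated against central finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .encode import FeatureBag, FEATURE_DIM
from .nn import Adam, clip_grads, he_init, softmax, stable_softmax_vec

__all__ = [
    "MILParams",
    "MILHyper",
    "compress",
    "attention_scores",
    "pool",
    "classify_slide",
    "forward_bag",
    "bag_loss_and_grads",
    "train_mil",
    "AttentionMIL",
    "AttentionMILResults",
    "save_mil_params",
    "load_mil_params",
]

HIDDEN_DIM = 128
ATT_DIM = 64


@dataclass
class MILParams:
    """All learnable arrays of the slide classifier."""

    W1: np.ndarray  # (128, 256)
    b1: np.ndarray  # (128,)
    W2: np.ndarray  # (128, 128)
    b2: np.ndarray  # (128,)
    U_a: np.ndarray  # (64, 128) sigmoid gate
    V_a: np.ndarray  # (64, 128) tanh branch
    w_a: np.ndarray  # (1, 64)
    Wc: np.ndarray  # (2, 128)
    bc: np.ndarray  # (2,)
    dropout_rate: float = 0.25
    seed: int = 0

    def copy(self) -> "MILParams":
        return MILParams(
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            k: v for k, v in self.__dict__.items() if isinstance(v, np.ndarray)
        }

    @classmethod
    def init(cls, seed: int = 0, dropout_rate: float = 0.25) -> "MILParams":
        rng = np.random.default_rng(seed)
        return cls(
            W1=he_init(rng, (HIDDEN_DIM, FEATURE_DIM)),
            b1=np.zeros(HIDDEN_DIM),
            W2=he_init(rng, (HIDDEN_DIM, HIDDEN_DIM)),
            b2=np.zeros(HIDDEN_DIM),
            U_a=he_init(rng, (ATT_DIM, HIDDEN_DIM)),
            V_a=he_init(rng, (ATT_DIM, HIDDEN_DIM)),
            w_a=he_init(rng, (1, ATT_DIM)),
            Wc=he_init(rng, (2, HIDDEN_DIM)),
            bc=np.zeros(2),
            dropout_rate=dropout_rate,
            seed=seed,
        )


@dataclass
class MILHyper:
    """Optimisation hyperparameters (the attention equations fix the model)."""

    lr: float = 1e-4
    epochs: int = 200
    weight_decay: float = 1e-5
    dropout_rate: float = 0.25
    patience: int = 20
    seed: int = 0


# ---------------------------------------------------------------------------
# forward pieces
# ---------------------------------------------------------------------------


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {what}")


def compress(
    bag: FeatureBag | np.ndarray,
    params: MILParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Instance compression 256 -> 128 -> 128 (two FC+ReLU+dropout blocks)."""
    X = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag, float)
    _check_finite(X, "input bag")
    h = np.maximum(X @ params.W1.T + params.b1, 0.0)
    if train_mode and params.dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        h = h * (rng.random(h.shape) >= params.dropout_rate) / (1 - params.dropout_rate)
    h = np.maximum(h @ params.W2.T + params.b2, 0.0)
    if train_mode and params.dropout_rate > 0:
        h = h * (rng.random(h.shape) >= params.dropout_rate) / (1 - params.dropout_rate)
    return h


def attention_scores(h: np.ndarray, params: MILParams) -> np.ndarray:
    """Gated attention: softmax over w_a.(tanh(V_a h^T) (*) sigmoid(U_a h^T))."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[0] == 0:
        raise ValueError("empty bag: attention is undefined for M = 0")
    t = np.tanh(h @ params.V_a.T)  # (M, 64)
    s = 1.0 / (1.0 + np.exp(-(h @ params.U_a.T)))  # (M, 64)
    e = (t * s) @ params.w_a.ravel()  # (M,)
    return stable_softmax_vec(e)


def pool(A: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Slide embedding H = sum_i A_i h_i."""
    A = np.asarray(A, dtype=float).ravel()
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if len(A) != len(h):
        raise ValueError(f"attention length {len(A)} != bag size {len(h)}")
    return A @ h


def classify_slide(H: np.ndarray, params: MILParams) -> float:
    """P(label = 1) from the slide embedding via affine 128->2 + softmax."""
    _check_finite(np.asarray(H, float), "slide embedding")
    logits = params.Wc @ np.asarray(H, dtype=float) + params.bc
    return float(softmax(logits)[1])


def forward_bag(bag: FeatureBag | np.ndarray, params: MILParams) -> dict:
    """Deterministic (eval-mode) forward pass; returns all intermediates."""
    h = compress(bag, params, train_mode=False)
    A = attention_scores(h, params)
    H = pool(A, h)
    logits = params.Wc @ H + params.bc
    p = softmax(logits)
    return {"h": h, "A": A, "H": H, "logits": logits, "proba": float(p[1])}


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------


def branch_forward_cache(
    X: np.ndarray,
    params: MILParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Forward pass of the image branch (compression + attention + pooling),
    retaining every intermediate needed for backpropagation."""
    X = np.asarray(X, dtype=float)
    keep = 1.0 - params.dropout_rate if train_mode and params.dropout_rate > 0 else 1.0
    use_drop = keep < 1.0
    if use_drop and rng is None:
        rng = np.random.default_rng(params.seed)

    z1 = X @ params.W1.T + params.b1
    a1 = np.maximum(z1, 0.0)
    m1 = (rng.random(a1.shape) >= params.dropout_rate) if use_drop else None
    d1 = a1 * m1 / keep if use_drop else a1
    z2 = d1 @ params.W2.T + params.b2
    a2 = np.maximum(z2, 0.0)
    m2 = (rng.random(a2.shape) >= params.dropout_rate) if use_drop else None
    h = a2 * m2 / keep if use_drop else a2

    t = np.tanh(h @ params.V_a.T)
    s = 1.0 / (1.0 + np.exp(-(h @ params.U_a.T)))
    g = t * s
    e = g @ params.w_a.ravel()
    A = stable_softmax_vec(e)
    H = A @ h
    return {
        "X": X, "z1": z1, "m1": m1, "d1": d1, "z2": z2, "m2": m2, "h": h,
        "t": t, "s": s, "g": g, "A": A, "H": H, "keep": keep, "use_drop": use_drop,
    }


def branch_backward_from_dH(
    cache: dict, params: MILParams, dH: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of the image-branch parameters given dLoss/dH.

    Backward mirrors the forward chain: pooling -> softmax attention ->
    gated branches -> the two compression blocks (dropout masks replayed
    exactly)."""
    X, h, t, s, g, A = (cache[k] for k in ("X", "h", "t", "s", "g", "A"))
    keep, use_drop = cache["keep"], cache["use_drop"]

    dA = h @ dH  # (M,)
    dh = np.outer(A, dH)  # pooling path
    de = A * (dA - float(A @ dA))  # softmax Jacobian-vector product
    dg = np.outer(de, params.w_a.ravel())  # (M, 64)
    gwa = (de @ g)[None, :]  # (1, 64)
    dt = dg * s
    ds = dg * t
    dzv = dt * (1.0 - t * t)  # pre-activation of tanh branch
    dzu = ds * s * (1.0 - s)  # pre-activation of sigmoid gate
    gVa = dzv.T @ h
    gUa = dzu.T @ h
    dh += dzv @ params.V_a + dzu @ params.U_a

    da2 = dh * cache["m2"] / keep if use_drop else dh
    dz2 = da2 * (cache["z2"] > 0)
    gW2 = dz2.T @ cache["d1"]
    gb2 = dz2.sum(axis=0)
    dd1 = dz2 @ params.W2
    da1 = dd1 * cache["m1"] / keep if use_drop else dd1
    dz1 = da1 * (cache["z1"] > 0)
    gW1 = dz1.T @ X
    gb1 = dz1.sum(axis=0)

    return {
        "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
        "U_a": gUa, "V_a": gVa, "w_a": gwa,
    }


def bag_loss_and_grads(
    X: np.ndarray,
    label: int,
    params: MILParams,
    train_mode: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy loss of one bag and analytic gradients for every array."""
    cache = branch_forward_cache(X, params, train_mode=train_mode, rng=rng)
    H = cache["H"]
    logits = params.Wc @ H + params.bc
    p = softmax(logits)
    loss = -float(np.log(max(p[label], 1e-300)))

    dlogits = p.copy()
    dlogits[label] -= 1.0
    grads = branch_backward_from_dH(cache, params, params.Wc.T @ dlogits)
    grads["Wc"] = np.outer(dlogits, H)
    grads["bc"] = dlogits
    return loss, grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _auroc(y: np.ndarray, scores: np.ndarray) -> float:
    # local rank-based AUROC to avoid circular import with evaluate
    from scipy.stats import rankdata

    y = np.asarray(y)
    r = rankdata(scores)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def train_mil(
    bags: list[FeatureBag],
    labels: np.ndarray,
    hyper: MILHyper | None = None,
    val_bags: list[FeatureBag] | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[MILParams, dict]:
    """Fit the attention MIL classifier from slide labels only.

    One bag per gradient step (Adam, weight decay), epoch order shuffled by
    a seeded generator. When a validation set is given, the parameters of
    the epoch with the best validation AUROC are returned (early stopping
    after ``patience`` epochs without improvement; ties keep the earliest
    epoch). Fully reproducible given ``hyper.seed``.
    """
    hyper = hyper or MILHyper()
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(bags) != len(labels):
        raise ValueError("bags and labels must align")
    if hyper.epochs > 0 and len(classes) < 2:
        raise ValueError("training requires slides of both classes")

    params = MILParams.init(seed=hyper.seed, dropout_rate=hyper.dropout_rate)
    if hyper.epochs == 0:
        return params, {"epochs_run": 0, "history": []}

    rng = np.random.default_rng(hyper.seed)
    opt = Adam(params.arrays(), lr=hyper.lr, weight_decay=hyper.weight_decay)
    best = {"auroc": -np.inf, "epoch": -1, "params": params.copy()}
    history = []
    stale = 0
    for epoch in range(hyper.epochs):
        order = rng.permutation(len(bags))
        total = 0.0
        for i in order:
            loss, grads = bag_loss_and_grads(
                bags[i].features, int(labels[i]), params, train_mode=True, rng=rng
            )
            opt.step(params.arrays(), clip_grads(grads))
            total += loss
        entry = {"epoch": epoch, "train_loss": total / len(bags)}
        if val_bags is not None and val_labels is not None and len(val_bags) > 0:
            scores = np.array([forward_bag(b, params)["proba"] for b in val_bags])
            entry["val_auroc"] = _auroc(np.asarray(val_labels, int), scores)
            if entry["val_auroc"] > best["auroc"]:  # strict: ties keep earliest
                best = {
                    "auroc": entry["val_auroc"],
                    "epoch": epoch,
                    "params": params.copy(),
                }
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if val_bags is not None and stale > hyper.patience:
            break

    log = {"epochs_run": len(history), "history": history}
    if best["epoch"] >= 0:
        log["best_epoch"] = best["epoch"]
        log["best_val_auroc"] = best["auroc"]
        return best["params"], log
    return params, log


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class AttentionMIL:
    """Slide-level weakly supervised classifier (gated-attention MIL).

    Parameters
    ----------
    bags, labels
        Training bags and their binary slide labels.
    val_bags, val_labels
        Optional validation split used for early stopping / model selection.
    """

    def __init__(self, bags, labels, val_bags=None, val_labels=None):
        self.bags = list(bags)
        self.labels = np.asarray(labels, dtype=int)
        self.val_bags = list(val_bags) if val_bags is not None else None
        self.val_labels = (
            np.asarray(val_labels, dtype=int) if val_labels is not None else None
        )

    def fit(self, **hyper_kwargs) -> "AttentionMILResults":
        hyper = MILHyper(**hyper_kwargs)
        params, log = train_mil(
            self.bags, self.labels, hyper, self.val_bags, self.val_labels
        )
        return AttentionMILResults(self, params, hyper, log)


@dataclass
class AttentionMILResults:
    model: AttentionMIL
    params: MILParams
    hyper: MILHyper
    log: dict = field(default_factory=dict)

    def predict_proba(self, bags) -> np.ndarray:
        return np.array([forward_bag(b, self.params)["proba"] for b in bags])

    def attention(self, bag) -> np.ndarray:
        return forward_bag(bag, self.params)["A"]

    def summary(self) -> str:
        lines = [
            "Gated-Attention MIL slide classifier",
            "=" * 44,
            f"training slides       {len(self.model.bags)}",
            f"epochs run            {self.log.get('epochs_run', 0)}",
        ]
        if "best_epoch" in self.log:
            lines.append(f"selected epoch        {self.log['best_epoch']}")
            lines.append(f"validation AUROC      {self.log['best_val_auroc']:.4f}")
        n_par = sum(v.size for v in self.params.arrays().values())
        lines.append(f"parameters            {n_par}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_mil_params(params: MILParams, path: str, hyper: MILHyper | None = None) -> None:
    """Single-file archive of named arrays + JSON hyperparameter header."""
    header = {"dropout_rate": params.dropout_rate, "seed": params.seed}
    if hyper is not None:
        header["hyper"] = asdict(hyper)
    np.savez(
        path,
        __header__=np.frombuffer(
            json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
        ),
        **params.arrays(),
    )


def load_mil_params(path: str) -> MILParams:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__header__"}
    return MILParams(
        **arrays,
        dropout_rate=float(header.get("dropout_rate", 0.25)),
        seed=int(header.get("seed", 0)),
    )
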