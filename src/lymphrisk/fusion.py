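"""Multimodal fusion of slide and clinical representations via compact
bilinear pooling (CBP).

The 128-d attention-pooled slide embedding and a 128-d MLP embedding of the
clinical design vector are each count-sketched into R^d (random hash +
random sign, fixed once per model); their bilinear (outer-product)
interaction is approximated by the circular convolution of the two
sketches, computed in the Fourier domain. Standard CBP post-processing
(signed square root, then L2 normalisation) is applied before the final
affine d->2 classifier. Training is joint end-to-end backpropagation
through both branches; the sketch hashes are fixed, not learned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .encode import FeatureBag
from .mil import (
    MILParams,
    branch_backward_from_dH,
    branch_forward_cache,
)
from .nn import Adam, clip_grads, he_init, softmax

__all__ = [
    "CountSketchSpec",
    "FusionParams",
    "FusionHyper",
    "count_sketch",
    "embed_clinical",
    "cbp_fuse",
    "classify_fused",
    "forward_fused",
    "train_fusion",
    "FusionClassifier",
    "FusionClassifierResults",
    "save_fusion_params",
    "load_fusion_params",
]

EMBED_DIM = 128
DEFAULT_SKETCH_DIM = 4096


@dataclass
class CountSketchSpec:
    """Random hash/sign pair defining one count-sketch projection."""

    input_dim: int
    output_dim: int
    h: np.ndarray  # (input_dim,) ints in [0, output_dim)
    s: np.ndarray  # (input_dim,) entries in {-1, +1}
    seed: int = 0

    @classmethod
    def draw(cls, input_dim: int, output_dim: int, seed: int) -> "CountSketchSpec":
        rng = np.random.default_rng(seed)
        return cls(
            input_dim=input_dim,
            output_dim=output_dim,
            h=rng.integers(0, output_dim, size=input_dim),
            s=rng.choice(np.array([-1.0, 1.0]), size=input_dim),
            seed=seed,
        )


def count_sketch(v: np.ndarray, spec: CountSketchSpec) -> np.ndarray:
    """psi(v)[t] = sum_{j: h(j)=t} s(j) v(j); linear in v."""
    v = np.asarray(v, dtype=float).ravel()
    if len(v) != spec.input_dim:
        raise ValueError(f"vector length {len(v)} != sketch input_dim {spec.input_dim}")
    out = np.zeros(spec.output_dim)
    np.add.at(out, spec.h, spec.s * v)
    return out


def _count_sketch_backward(dpsi: np.ndarray, spec: CountSketchSpec) -> np.ndarray:
    return spec.s * dpsi[spec.h]


def _circular_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = len(a)
    return np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=d)


@dataclass
class FusionParams:
    """Clinical embedding MLP, two sketches, fused classifier, image branch."""

    mil: MILParams
    Wm1: np.ndarray  # (128, p)
    bm1: np.ndarray
    Wm2: np.ndarray  # (128, 128)
    bm2: np.ndarray
    sketch_image: CountSketchSpec
    sketch_clinical: CountSketchSpec
    Wf: np.ndarray  # (2, d)
    bf: np.ndarray  # (2,)
    signed_sqrt: bool = True
    l2_normalize: bool = True
    seed: int = 0

    @classmethod
    def init(
        cls,
        clinical_dim: int,
        sketch_dim: int = DEFAULT_SKETCH_DIM,
        seed: int = 0,
        dropout_rate: float = 0.25,
        signed_sqrt: bool = True,
        l2_normalize: bool = True,
    ) -> "FusionParams":
        rng = np.random.default_rng(seed)
        return cls(
            mil=MILParams.init(seed=seed, dropout_rate=dropout_rate),
            Wm1=he_init(rng, (EMBED_DIM, clinical_dim)),
            bm1=np.zeros(EMBED_DIM),
            Wm2=he_init(rng, (EMBED_DIM, EMBED_DIM)),
            bm2=np.zeros(EMBED_DIM),
            # embeddings are augmented with a constant bias coordinate
            # before sketching, so the fused form spans both modalities'
            # linear terms as well as their interactions
            sketch_image=CountSketchSpec.draw(EMBED_DIM + 1, sketch_dim, seed * 2 + 1),
            sketch_clinical=CountSketchSpec.draw(EMBED_DIM + 1, sketch_dim, seed * 2 + 2),
            Wf=he_init(rng, (2, sketch_dim)) * 0.1,
            bf=np.zeros(2),
            signed_sqrt=signed_sqrt,
            l2_normalize=l2_normalize,
            seed=seed,
        )

    def trainable(self) -> dict[str, np.ndarray]:
        out = {f"mil.{k}": v for k, v in self.mil.arrays().items() if k not in ("Wc", "bc")}
        out.update(
            Wm1=self.Wm1, bm1=self.bm1, Wm2=self.Wm2, bm2=self.bm2,
            Wf=self.Wf, bf=self.bf,
        )
        return out

    def copy(self) -> "FusionParams":
        return FusionParams(
            mil=self.mil.copy(),
            Wm1=self.Wm1.copy(), bm1=self.bm1.copy(),
            Wm2=self.Wm2.copy(), bm2=self.bm2.copy(),
            sketch_image=self.sketch_image,
            sketch_clinical=self.sketch_clinical,
            Wf=self.Wf.copy(), bf=self.bf.copy(),
            signed_sqrt=self.signed_sqrt,
            l2_normalize=self.l2_normalize,
            seed=self.seed,
        )


@dataclass
class FusionHyper:
    lr: float = 1e-4
    epochs: int = 200
    weight_decay: float = 1e-5
    dropout_rate: float = 0.25
    patience: int = 20
    sketch_dim: int = DEFAULT_SKETCH_DIM
    freeze_image: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# forward pieces
# ---------------------------------------------------------------------------


def embed_clinical(
    x: np.ndarray, params: FusionParams, return_cache: bool = False
):
    """Two affine+ReLU blocks: clinical design vector -> 128-d embedding."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != params.Wm1.shape[1]:
        raise ValueError(
            f"clinical vector length {len(x)} != expected {params.Wm1.shape[1]}"
        )
    z1 = params.Wm1 @ x + params.bm1
    a1 = np.maximum(z1, 0.0)
    z2 = params.Wm2 @ a1 + params.bm2
    v = np.maximum(z2, 0.0)
    if return_cache:
        return v, {"x": x, "z1": z1, "a1": a1, "z2": z2}
    return v


def cbp_fuse(
    u: np.ndarray,
    v: np.ndarray,
    sketch_u: CountSketchSpec,
    sketch_v: CountSketchSpec,
    signed_sqrt: bool = True,
    l2_normalize: bool = True,
) -> np.ndarray:
    """Compact bilinear pooling of two vectors.

    Circular convolution of the two count sketches (elementwise product of
    Fourier transforms), optionally followed by signed square root and unit
    L2 scaling (the norm of a zero vector is left as zero).
    """
    psi_u = count_sketch(u, sketch_u)
    psi_v = count_sketch(v, sketch_v)
    fused = _circular_conv(psi_u, psi_v)
    if signed_sqrt:
        fused = np.sign(fused) * np.sqrt(np.abs(fused))
    if l2_normalize:
        norm = np.linalg.norm(fused)
        if norm > 0:
            fused = fused / norm
    return fused


def classify_fused(fused: np.ndarray, params: FusionParams) -> float:
    """P(label = 1) from the fused vector via affine d->2 + softmax."""
    logits = params.Wf @ np.asarray(fused, dtype=float) + params.bf
    return float(softmax(logits)[1])


def _augment(v: np.ndarray, spec: CountSketchSpec) -> np.ndarray:
    """Append the constant bias coordinate when the sketch expects it."""
    if spec.input_dim == len(v) + 1:
        return np.append(v, 1.0)
    return v


def forward_fused(bag: FeatureBag, x_clin: np.ndarray, params: FusionParams) -> dict:
    """Eval-mode forward pass of the whole fusion network."""
    cache = branch_forward_cache(bag.features, params.mil, train_mode=False)
    v = embed_clinical(x_clin, params)
    fused = cbp_fuse(
        _augment(cache["H"], params.sketch_image),
        _augment(v, params.sketch_clinical),
        params.sketch_image, params.sketch_clinical,
        params.signed_sqrt, params.l2_normalize,
    )
    proba = classify_fused(fused, params)
    return {"H": cache["H"], "A": cache["A"], "clinical_embedding": v,
            "fused": fused, "proba": proba}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _fused_loss_and_grads(
    bag: FeatureBag,
    x_clin: np.ndarray,
    label: int,
    params: FusionParams,
    train_mode: bool,
    rng: np.random.Generator | None,
    freeze_image: bool,
) -> tuple[float, dict[str, np.ndarray]]:
    # a frozen image branch runs in eval mode: deterministic embeddings,
    # no dropout noise injected into the head's training signal
    img = branch_forward_cache(
        bag.features, params.mil,
        train_mode=train_mode and not freeze_image, rng=rng,
    )
    H = img["H"]
    v, clin = embed_clinical(x_clin, params, return_cache=True)

    psi_u = count_sketch(_augment(H, params.sketch_image), params.sketch_image)
    psi_v = count_sketch(_augment(v, params.sketch_clinical), params.sketch_clinical)
    Fu, Fv = np.fft.rfft(psi_u), np.fft.rfft(psi_v)
    d = params.sketch_image.output_dim
    c = np.fft.irfft(Fu * Fv, n=d)
    f = np.sign(c) * np.sqrt(np.abs(c)) if params.signed_sqrt else c
    norm = np.linalg.norm(f) if params.l2_normalize else 0.0
    fn = f / norm if params.l2_normalize and norm > 0 else f

    logits = params.Wf @ fn + params.bf
    p = softmax(logits)
    loss = -float(np.log(max(p[label], 1e-300)))

    dlogits = p.copy()
    dlogits[label] -= 1.0
    grads: dict[str, np.ndarray] = {
        "Wf": np.outer(dlogits, fn), "bf": dlogits,
    }
    dfn = params.Wf.T @ dlogits
    if params.l2_normalize and norm > 0:
        df = (dfn - fn * float(fn @ dfn)) / norm
    else:
        df = dfn
    if params.signed_sqrt:
        dc = df / np.maximum(2.0 * np.sqrt(np.abs(c)), 1e-6)
    else:
        dc = df
    Fd = np.fft.rfft(dc)
    dpsi_u = np.fft.irfft(Fd * np.conj(Fv), n=d)
    dpsi_v = np.fft.irfft(Fd * np.conj(Fu), n=d)
    dH = _count_sketch_backward(dpsi_u, params.sketch_image)
    dv = _count_sketch_backward(dpsi_v, params.sketch_clinical)
    if params.sketch_image.input_dim == len(H) + 1:
        dH = dH[:-1]  # bias coordinate carries no gradient
    if params.sketch_clinical.input_dim == len(v) + 1:
        dv = dv[:-1]

    # clinical MLP backward
    dz2 = dv * (clin["z2"] > 0)
    grads["Wm2"] = np.outer(dz2, clin["a1"])
    grads["bm2"] = dz2
    da1 = params.Wm2.T @ dz2
    dz1 = da1 * (clin["z1"] > 0)
    grads["Wm1"] = np.outer(dz1, clin["x"])
    grads["bm1"] = dz1

    if not freeze_image:
        for k, g in branch_backward_from_dH(img, params.mil, dH).items():
            grads[f"mil.{k}"] = g
    return loss, grads


def _auroc(y, scores) -> float:
    from scipy.stats import rankdata

    y = np.asarray(y)
    r = rankdata(scores)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def train_fusion(
    bags: list[FeatureBag],
    clinical_X: np.ndarray,
    labels: np.ndarray,
    hyper: FusionHyper | None = None,
    val_bags: list[FeatureBag] | None = None,
    val_clinical_X: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    init_mil: MILParams | None = None,
) -> tuple[FusionParams, dict]:
    """Joint end-to-end training of compression, attention, clinical
    embedding and fused classifier (sketch hashes fixed, not learned).

    Early stopping on validation AUROC when a validation split is given;
    fully reproducible given ``hyper.seed``. ``init_mil`` optionally warm
    starts the image branch from a pretrained MIL checkpoint;
    ``hyper.freeze_image`` keeps it frozen.
    """
    hyper = hyper or FusionHyper()
    clinical_X = np.asarray(clinical_X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(bags) == len(clinical_X) == len(labels)):
        raise ValueError("modalities and labels must align")

    params = FusionParams.init(
        clinical_dim=clinical_X.shape[1],
        sketch_dim=hyper.sketch_dim,
        seed=hyper.seed,
        dropout_rate=hyper.dropout_rate,
    )
    if init_mil is not None:
        params.mil = init_mil.copy()
        params.mil.dropout_rate = hyper.dropout_rate
    if hyper.epochs == 0:
        return params, {"epochs_run": 0, "history": []}
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes")

    rng = np.random.default_rng(hyper.seed)
    opt = Adam(params.trainable(), lr=hyper.lr, weight_decay=hyper.weight_decay)
    best = {"auroc": -np.inf, "epoch": -1, "params": params.copy()}
    history, stale = [], 0
    have_val = val_bags is not None and val_labels is not None and len(val_bags) > 0
    for epoch in range(hyper.epochs):
        order = rng.permutation(len(bags))
        total = 0.0
        for i in order:
            loss, grads = _fused_loss_and_grads(
                bags[i], clinical_X[i], int(labels[i]), params,
                train_mode=True, rng=rng, freeze_image=hyper.freeze_image,
            )
            opt.step(params.trainable(), clip_grads(grads))
            total += loss
        entry = {"epoch": epoch, "train_loss": total / len(bags)}
        if have_val:
            scores = np.array(
                [
                    forward_fused(b, x, params)["proba"]
                    for b, x in zip(val_bags, val_clinical_X)
                ]
            )
            entry["val_auroc"] = _auroc(np.asarray(val_labels, int), scores)
            if entry["val_auroc"] > best["auroc"]:
                best = {"auroc": entry["val_auroc"], "epoch": epoch,
                        "params": params.copy()}
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if have_val and stale > hyper.patience:
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


class FusionClassifier:
    """Joint image + clinical R/R classifier with CBP fusion.

    ``bags`` maps patient_id -> FeatureBag and ``clinical_X`` is a patient
    x feature matrix indexed by patient_id (any pandas DataFrame); patients
    must appear in both modalities.
    """

    def __init__(self, bags: dict, clinical_X, labels: dict,
                 val_ids: list | None = None):
        import pandas as pd

        clin_ids = list(clinical_X.index) if isinstance(clinical_X, pd.DataFrame) else None
        if clin_ids is not None:
            only_img = sorted(set(bags) - set(clin_ids))
            only_clin = sorted(set(clin_ids) - set(bags))
            if only_img or only_clin:
                raise ValueError(
                    "patients present in one modality only: "
                    f"image-only={only_img}, clinical-only={only_clin}"
                )
            ids = sorted(bags)
            X = clinical_X.loc[ids].to_numpy(dtype=float)
        else:
            ids = sorted(bags)
            X = np.asarray(clinical_X, dtype=float)
        self.patient_ids = ids
        val_ids = set(val_ids or [])
        tr = [i for i, pid in enumerate(ids) if pid not in val_ids]
        va = [i for i, pid in enumerate(ids) if pid in val_ids]
        y = np.array([labels[pid] for pid in ids], dtype=int)
        self.bags = [bags[ids[i]] for i in tr]
        self.X = X[tr]
        self.y = y[tr]
        self.val_bags = [bags[ids[i]] for i in va] or None
        self.val_X = X[va] if va else None
        self.val_y = y[va] if va else None

    def fit(self, init_mil: MILParams | None = None, **hyper_kwargs):
        hyper = FusionHyper(**hyper_kwargs)
        params, log = train_fusion(
            self.bags, self.X, self.y, hyper,
            self.val_bags, self.val_X, self.val_y, init_mil=init_mil,
        )
        return FusionClassifierResults(self, params, hyper, log)


@dataclass
class FusionClassifierResults:
    model: FusionClassifier
    params: FusionParams
    hyper: FusionHyper
    log: dict = field(default_factory=dict)

    def predict_proba(self, bags, clinical_X) -> np.ndarray:
        clinical_X = np.asarray(clinical_X, dtype=float)
        return np.array(
            [forward_fused(b, x, self.params)["proba"]
             for b, x in zip(bags, clinical_X)]
        )

    def summary(self) -> str:
        lines = [
            "CBP fusion classifier (image + clinical)",
            "=" * 44,
            f"training patients     {len(self.model.bags)}",
            f"sketch dimension      {self.params.sketch_image.output_dim}",
            f"epochs run            {self.log.get('epochs_run', 0)}",
        ]
        if "best_epoch" in self.log:
            lines.append(f"selected epoch        {self.log['best_epoch']}")
            lines.append(f"validation AUROC      {self.log['best_val_auroc']:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_fusion_params(params: FusionParams, path: str,
                       hyper: FusionHyper | None = None) -> None:
    header = {
        "signed_sqrt": params.signed_sqrt,
        "l2_normalize": params.l2_normalize,
        "seed": params.seed,
        "mil_dropout_rate": params.mil.dropout_rate,
        "mil_seed": params.mil.seed,
        "sketch_image": {"input_dim": params.sketch_image.input_dim,
                         "output_dim": params.sketch_image.output_dim,
                         "seed": params.sketch_image.seed},
        "sketch_clinical": {"input_dim": params.sketch_clinical.input_dim,
                            "output_dim": params.sketch_clinical.output_dim,
                            "seed": params.sketch_clinical.seed},
    }
    if hyper is not None:
        header["hyper"] = asdict(hyper)
    arrays = {f"mil.{k}": v for k, v in params.mil.arrays().items()}
    arrays.update(
        Wm1=params.Wm1, bm1=params.bm1, Wm2=params.Wm2, bm2=params.bm2,
        Wf=params.Wf, bf=params.bf,
        sk1_h=params.sketch_image.h, sk1_s=params.sketch_image.s,
        sk2_h=params.sketch_clinical.h, sk2_s=params.sketch_clinical.s,
    )
    np.savez(
        path,
        __header__=np.frombuffer(
            json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
        ),
        **arrays,
    )


def load_fusion_params(path: str) -> FusionParams:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        data = {k: npz[k] for k in npz.files if k != "__header__"}
    mil_arrays = {k[4:]: v for k, v in data.items() if k.startswith("mil.")}
    mil = MILParams(
        **mil_arrays,
        dropout_rate=float(header.get("mil_dropout_rate", 0.25)),
        seed=int(header.get("mil_seed", 0)),
    )
    sk1 = CountSketchSpec(
        h=data["sk1_h"], s=data["sk1_s"], **header["sketch_image"]
    )
    sk2 = CountSketchSpec(
        h=data["sk2_h"], s=data["sk2_s"], **header["sketch_clinical"]
    )
    return FusionParams(
        mil=mil,
        Wm1=data["Wm1"], bm1=data["bm1"], Wm2=data["Wm2"], bm2=data["bm2"],
        sketch_image=sk1, sketch_clinical=sk2,
        Wf=data["Wf"], bf=data["bf"],
        signed_sqrt=bool(header["signed_sqrt"]),
        l2_normalize=bool(header["l2_normalize"]),
        seed=int(header["seed"]),
    )
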