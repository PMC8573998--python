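"""Coverage-array rendering and the convolutional false-positive filter.

Short-read IR candidates are frequently artifacts: ragged or partial
intronic coverage, overlapping features, boundary ambiguity.  An expert
scrolling a genome browser rejects these on sight; this module automates
that review.  Each candidate locus is rendered as a fixed-size
channels x width array (flanking exon coverage at native resolution, the
intron body linearly resampled, plus splice-evidence and boundary-marker
channels) and scored by a small 1-D convolutional network trained on
examples whose labels come from long-read quantification of the same
introns — long reads resolve full transcript structure and therefore serve
as ground truth for whether the retention is real.

Labeling rules (applied to a long-read record):

* true-IR  — no warnings, informative depth >= 25 and IRratio > 0.1;
* false-IR — informative depth >= 50 and IRratio exactly 0 (deeper evidence
  is demanded for asserting absence than presence);
* otherwise unlabeled; and a final label is kept only when the directional
  and non-directional long-read quantifications agree.

The network itself (two conv layers, max-pooling, one dense layer, sigmoid
output) is implemented directly on numpy: the arrays are tiny and training
sets number in the hundreds, so a hand-rolled Adam loop is fast, exactly
reproducible from its seed, and dependency-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .quantify import IRRecord
from .signal import DepthProfile, SpliceCounts

__all__ = [
    "TRUE_IR",
    "FALSE_IR",
    "CoverageArray",
    "LabeledExample",
    "CNNConfig",
    "CNNModel",
    "FoldMetrics",
    "make_input_array",
    "select_candidates",
    "label_from_longreads",
    "build_training_set",
    "train_cnn",
    "predict",
    "apply_filter",
    "evaluate",
    "save_model",
    "load_model",
]

TRUE_IR = "true-IR"
FALSE_IR = "false-IR"


@dataclass
class CoverageArray:
    """Normalized (channels x width) rendering of one intron locus."""

    values: np.ndarray
    intron: str = ""


@dataclass
class LabeledExample:
    array: CoverageArray
    label: str  # TRUE_IR or FALSE_IR


def make_input_array(
    profile: DepthProfile,
    counts: SpliceCounts,
    flank: int = 30,
    width: int = 160,
) -> CoverageArray:
    """Render a depth profile + splice counts as the CNN input array.

    Channel 0: per-base depth — ``flank`` exonic bases either side at native
    resolution, intron body linearly resampled to ``width - 2*flank``
    columns; masked body positions are zeroed first (they carry no
    evidence).  Channel 1: splice evidence — SpliceLeft over the left flank,
    ExactSplice over the body, SpliceRight over the right flank.  Channel 2:
    fixed boundary markers at the exon-intron junction columns.  Channels
    are max-normalized to [0, 1]; an all-zero channel stays zero.
    """
    if flank <= 0 or width <= 2 * flank:
        raise ValueError("need flank > 0 and width > 2*flank")
    body_width = width - 2 * flank
    if profile.intron.length < 1:
        raise ValueError("zero-length intron")

    body = profile.depth.astype(float).copy()
    body[profile.mask] = 0.0
    if body.size == 1:
        resampled = np.full(body_width, body[0])
    else:
        grid = np.linspace(0.0, body.size - 1, body_width)
        resampled = np.interp(grid, np.arange(body.size), body)

    def flank_vals(arr: np.ndarray | None, left: bool) -> np.ndarray:
        out = np.zeros(flank)
        if arr is not None and arr.size:
            take = min(flank, arr.size)
            if left:
                out[-take:] = arr[-take:]
            else:
                out[:take] = arr[:take]
        return out

    ch0 = np.concatenate(
        [flank_vals(profile.left_flank, True), resampled,
         flank_vals(profile.right_flank, False)]
    )
    ch1 = np.concatenate(
        [
            np.full(flank, float(counts.splice_left)),
            np.full(body_width, float(counts.exact_splice)),
            np.full(flank, float(counts.splice_right)),
        ]
    )
    ch2 = np.zeros(width)
    for col in (flank - 1, flank, flank + body_width - 1, flank + body_width):
        ch2[col] = 1.0
    arr = np.stack([ch0, ch1, ch2]).astype(np.float32)
    for c in range(arr.shape[0]):
        peak = arr[c].max()
        if peak > 0:
            arr[c] /= peak
    return CoverageArray(values=arr, intron=profile.intron.name)


def select_candidates(sr_records: Iterable[IRRecord]) -> list[IRRecord]:
    """Putative IR candidates: short-read IRratio above 0.05, no warnings."""
    return [r for r in sr_records if r.irratio > 0.05 and not r.warnings]


def _label_one(rec: IRRecord) -> str | None:
    if not rec.warnings and rec.depth >= 25 and rec.irratio > 0.1:
        return TRUE_IR
    if rec.depth >= 50 and rec.irratio == 0:
        return FALSE_IR
    return None


def label_from_longreads(
    lr_dir: IRRecord | None, lr_nondir: IRRecord | None
) -> str | None:
    """Long-read label for one intron; requires dir/non-dir congruence."""
    if lr_dir is None or lr_nondir is None:
        return None
    a, b = _label_one(lr_dir), _label_one(lr_nondir)
    return a if (a is not None and a == b) else None


def build_training_set(
    arrays: Mapping[str, CoverageArray],
    labels: Mapping[str, str | None],
    sr_records: Mapping[str, IRRecord],
    seed: int = 0,
) -> list[LabeledExample]:
    """Assemble a balanced labeled dataset from candidates and long-read labels.

    Positives and negatives are the short-read candidates carrying a
    congruent long-read label.  Because genuine false-positive candidates
    are scarce, the negative class is augmented with long-read-negative
    introns outside the candidate set whose short-read IRratio still
    exceeds 0.01 (so they show some intronic signal worth rejecting).  If
    one class remains larger, it is downsampled.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    candidate_keys = {
        k for k, r in sr_records.items() if r.irratio > 0.05 and not r.warnings
    }
    pos = [
        k for k in sorted(candidate_keys)
        if labels.get(k) == TRUE_IR and k in arrays
    ]
    neg = [
        k for k in sorted(candidate_keys)
        if labels.get(k) == FALSE_IR and k in arrays
    ]
    if len(neg) < len(pos):
        pool = [
            k
            for k in sorted(arrays)
            if k not in candidate_keys
            and labels.get(k) == FALSE_IR
            and k in sr_records
            and sr_records[k].irratio > 0.01
        ]
        take = min(len(pos) - len(neg), len(pool))
        if take:
            neg += list(rng.choice(pool, size=take, replace=False))
    n = min(len(pos), len(neg))
    if len(pos) > n:
        pos = list(rng.choice(pos, size=n, replace=False))
    if len(neg) > n:
        neg = list(rng.choice(neg, size=n, replace=False))
    examples = [LabeledExample(arrays[k], TRUE_IR) for k in pos] + [
        LabeledExample(arrays[k], FALSE_IR) for k in neg
    ]
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------


@dataclass
class CNNConfig:
    in_channels: int = 3
    width: int = 160
    conv_channels: tuple[int, int] = (8, 16)
    kernel: int = 5
    hidden: int = 32
    epochs: int = 40
    batch_size: int = 32
    lr: float = 1e-3
    val_fraction: float = 0.15
    patience: int = 8


@dataclass
class FoldMetrics:
    fold: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float


@dataclass
class CNNModel:
    config: CNNConfig
    params: dict[str, np.ndarray]
    seed: int
    fold_metrics: list[FoldMetrics] = field(default_factory=list)

    @property
    def cv_balanced_accuracy(self) -> float:
        return float(np.mean([m.balanced_accuracy for m in self.fold_metrics]))


def _init_params(cfg: CNNConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    c1, c2 = cfg.conv_channels
    w_after = cfg.width // 4  # two pooling stages of 2
    flat = c2 * w_after
    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return {
        "W1": he((c1, cfg.in_channels, cfg.kernel), cfg.in_channels * cfg.kernel),
        "b1": np.zeros(c1),
        "W2": he((c2, c1, cfg.kernel), c1 * cfg.kernel),
        "b2": np.zeros(c2),
        "W3": he((flat, cfg.hidden), flat),
        "b3": np.zeros(cfg.hidden),
        "W4": he((cfg.hidden, 1), cfg.hidden),
        "b4": np.zeros(1),
    }


def _conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    K = W.shape[2]
    pad = K // 2
    L = x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    out = np.zeros((x.shape[0], W.shape[0], L))
    for k in range(K):
        out += np.einsum("ncl,oc->nol", xp[:, :, k : k + L], W[:, :, k])
    return out + b[None, :, None], xp


def _conv1d_back(dout: np.ndarray, xp: np.ndarray, W: np.ndarray):
    K = W.shape[2]
    pad = K // 2
    L = dout.shape[2]
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for k in range(K):
        dW[:, :, k] = np.einsum("nol,ncl->oc", dout, xp[:, :, k : k + L])
        dxp[:, :, k : k + L] += np.einsum("nol,oc->ncl", dout, W[:, :, k])
    db = dout.sum(axis=(0, 2))
    return dW, db, dxp[:, :, pad : pad + L]


def _maxpool2(x: np.ndarray):
    n, c, l = x.shape
    xr = x.reshape(n, c, l // 2, 2)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), idx


def _maxpool2_back(dout: np.ndarray, idx: np.ndarray, in_shape):
    n, c, l = in_shape
    dxr = np.zeros((n, c, l // 2, 2))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=3)
    return dxr.reshape(in_shape)


def _forward(params, x, want_cache=False):
    z1, xp1 = _conv1d(x, params["W1"], params["b1"])
    a1 = np.maximum(z1, 0.0)
    p1, i1 = _maxpool2(a1)
    z2, xp2 = _conv1d(p1, params["W2"], params["b2"])
    a2 = np.maximum(z2, 0.0)
    p2, i2 = _maxpool2(a2)
    flat = p2.reshape(x.shape[0], -1)
    z3 = flat @ params["W3"] + params["b3"]
    a3 = np.maximum(z3, 0.0)
    logits = (a3 @ params["W4"] + params["b4"]).ravel()
    if not want_cache:
        return logits, None
    cache = (xp1, z1, a1.shape, i1, xp2, z2, a2.shape, i2, p2.shape, flat, z3, a3)
    return logits, cache


def _backward(params, x, y, logits, cache):
    n = x.shape[0]
    xp1, z1, a1_shape, i1, xp2, z2, a2_shape, i2, p2_shape, flat, z3, a3 = cache
    p = 1.0 / (1.0 + np.exp(-logits))
    dlogits = (p - y) / n
    grads = {}
    grads["W4"] = a3.T @ dlogits[:, None]
    grads["b4"] = np.array([dlogits.sum()])
    da3 = dlogits[:, None] @ params["W4"].T
    dz3 = da3 * (z3 > 0)
    grads["W3"] = flat.T @ dz3
    grads["b3"] = dz3.sum(axis=0)
    dflat = dz3 @ params["W3"].T
    dp2 = dflat.reshape(p2_shape)
    da2 = _maxpool2_back(dp2, i2, a2_shape)
    dz2 = da2 * (z2 > 0)
    grads["W2"], grads["b2"], dp1 = _conv1d_back(dz2, xp2, params["W2"])
    da1 = _maxpool2_back(dp1, i1, a1_shape)
    dz1 = da1 * (z1 > 0)
    grads["W1"], grads["b1"], _ = _conv1d_back(dz1, xp1, params["W1"])
    return grads


def _bce(logits: np.ndarray, y: np.ndarray) -> float:
    # numerically stable binary cross-entropy with logits
    return float(
        np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    )


def _fit(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    cfg: CNNConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Adam training loop with optional early stopping on a validation split."""
    n = X.shape[0]
    n_val = int(cfg.val_fraction * n)
    use_val = cfg.patience > 0 and n_val >= 8 and n - n_val >= 16
    order = rng.permutation(n)
    if use_val:
        val_idx, tr_idx = order[:n_val], order[n_val:]
    else:
        val_idx, tr_idx = order[:0], order
    Xtr, ytr = X[tr_idx], y[tr_idx]
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_loss, best_params, since_best = np.inf, None, 0
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(Xtr))
        for lo in range(0, len(Xtr), cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits, cache = _forward(params, xb, want_cache=True)
            grads = _backward(params, xb, yb, logits, cache)
            t += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                params[k] = params[k] - cfg.lr * mhat / (np.sqrt(vhat) + eps)
        if use_val:
            val_logits, _ = _forward(params, X[val_idx])
            loss = _bce(val_logits, y[val_idx])
            if loss < best_loss - 1e-5:
                best_loss = loss
                best_params = {k: p.copy() for k, p in params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    if use_val and best_params is not None:
        return best_params
    return params


def _to_xy(dataset: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([ex.array.values for ex in dataset]).astype(float)
    y = np.array([1.0 if ex.label == TRUE_IR else 0.0 for ex in dataset])
    return X, y


def train_cnn(
    dataset: Sequence[LabeledExample],
    folds: int = 10,
    seed: int = 0,
    config: CNNConfig | None = None,
) -> CNNModel:
    """Stratified k-fold cross-validated training; final model on all data.

    Per-fold sensitivity, specificity and balanced accuracy are recorded on
    the held-out fold; the returned model is retrained on the full dataset.
    Fully reproducible from ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cfg = config or CNNConfig()
    X, y = _to_xy(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    cfg.width = X.shape[2]
    cfg.in_channels = X.shape[1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    metrics = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        rng = np.random.default_rng(seed * 7919 + fold)
        params = _fit(_init_params(cfg, rng), X[tr], y[tr], cfg, rng)
        logits, _ = _forward(params, X[te])
        sens, spec, bal = evaluate(1 / (1 + np.exp(-logits)) >= 0.5, y[te] == 1)
        metrics.append(FoldMetrics(fold, sens, spec, bal))
    rng = np.random.default_rng(seed)
    params = _fit(_init_params(cfg, rng), X, y, cfg, rng)
    return CNNModel(config=cfg, params=params, seed=seed, fold_metrics=metrics)


def predict(model: CNNModel, arrays: Sequence[CoverageArray]) -> np.ndarray:
    """Probability that each locus is a genuine IR event."""
    if not arrays:
        return np.zeros(0)
    X = np.stack([a.values for a in arrays]).astype(float)
    logits, _ = _forward(model.params, X)
    return 1.0 / (1.0 + np.exp(-logits))


def apply_filter(
    records: Sequence[IRRecord],
    probabilities: Sequence[float],
    cutoff: float = 0.5,
) -> list[IRRecord]:
    """Drop candidate records the classifier scores below ``cutoff``."""
    if len(records) != len(probabilities):
        raise ValueError("records and probabilities differ in length")
    return [r for r, p in zip(records, probabilities) if p >= cutoff]


def evaluate(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) of boolean calls."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    tp = int(np.sum(pred & lab))
    tn = int(np.sum(~pred & ~lab))
    fp = int(np.sum(pred & ~lab))
    fn = int(np.sum(~pred & lab))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens, spec, (sens + spec) / 2.0


def save_model(model: CNNModel, path: str) -> None:
    """Save config + weights + seed + fold metrics as one archive."""
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "fold_metrics": [asdict(m) for m in model.fold_metrics],
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.params,
    )


def load_model(path: str) -> CNNModel:
    with np.load(path if path.endswith(".npz") else path + ".npz") as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = CNNConfig(**{**meta["config"],
                       "conv_channels": tuple(meta["config"]["conv_channels"])})
    return CNNModel(
        config=cfg,
        params=params,
        seed=meta["seed"],
        fold_metrics=[FoldMetrics(**m) for m in meta["fold_metrics"]],
    )
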