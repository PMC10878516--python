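"""Pluggable pixel classifiers, 3-way ensemble voting, and inference.

The pipeline's contract for a classifier is the :class:`Predictor`
interface: a normalized image (or spatiotemporal stack) in, per-pixel
class probabilities out.  The built-in trainable model is a compact
multilayer perceptron over a multiscale filter-bank (Gaussian intensity,
edge and texture features at several scales) — small enough to train on
a CPU in minutes, deterministic for a fixed seed, and trained with
weighted cross-entropy so rare classes (mitotic and daughter nuclei) are
not swamped by background.

Robust inference uses three independently seeded instances of the same
model: a pixel is declared foreground (or assigned a class) only when at
least two of the three agree, which suppresses each instance's
idiosyncratic errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import multiscale_basic_features

from .fogbank import FogbankParams, separate_objects
from .imgio import TimeLapse, zscore_normalize

MODES = ("2d", "3d")


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier instance.

    mode "2d": binary nucleus/background segmentation of single frames,
    256x256 training tiles, class weights (1, 2) — nuclei count double.
    mode "3d": 4-class spatiotemporal segmentation, 256x256x16 tiles with
    random 128x128x16 crops per training draw, class weights
    (1, 2, 20, 20) — the short-lived mitotic and daughter classes are
    heavily upweighted.  Augmentations: reflections, right-angle
    rotations, Gaussian blur.
    """

    mode: str = "2d"
    class_weights: tuple[float, ...] = ()
    hidden_units: int = 24
    feature_sigma_min: float = 1.0
    feature_sigma_max: float = 8.0
    temporal_offsets: tuple[int, ...] = (-3, 3)  # extra context frames (3d)
    augment: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.class_weights:
            object.__setattr__(
                self,
                "class_weights",
                (1.0, 2.0) if self.mode == "2d" else (1.0, 2.0, 20.0, 20.0),
            )
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)

    @property
    def input_tile(self) -> tuple[int, ...]:
        return (256, 256) if self.mode == "2d" else (128, 128, 16)


def _frame_features(image: np.ndarray, spec: ClassifierSpec) -> np.ndarray:
    """(H, W, F) multiscale intensity/edge/texture features of one frame."""
    return multiscale_basic_features(
        np.asarray(image, dtype=np.float32),
        intensity=True,
        edges=True,
        texture=True,
        sigma_min=spec.feature_sigma_min,
        sigma_max=spec.feature_sigma_max,
    )


def _stack_features(
    stack: np.ndarray, t: int, spec: ClassifierSpec
) -> np.ndarray:
    """Features for frame t of a (t, H, W) stack, with temporal context."""
    feats = [_frame_features(stack[t], spec)]
    if spec.mode == "3d":
        for off in spec.temporal_offsets:
            s = int(np.clip(t + off, 0, stack.shape[0] - 1))
            feats.append(_frame_features(stack[s] - stack[t], spec))
    return np.concatenate(feats, axis=-1)


class Predictor:
    """Trained pixel classifier: softmax MLP over filter-bank features.

    Satisfies the pipeline's predictor contract: ``predict_stack`` maps a
    normalized (t, H, W) stack to (t, H, W, C) probabilities summing to
    one per pixel.  ``tag`` identifies the training seed for ensemble
    bookkeeping.
    """

    def __init__(self, spec: ClassifierSpec, weights: dict, tag: str = ""):
        self.spec = spec
        self.weights = weights
        self.tag = tag or f"seed{spec.rng_seed}"

    def _forward(self, X: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2 = (
            self.weights["W1"],
            self.weights["b1"],
            self.weights["W2"],
            self.weights["b2"],
        )
        h = np.maximum(X @ W1 + b1, 0.0)
        z = h @ W2 + b2
        z -= z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict_frame(
        self, image: np.ndarray, stack: np.ndarray | None = None,
        t: int = 0,
    ) -> np.ndarray:
        """(H, W, C) class probabilities for one normalized frame."""
        if self.spec.mode == "3d":
            if stack is None:
                stack = np.asarray(image)[None]
                t = 0
            feats = _stack_features(np.asarray(stack), t, self.spec)
        else:
            feats = _frame_features(image, self.spec)
        H, W, F = feats.shape
        return self._forward(feats.reshape(-1, F)).reshape(
            H, W, self.spec.n_classes
        )

    def predict_stack(self, stack: np.ndarray) -> np.ndarray:
        """(t, H, W, C) probabilities for a normalized stack."""
        stack = np.asarray(stack)
        return np.stack(
            [
                self.predict_frame(stack[t], stack=stack, t=t)
                for t in range(stack.shape[0])
            ]
        )

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        spec = {
            "mode": self.spec.mode,
            "class_weights": list(self.spec.class_weights),
            "hidden_units": self.spec.hidden_units,
            "feature_sigma_min": self.spec.feature_sigma_min,
            "feature_sigma_max": self.spec.feature_sigma_max,
            "temporal_offsets": list(self.spec.temporal_offsets),
            "augment": self.spec.augment,
            "rng_seed": self.spec.rng_seed,
            "tag": self.tag,
        }
        (d / "spec.json").write_text(json.dumps(spec, indent=2))
        np.savez(d / "weights.npz", **self.weights)

    @classmethod
    def load(cls, directory: str | Path) -> "Predictor":
        d = Path(directory)
        meta = json.loads((d / "spec.json").read_text())
        tag = meta.pop("tag")
        meta["class_weights"] = tuple(meta["class_weights"])
        meta["temporal_offsets"] = tuple(meta["temporal_offsets"])
        spec = ClassifierSpec(**meta)
        with np.load(d / "weights.npz") as z:
            weights = {k: z[k] for k in z.files}
        return cls(spec, weights, tag)


class OracleMapPredictor:
    """Predictor backed by precomputed per-frame probability maps.

    Lets ensemble voting, post-processing and tracking be exercised with
    controlled error rates and no training (see
    ``simdata.oracle_classifier``).  Input pixels are ignored; the stored
    maps are returned frame by frame.
    """

    def __init__(self, maps: Sequence[np.ndarray], mode: str = "2d", tag: str = "oracle"):
        self.maps = [np.asarray(m) for m in maps]
        self.tag = tag
        n_classes = self.maps[0].shape[-1]
        self.spec = ClassifierSpec(
            mode=mode, class_weights=tuple([1.0] * n_classes)
        )

    def predict_frame(self, image, stack=None, t: int = 0) -> np.ndarray:
        return self.maps[t]

    def predict_stack(self, stack: np.ndarray) -> np.ndarray:
        if len(self.maps) != np.asarray(stack).shape[0]:
            raise ValueError("oracle maps do not cover this stack")
        return np.stack(self.maps)


def binary_oracle_predictors(
    truth, flip_rate: float, seeds: Sequence[int]
) -> list[OracleMapPredictor]:
    """Three binary-mode oracles with independent, reproducible errors."""
    from .simdata import oracle_classifier

    preds = []
    for s in seeds:
        maps4 = oracle_classifier(truth, flip_rate, rng_seed=s)
        maps2 = []
        for m in maps4:
            fg = m[..., 1:].sum(axis=-1)
            maps2.append(np.stack([m[..., 0], fg], axis=-1))
        preds.append(OracleMapPredictor(maps2, mode="2d", tag=f"oracle{s}"))
    return preds


# ---------------------------------------------------------------------------
# training

def _augment_tile(img, lab, rng: np.random.Generator):
    """Random reflection / right-angle rotation / Gaussian blur."""
    k = int(rng.integers(0, 4))
    img, lab = np.rot90(img, k), np.rot90(lab, k)
    if rng.uniform() < 0.5:
        img, lab = img[::-1], lab[::-1]
    if rng.uniform() < 0.5:
        img, lab = img[:, ::-1], lab[:, ::-1]
    if rng.uniform() < 0.3:
        img = ndi.gaussian_filter(img, float(rng.uniform(0.5, 1.2)))
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def train(
    tiles: Sequence[tuple[np.ndarray, np.ndarray]],
    spec: ClassifierSpec,
    epochs: int = 8,
    rng_seed: int | None = None,
    pixels_per_tile: int = 4000,
    learning_rate: float = 0.05,
) -> Predictor:
    """Train one classifier instance on (image, label) tile pairs.

    Loss is cross-entropy weighted by ``spec.class_weights``; each epoch
    visits every tile once in seeded random order, augments it
    (reflection, rotation, blur), and takes one Adam step on a random
    pixel subsample.  ``epochs=0`` returns the seeded random
    initialization — a valid (if uninformative) Predictor.
    """
    if len(tiles) == 0:
        raise ValueError("need at least one training tile")
    seed = spec.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    C = spec.n_classes
    for _, lab in tiles:
        bad = np.setdiff1d(np.unique(lab), np.arange(C))
        if bad.size:
            raise ValueError(f"label values {bad} invalid for {C}-class mode")

    # probe feature dimensionality
    img0, _ = tiles[0]
    img0 = np.asarray(img0, dtype=float)
    if spec.mode == "3d":
        F = _stack_features(np.moveaxis(img0, -1, 0), 0, spec).shape[-1]
    else:
        F = _frame_features(img0, spec).shape[-1]
    H = spec.hidden_units
    W1 = rng.normal(0, np.sqrt(2.0 / F), (F, H))
    b1 = np.zeros(H)
    W2 = rng.normal(0, np.sqrt(2.0 / H), (H, C))
    b2 = np.zeros(C)
    params = [W1, b1, W2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    w_class = np.asarray(spec.class_weights, dtype=float)
    step = 0

    def adam(grads):
        nonlocal step
        step += 1
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for i, g in enumerate(grads):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mh = m[i] / (1 - beta1**step)
            vh = v[i] / (1 - beta2**step)
            params[i] -= learning_rate * mh / (np.sqrt(vh) + eps)

    for _ in range(epochs):
        order = rng.permutation(len(tiles))
        for ti in order:
            img, lab = tiles[ti]
            img = np.asarray(img, dtype=float)
            lab = np.asarray(lab)
            if spec.mode == "3d":
                # random 128x128 spatial crop of the 256x256x16 tile
                th, tw, _ = spec.input_tile
                r0 = int(rng.integers(0, max(1, img.shape[0] - th + 1)))
                c0 = int(rng.integers(0, max(1, img.shape[1] - tw + 1)))
                img = img[r0 : r0 + th, c0 : c0 + tw]
                lab = lab[r0 : r0 + th, c0 : c0 + tw]
                if spec.augment:
                    img, lab = _augment_tile(img, lab, rng)
                stack = np.moveaxis(img, -1, 0)
                t_mid = int(rng.integers(0, stack.shape[0]))
                feats = _stack_features(stack, t_mid, spec)
                labels = lab[..., t_mid]
            else:
                if spec.augment:
                    img, lab = _augment_tile(img, lab, rng)
                feats = _frame_features(img, spec)
                labels = lab
            X = feats.reshape(-1, feats.shape[-1])
            y = labels.reshape(-1).astype(int)
            n = min(pixels_per_tile, X.shape[0])
            idx = rng.choice(X.shape[0], size=n, replace=False)
            Xb, yb = X[idx], y[idx]
            # forward
            h_pre = Xb @ params[0] + params[1]
            h = np.maximum(h_pre, 0.0)
            z = h @ params[2] + params[3]
            z -= z.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            # weighted cross-entropy gradient
            w = w_class[yb]
            w = w / w.sum()
            dz = p.copy()
            dz[np.arange(n), yb] -= 1.0
            dz *= w[:, None]
            gW2 = h.T @ dz
            gb2 = dz.sum(axis=0)
            dh = dz @ params[2].T
            dh[h_pre <= 0] = 0.0
            gW1 = Xb.T @ dh
            gb1 = dh.sum(axis=0)
            adam([gW1, gb1, gW2, gb2])

    weights = {"W1": params[0], "b1": params[1], "W2": params[2], "b2": params[3]}
    return Predictor(spec, weights, tag=f"seed{seed}")


def train_ensemble(
    tiles, spec: ClassifierSpec, epochs: int = 8, seeds: Sequence[int] = (0, 1, 2)
) -> list[Predictor]:
    """Three instances of the same model differing only in training seed."""
    if len(seeds) != 3:
        raise ValueError("ensemble uses exactly 3 seeds")
    return [train(tiles, spec, epochs=epochs, rng_seed=s) for s in seeds]


# ---------------------------------------------------------------------------
# ensemble inference

def vote_masks(decisions: Sequence[np.ndarray], vote_threshold: int = 2) -> np.ndarray:
    """Per-pixel majority over per-member class decisions.

    A class wins a pixel when at least ``vote_threshold`` members chose
    it; when no class reaches the threshold the tie breaks toward the
    lowest class id among the most-voted classes.
    """
    decisions = [np.asarray(d) for d in decisions]
    n_classes = int(max(d.max() for d in decisions)) + 1
    counts = np.zeros(decisions[0].shape + (max(n_classes, 2),), dtype=np.int8)
    for d in decisions:
        for k in range(counts.shape[-1]):
            counts[..., k] += d == k
    return counts.argmax(axis=-1).astype(np.uint8)


def _member_decisions(
    stack: np.ndarray, predictor, mode: str
) -> np.ndarray:
    prob = predictor.predict_stack(stack)
    if mode == "2d":
        return (prob[..., 1] > 0.5).astype(np.uint8)
    return prob.argmax(axis=-1).astype(np.uint8)


def predict_ensemble(
    stack: TimeLapse | np.ndarray,
    predictors: Sequence,
    vote_threshold: int = 2,
    normalize: bool = True,
) -> np.ndarray:
    """2-of-3 voted class mask for a stack.

    Each of the exactly three predictors classifies every pixel (binary
    mode: nucleus iff its nucleus probability exceeds 0.5; 4-class mode:
    argmax); the output keeps a decision where at least
    ``vote_threshold`` members agree.
    """
    if len(predictors) != 3:
        raise ValueError("ensemble voting is defined for exactly 3 predictors")
    modes = {p.spec.mode for p in predictors}
    if len(modes) != 1:
        raise ValueError("predictors must share a mode")
    mode = modes.pop()
    arr = stack.as_array() if isinstance(stack, TimeLapse) else np.asarray(stack)
    if normalize:
        arr = np.stack([zscore_normalize(f) for f in arr])
    decisions = [_member_decisions(arr, p, mode) for p in predictors]
    return vote_masks(decisions, vote_threshold)


def infer_nuclei(
    phase: TimeLapse | np.ndarray,
    predictors: Sequence,
    fog: FogbankParams = FogbankParams(),
    vote_threshold: int = 2,
    normalize: bool = True,
) -> list[np.ndarray]:
    """Label-free instance segmentation of every frame.

    z-score normalization -> 3-way ensemble vote -> FogBank separation of
    the voted binary mask, per frame.  A radius-1 morphological smoothing
    (closing then opening) removes single-pixel vote noise from the mask
    edges before separation.
    """
    voted = predict_ensemble(phase, predictors, vote_threshold, normalize)
    out = []
    struct = ndi.generate_binary_structure(2, 1)
    for t in range(voted.shape[0]):
        mask = voted[t] > 0
        mask = ndi.binary_closing(mask, structure=struct)
        mask = ndi.binary_opening(mask, structure=struct)
        out.append(separate_objects(mask, intensity=None, params=fog))
    return out


def infer_classes(
    phase: TimeLapse | np.ndarray,
    predictors: Sequence,
    vote_threshold: int = 2,
    normalize: bool = True,
) -> np.ndarray:
    """Voted (t, H, W) 4-class stack for mitosis post-processing."""
    return predict_ensemble(phase, predictors, vote_threshold, normalize)
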