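"""Morphology classifier: extreme-group training and ambiguous-image triage.

The residual network is trained only on the two unambiguous morphological
groups (Group 1 vs Group 3, encoded 0 vs 1) with class-weighted binary
cross-entropy.  Ambiguous Group-2 images are then *triaged* from the
network's sigmoid output: probabilities at or below ``triage_low`` are
re-labelled Group 1, at or above ``triage_high`` Group 3, and anything in
between stays Group 2.  Lesion-level assessments take the worst (maximum)
group over a lesion's slices at a timepoint.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .cohort import LesionRecord
from .nn import Adam, ResNetSmall, bce_with_logits, sigmoid
from .phantom import RoiImage


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the reference training recipe (Adam, batch 32, learning
    rate 1e-5, 120 epochs, binary cross-entropy, 3:1 train:validation).
    For training this architecture from random initialisation on phantoms, the
    pipeline module supplies a faster "phantom profile" (see
    :data:`morphmr.pipeline.PHANTOM_TRAIN_PROFILE`).
    """

    learning_rate: float = 1e-5
    epochs: int = 120
    batch_size: int = 32
    optimizer: str = "adam"
    loss: str = "binary_cross_entropy"
    split_ratio: float = 0.75
    seed: int = 0
    triage_low: float = 0.25
    triage_high: float = 0.75
    widths: Tuple[int, int, int, int] = (16, 32, 64, 128)
    class_weighting: bool = True
    #: number of independently initialised networks whose sigmoid outputs are
    #: averaged; >1 stabilises where the decision boundary lands inside the
    #: unlabelled mid-severity gap
    n_ensemble: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0,1)")
        if not 0.0 < self.triage_low < 0.5:
            raise ValueError("triage_low must be in (0, 0.5)")
        if not 0.5 < self.triage_high < 1.0:
            raise ValueError("triage_high must be in (0.5, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "binary_cross_entropy":
            raise ValueError("only binary cross-entropy loss is supported")
        if self.learning_rate <= 0 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid learning_rate / epochs / batch_size")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")


@dataclass
class TrainedModel:
    """Network ensemble plus feature standardisation and training history.

    ``history`` holds the per-epoch curves of the first ensemble member;
    ``member_histories`` keeps every member's curves.
    """

    nets: List[ResNetSmall]
    config: TrainConfig
    diam_mean: float = 0.0
    diam_sd: float = 1.0
    history: Dict[str, List[float]] = field(default_factory=dict)
    member_histories: List[Dict[str, List[float]]] = field(default_factory=list)

    @property
    def net(self) -> ResNetSmall:
        return self.nets[0]

    def predict_proba(
        self, images: Sequence[RoiImage], batch_size: int = 256, augment: bool = True
    ) -> np.ndarray:
        """P(Group-3-like), averaged over the ensemble; always in [0, 1].

        With ``augment`` the prediction is additionally averaged over the
        eight dihedral orientations of the patch; the phantom statistics are
        isotropic, so this reduces prediction variance without bias.
        """
        pix = np.stack([img.pixels for img in images])
        diam = np.array([img.diameter_cm for img in images], dtype=float)
        dz = (diam - self.diam_mean) / self.diam_sd
        if not augment:
            return self._predict_arrays(pix, dz, batch_size)
        views = []
        for k in range(4):
            rot = np.rot90(pix, k=k, axes=(1, 2))
            views.append(np.ascontiguousarray(rot))
            views.append(np.ascontiguousarray(rot[:, :, ::-1]))
        logit_sum = np.zeros(len(pix))
        for v in views:
            logit_sum += self._logits(v, dz, batch_size)
        return sigmoid(logit_sum / len(views))

    def _logits(self, pix: np.ndarray, dz: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Ensemble-mean logit (geometric mean of odds across members)."""
        member_logits = []
        for net in self.nets:
            out = [
                net.forward(pix[i : i + batch_size], dz[i : i + batch_size])
                for i in range(0, len(pix), batch_size)
            ]
            member_logits.append(np.concatenate(out))
        return np.mean(member_logits, axis=0)

    def _predict_arrays(self, pix: np.ndarray, dz: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if len(pix) == 0:
            return np.empty(0)
        return sigmoid(self._logits(pix, dz, batch_size))


def build_model(config: TrainConfig) -> TrainedModel:
    """Construct the (untrained) network ensemble from a config.

    Parameter initialisation is fully determined by ``config.seed``; member
    seeds are derived from it.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_ensemble) % (2**31)
    nets = [ResNetSmall(widths=config.widths, seed=int(s)) for s in seeds]
    return TrainedModel(nets=nets, config=config)


def _stratified_split(
    labels: np.ndarray, split_ratio: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = max(1, int(round(split_ratio * len(idx))))
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def train(
    model: TrainedModel,
    images: Sequence[RoiImage],
    config: Optional[TrainConfig] = None,
) -> TrainedModel:
    """Train on Group-1/Group-3 images (label encoding: Group 3 -> 1).

    The data are split into stratified train/validation sets at
    ``split_ratio``; optimisation is Adam on class-weighted binary
    cross-entropy.  Per-epoch training loss, validation AUC and validation
    accuracy are recorded in ``model.history``.
    """
    config = config or model.config
    groups = np.array([img.true_group for img in images])
    if any(g not in (1, 3) for g in groups):
        raise ValueError("training images must be labelled Group 1 or Group 3 only")
    labels = (groups == 3).astype(float)
    if len(np.unique(labels)) < 2 or min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least two images of each of Groups 1 and 3")

    pix = np.stack([img.pixels for img in images])
    diam = np.array([img.diameter_cm for img in images], dtype=float)

    split_rng = np.random.default_rng(config.seed)
    tr, va = _stratified_split(labels, config.split_ratio, split_rng)

    # diameter standardised over the training split only
    model.diam_mean = float(diam[tr].mean())
    model.diam_sd = float(diam[tr].std()) or 1.0
    dz = (diam - model.diam_mean) / model.diam_sd

    if config.class_weighting:
        n0, n1 = (labels[tr] == 0).sum(), (labels[tr] == 1).sum()
        w_per_class = {0.0: len(tr) / (2.0 * n0), 1.0: len(tr) / (2.0 * n1)}
    else:
        w_per_class = {0.0: 1.0, 1.0: 1.0}
    weights = np.array([w_per_class[l] for l in labels])

    model.member_histories = []
    for midx, net in enumerate(model.nets):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919 + midx]))
        opt = Adam(net.params(), lr=config.learning_rate)
        history: Dict[str, List[float]] = {"loss": [], "val_auc": [], "val_accuracy": []}
        for epoch in range(config.epochs):
            order = rng.permutation(tr)
            epoch_loss, seen = 0.0, 0
            for i in range(0, len(order), config.batch_size):
                b = order[i : i + config.batch_size]
                logits = net.forward(pix[b], dz[b])
                loss, dlogits = bce_with_logits(logits, labels[b], weights[b])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training aborted: non-finite loss in member {midx}, epoch {epoch}, "
                        f"batch starting {i} (lr={config.learning_rate})"
                    )
                net.backward(dlogits)
                opt.step(net.grads())
                epoch_loss += loss * len(b)
                seen += len(b)
            val_prob = np.concatenate(
                [net.predict_proba(pix[va][i : i + 256], dz[va][i : i + 256])
                 for i in range(0, len(va), 256)]
            )
            val_auc = float(roc_auc_score(labels[va], val_prob)) if len(np.unique(labels[va])) > 1 else float("nan")
            val_acc = float(((val_prob >= 0.5) == labels[va]).mean())
            history["loss"].append(epoch_loss / max(seen, 1))
            history["val_auc"].append(val_auc)
            history["val_accuracy"].append(val_acc)
        model.member_histories.append(history)

    model.history = model.member_histories[0]
    return model


# ---------------------------------------------------------------------------
# triage and aggregation


@dataclass
class SliceAssessment:
    image: RoiImage
    prob_group3: float
    triaged_group: int


@dataclass
class LesionAssessment:
    lesion_id: str
    timepoint: int
    group: int
    source: str  # "radiologist" | "resnet"


def triage_group(prob_group3: float, config: TrainConfig) -> int:
    """Map a Group-3 probability onto Groups 1/2/3 (inclusive thresholds)."""
    if not 0.0 <= prob_group3 <= 1.0:
        raise ValueError(f"probability must be in [0,1], got {prob_group3}")
    if prob_group3 <= config.triage_low:
        return 1
    if prob_group3 >= config.triage_high:
        return 3
    return 2


def aggregate_slices(slice_groups: Sequence[int]) -> int:
    """Worst-response rule over a lesion's slices: the maximum group wins."""
    if len(slice_groups) == 0:
        raise ValueError("cannot aggregate an empty slice list")
    if any(g not in (1, 2, 3) for g in slice_groups):
        raise ValueError("slice groups must be 1, 2 or 3")
    return max(slice_groups)


def assess_lesion(
    model: TrainedModel, lesion: LesionRecord, timepoint: int, config: Optional[TrainConfig] = None
) -> LesionAssessment:
    """Network assessment of one lesion at one timepoint (worst slice)."""
    config = config or model.config
    if not lesion.eligible:
        raise ValueError(
            f"lesion {lesion.lesion_id} is ineligible ({lesion.exclusion_reason.value})"
        )
    slices = lesion.slices_by_timepoint.get(timepoint, [])
    if not slices:
        raise ValueError(f"lesion {lesion.lesion_id} has no slices at day {timepoint}")
    probs = model.predict_proba(slices)
    groups = [triage_group(float(p), config) for p in probs]
    return LesionAssessment(
        lesion_id=lesion.lesion_id,
        timepoint=timepoint,
        group=aggregate_slices(groups),
        source="resnet",
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-archive checkpoint: config + all member weights + history."""
    meta = {
        "config": asdict(model.config),
        "diam_mean": model.diam_mean,
        "diam_sd": model.diam_sd,
        "member_histories": model.member_histories,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for i, net in enumerate(model.nets):
            buf = BytesIO()
            np.savez(buf, *net.get_weights())
            zf.writestr(f"weights_{i}.npz", buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        cfg_dict = meta["config"]
        cfg_dict["widths"] = tuple(cfg_dict["widths"])
        config = TrainConfig(**cfg_dict)
        model = build_model(config)
        for i, net in enumerate(model.nets):
            with np.load(BytesIO(zf.read(f"weights_{i}.npz"))) as arrs:
                net.set_weights([arrs[f"arr_{j}"] for j in range(len(arrs.files))])
    model.diam_mean = meta["diam_mean"]
    model.diam_sd = meta["diam_sd"]
    model.member_histories = meta["member_histories"]
    model.history = model.member_histories[0] if model.member_histories else {}
    return model
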