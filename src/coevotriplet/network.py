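"""The four-branch residual distogram network and its training loop.

Architecture: each of the three coevolutionary tensors (L, L, 441) enters
its own branch — a 1x1 channel-reduction convolution (441 -> hidden),
instance normalization, then a stack of residual basic blocks. The branch
outputs are concatenated along channels and fused by a fourth residual
stack, projected to 12 channels, and passed through a per-pair softmax.
Because a distance map is symmetric, the softmax output for pairs (i, j)
and (j, i) is averaged to give the final prediction.

Distances are discretized into 12 bins — below 5 A, ten 1-A bins from 5 to
15 A, and beyond 15 A — and training minimizes the summed negative
log-likelihood of the true bin over residue pairs. A two-state
cross-entropy at the 8 A contact cutoff is available as the alternative
training loss for the distance-vs-binary ablation. The predicted contact
probability of a pair is the total mass of the first four bins, i.e. of
distances below 8 A, matching the CASP contact definition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from coevotriplet.nn import Adam, Conv2d, Dropout, InstanceNorm2d, ReLU, ResidualBlock, Sequential

__all__ = [
    "BinScheme",
    "NetConfig",
    "LabelMap",
    "DistogramPrediction",
    "TripletDistogramNet",
    "build_model",
    "discretize_distance",
    "labels_from_structure",
    "distance_nll_loss",
    "binary_bce_loss",
    "contact_probability",
    "train",
]

FEATURE_NAMES = ("cov", "pre", "plm")


@dataclass(frozen=True)
class BinScheme:
    """The 12-bin distance discretization.

    Bin 0 holds d < 5 A; bins 1..10 are the 1-A intervals [5+(k-1), 5+k);
    bin 11 holds d >= 15 A. The first four bins together cover exactly
    d < 8 A, the CASP contact cutoff.
    """

    edges: tuple[float, ...] = (5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)
    n_bins: int = 12
    contact_bins: tuple[int, ...] = (0, 1, 2, 3)

    def discretize(self, d: np.ndarray | float) -> np.ndarray | int:
        d_arr = np.asarray(d, dtype=np.float64)
        if np.any(~np.isfinite(d_arr)) or np.any(d_arr < 0):
            raise ValueError("distances must be finite and nonnegative")
        bins = np.searchsorted(np.asarray(self.edges), d_arr, side="right")
        if np.isscalar(d):
            return int(bins)
        return bins.astype(np.int64)


def discretize_distance(d: float, scheme: BinScheme | None = None) -> int:
    """Bin index of a single distance under the 12-bin scheme."""
    scheme = scheme or BinScheme()
    return int(scheme.discretize(float(d)))


@dataclass
class NetConfig:
    """Network and training hyperparameters.

    Defaults are the desk-scale profile (2 blocks per branch, 16 hidden
    channels); ``paper_scale`` builds the full 24-block / 64-channel
    configuration.
    """

    channels_in: int = 441
    channels_hidden: int = 16
    blocks_per_branch: int = 2
    fusion_blocks: int = 2
    n_bins: int = 12
    dropout: float = 0.2
    kernel_size: int = 3
    lr: float = 3e-3
    max_epochs: int = 100
    seed: int = 0
    crop_size: int = 128
    features: tuple[str, ...] = FEATURE_NAMES
    loss: str = "distance"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in {"distance", "binary"}:
            raise ValueError("loss must be 'distance' or 'binary'")
        if not self.features or any(f not in FEATURE_NAMES for f in self.features):
            raise ValueError(f"features must be a nonempty subset of {FEATURE_NAMES}")

    @property
    def fusion_channels_in(self) -> int:
        return len(self.features) * self.channels_hidden

    @classmethod
    def paper_scale(cls, **overrides) -> "NetConfig":
        """Full-scale configuration: 64 channels, 24 blocks per stack.

        Constructible and trainable, but far beyond a desk-scale CPU
        budget; the smaller learning rate suits the much deeper stack.
        """
        base = dict(channels_hidden=64, blocks_per_branch=24, fusion_blocks=24, lr=1e-3)
        base.update(overrides)
        return cls(**base)


@dataclass
class LabelMap:
    """Discretized native distances: bin labels, validity mask, contacts."""

    bins: np.ndarray       # (L, L) int
    mask: np.ndarray       # (L, L) bool
    contacts: np.ndarray   # (L, L) bool, d < 8 A

    @property
    def length(self) -> int:
        return self.bins.shape[0]


@dataclass
class DistogramPrediction:
    """Per-pair probabilities over the 12 distance bins."""

    probs: np.ndarray      # (L, L, 12)
    symmetrized: bool = True

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def labels_from_structure(coords: np.ndarray, scheme: BinScheme | None = None,
                          residue_names: Sequence[str] | None = None) -> LabelMap:
    """Bin labels and contact flags from per-residue coordinates.

    ``coords`` holds one interaction site per residue (C-beta, or C-alpha
    for glycine, or a toy site); rows with any NaN are treated as missing
    and masked out of both labels and contacts. Contacts are strictly
    below 8.0 A.
    """
    scheme = scheme or BinScheme()
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (L, 3)")
    resolved = np.all(np.isfinite(coords), axis=1)
    if resolved.sum() < 2:
        raise ValueError("need at least two resolved residues")
    ell = coords.shape[0]
    filled = np.where(resolved[:, None], coords, 0.0)
    d = squareform(pdist(filled))
    mask = resolved[:, None] & resolved[None, :]
    bins = np.zeros((ell, ell), dtype=np.int64)
    bins[mask] = scheme.discretize(d[mask])
    contacts = mask & (d < 8.0)
    np.fill_diagonal(contacts, False)
    return LabelMap(bins=bins, mask=mask, contacts=contacts)


class TripletDistogramNet:
    """Branch-per-feature residual network with a fused distogram head."""

    def __init__(self, cfg: NetConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        ch = cfg.channels_hidden
        self.branches: dict[str, Sequential] = {}
        for name in cfg.features:
            layers = [
                Conv2d(cfg.channels_in, ch, 1, rng, f"{name}.reduce"),
                InstanceNorm2d(ch, name=f"{name}.norm"),
                ReLU(),
            ]
            for b in range(cfg.blocks_per_branch):
                layers.append(ResidualBlock(ch, cfg.kernel_size, cfg.dropout,
                                            rng, f"{name}.block{b}"))
            self.branches[name] = Sequential(*layers)
        fusion = [
            Conv2d(cfg.fusion_channels_in, ch, 1, rng, "fusion.reduce"),
            InstanceNorm2d(ch, name="fusion.norm"),
            ReLU(),
        ]
        for b in range(cfg.fusion_blocks):
            fusion.append(ResidualBlock(ch, cfg.kernel_size, cfg.dropout,
                                        rng, f"fusion.block{b}"))
        fusion.append(Conv2d(ch, cfg.n_bins, 1, rng, "fusion.project"))
        self.fusion = Sequential(*fusion)
        # dropout layers share one seeded generator so runs are reproducible
        for seq in list(self.branches.values()) + [self.fusion]:
            for layer in seq.layers:
                if isinstance(layer, ResidualBlock) and layer.drop is not None:
                    layer.drop.rng = self._dropout_rng
        self._branch_splits: list[int] = []

    def parameters(self):
        params = []
        for name in self.cfg.features:
            params.extend(self.branches[name].parameters())
        params.extend(self.fusion.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def set_training(self, mode: bool) -> None:
        for seq in self.branches.values():
            seq.set_training(mode)
        self.fusion.set_training(mode)

    def _as_channel_first(self, tensor: np.ndarray) -> np.ndarray:
        if tensor.ndim != 3 or tensor.shape[2] != self.cfg.channels_in:
            raise ValueError(f"feature tensor must be (L, L, {self.cfg.channels_in})")
        return np.ascontiguousarray(tensor.transpose(2, 0, 1), dtype=np.float32)

    def forward_logits(self, tensors: Mapping[str, np.ndarray]) -> np.ndarray:
        """Raw (12, L, L) logits; caches intermediates for backward."""
        lengths = {tensors[name].shape[0] for name in self.cfg.features}
        if len(lengths) != 1:
            raise ValueError("all feature tensors must share the same L")
        outs = []
        for name in self.cfg.features:
            x = self._as_channel_first(tensors[name])
            outs.append(self.branches[name].forward(x))
        fused = np.concatenate(outs, axis=0)
        self._branch_splits = [o.shape[0] for o in outs]
        return self.fusion.forward(fused)

    def backward_logits(self, dlogits: np.ndarray) -> None:
        dfused = self.fusion.backward(dlogits)
        start = 0
        for name, size in zip(self.cfg.features, self._branch_splits):
            self.branches[name].backward(dfused[start:start + size])
            start += size

    def predict(self, tensors: Mapping[str, np.ndarray]) -> DistogramPrediction:
        """Symmetrized softmax distogram for one protein (inference mode)."""
        self.set_training(False)
        logits = self.forward_logits(tensors)
        probs = _softmax_channels(logits)
        probs = probs.transpose(1, 2, 0)                     # (L, L, 12)
        probs = 0.5 * (probs + probs.transpose(1, 0, 2))     # average (i,j), (j,i)
        return DistogramPrediction(probs=probs.astype(np.float64), symmetrized=True)

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {p.name or f"param{i}": p.value for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: Mapping[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            key = p.name or f"param{i}"
            if key not in arrays:
                raise KeyError(f"missing parameter {key} in checkpoint")
            if arrays[key].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.value = np.ascontiguousarray(arrays[key], dtype=np.float32)


def build_model(cfg: NetConfig) -> TripletDistogramNet:
    """Construct the seeded network for a configuration."""
    return TripletDistogramNet(cfg)


def _softmax_channels(logits: np.ndarray) -> np.ndarray:
    mx = logits.max(axis=0, keepdims=True)
    ex = np.exp(logits - mx)
    return ex / ex.sum(axis=0, keepdims=True)


def _loss_mask(labels: LabelMap) -> np.ndarray:
    ell = labels.length
    i, j = np.indices((ell, ell))
    return labels.mask & (np.abs(i - j) >= 1)


def distance_nll_loss(pred: DistogramPrediction, labels: LabelMap,
                      average: bool = False) -> float:
    """Summed negative log-likelihood of the true distance bin.

    L = -sum_t sum_k y_t^k log p_t^k over masked off-diagonal pairs t;
    ``average`` divides by the number of pairs for reporting.
    """
    mask = _loss_mask(labels)
    t = int(mask.sum())
    if t == 0:
        raise ValueError("empty mask")
    p = pred.probs[mask]                       # (T, 12)
    y = labels.bins[mask]
    picked = np.clip(p[np.arange(t), y], 1e-30, None)
    loss = -float(np.log(picked).sum())
    return loss / t if average else loss


def binary_bce_loss(contact_probs: np.ndarray | DistogramPrediction, labels: LabelMap,
                    average: bool = False) -> float:
    """Two-state cross-entropy at the 8 A contact cutoff."""
    if isinstance(contact_probs, DistogramPrediction):
        contact_probs = contact_probability(contact_probs)
    mask = _loss_mask(labels)
    t = int(mask.sum())
    if t == 0:
        raise ValueError("empty mask")
    p = np.clip(contact_probs[mask], 1e-12, 1 - 1e-12)
    y = labels.contacts[mask].astype(np.float64)
    loss = -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return loss / t if average else loss


def contact_probability(pred: DistogramPrediction,
                        scheme: BinScheme | None = None) -> np.ndarray:
    """Contact map P[i, j] = sum of the first four (d < 8 A) bin masses."""
    scheme = scheme or BinScheme()
    return pred.probs[:, :, list(scheme.contact_bins)].sum(axis=2)


def _crop_example(tensors: Mapping[str, np.ndarray], labels: LabelMap,
                  crop: int, rng: np.random.Generator):
    ell = labels.length
    if ell <= crop:
        return tensors, labels
    start = int(rng.integers(0, ell - crop + 1))
    sl = slice(start, start + crop)
    t = {k: v[sl, sl] for k, v in tensors.items()}
    lab = LabelMap(bins=labels.bins[sl, sl], mask=labels.mask[sl, sl],
                   contacts=labels.contacts[sl, sl])
    return t, lab


def _training_step(model: TripletDistogramNet, tensors, labels: LabelMap,
                   loss_kind: str) -> tuple[float, np.ndarray]:
    """Forward + gradient w.r.t. logits for one protein; returns (mean loss, dlogits)."""
    logits = model.forward_logits(tensors)
    probs = _softmax_channels(logits)                       # (12, L, L)
    mask = _loss_mask(labels)
    t = int(mask.sum())
    if t == 0:
        raise ValueError("empty training mask")
    scheme = BinScheme()
    if loss_kind == "distance":
        y = np.zeros_like(probs)
        flat_bins = labels.bins
        for k in range(probs.shape[0]):
            y[k] = (flat_bins == k) & mask
        picked = np.clip((probs * y).sum(axis=0)[mask], 1e-30, None)
        loss = -float(np.log(picked).sum()) / t
        dlogits = (probs - y) * mask[None].astype(probs.dtype) / t
    else:
        cidx = list(scheme.contact_bins)
        pc = np.clip(probs[cidx].sum(axis=0), 1e-6, 1 - 1e-6)
        yb = labels.contacts.astype(np.float64)
        loss = -float(np.sum((yb * np.log(pc) + (1 - yb) * np.log(1 - pc))[mask])) / t
        dpc = (-yb / pc + (1 - yb) / (1 - pc)) * mask / t
        ind = np.zeros(probs.shape[0])
        ind[cidx] = 1.0
        dlogits = probs * (ind[:, None, None] - pc[None]) * dpc[None]
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    return loss, dlogits.astype(np.float32)


def train(model: TripletDistogramNet, dataset: Sequence[tuple[Mapping[str, np.ndarray], LabelMap]],
          cfg: NetConfig | None = None,
          validation: Sequence[tuple[Mapping[str, np.ndarray], LabelMap]] = (),
          epochs: int | None = None, clip_grad_norm: float = 5.0) -> dict:
    """Adam training over a dataset of (feature tensors, label map) pairs.

    Batch = one protein; proteins longer than ``crop_size`` are randomly
    square-cropped each visit. Dropout (rate ``cfg.dropout``) is active
    only here. Gradients are clipped to a global norm of
    ``clip_grad_norm`` (the two-state loss can produce near-singular
    gradients when predicted contact probabilities saturate). Returns a
    history dict with per-epoch mean training loss and, when a validation
    set is given, validation loss and long-range top-L/5 contact precision.
    """
    from coevotriplet.evaluation import precision_at

    cfg = cfg or model.cfg
    if not dataset:
        raise ValueError("need at least one training example")
    n_epochs = epochs if epochs is not None else cfg.max_epochs
    rng = np.random.default_rng(cfg.seed + 2)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history: dict = {"train_loss": [], "val_loss": [], "val_topL5_long": []}
    for _epoch in range(n_epochs):
        model.set_training(True)
        order = rng.permutation(len(dataset))
        losses = []
        for idx in order:
            tensors, labels = dataset[idx]
            tensors, labels = _crop_example(tensors, labels, cfg.crop_size, rng)
            opt.zero_grad()
            loss, dlogits = _training_step(model, tensors, labels, cfg.loss)
            model.backward_logits(dlogits)
            if clip_grad_norm:
                total = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in opt.params))
                if total > clip_grad_norm:
                    scale = clip_grad_norm / total
                    for p in opt.params:
                        p.grad *= scale
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if validation:
            model.set_training(False)
            vlosses, vprec = [], []
            for tensors, labels in validation:
                pred = model.predict(tensors)
                vlosses.append(distance_nll_loss(pred, labels, average=True))
                pmap = contact_probability(pred)
                vprec.append(precision_at(pmap, labels.contacts, "long", 5))
            history["val_loss"].append(float(np.mean(vlosses)))
            history["val_topL5_long"].append(float(np.mean(vprec)))
    model.set_training(False)
    return history
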