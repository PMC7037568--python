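"""3D convolutional auto-encoder for binary voxel envelopes.

A VGG-style stack of 3x3x3 convolutions with 2x pooling compresses the
31^3 occupancy grid through 16^3 -> 8^3 -> 4^3 spatial stages into a dense
latent vector (200 dimensions at full configuration); the decoder mirrors
the encoder with nearest upsampling and ends in a per-voxel sigmoid.
Training minimizes per-voxel binary cross-entropy against the binary
targets; the decoder output is binarized (threshold 0.5) only at
inference.  Alongside the trained weights the module computes a latent
*prior* — per-dimension min/max/mean/std over the encoded training set —
which the reconstruction engine uses to initialize and constrain its
search, exploiting the fact that valid codes occupy limited ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .voxel_shapes import GRID_SIZE, REFERENCE_RADIUS, VoxelGrid

DEFAULT_LATENT_DIM = 200
#: channels after each encoder conv block (decoder mirrors them)
DEFAULT_CHANNELS = (8, 16, 32)
BINARIZE_THRESHOLD = 0.5
#: upper bound on any model radius (A) handled by the pipeline
RADIUS_MAX = 300.0


class UntrainedCoderError(RuntimeError):
    """Operation requires a trained coder."""


@dataclass
class LatentCode:
    """The genome of a model: latent vector plus optional radius (A)."""

    z: np.ndarray
    radius: float | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 1:
            raise ValueError("latent vector must be 1D")
        if not np.isfinite(self.z).all():
            raise ValueError("latent vector must be finite")
        if self.radius is not None:
            if not (0 < self.radius <= RADIUS_MAX):
                raise ValueError(
                    f"radius must lie in (0, {RADIUS_MAX}], got {self.radius}")
            self.radius = float(self.radius)

    def copy(self) -> "LatentCode":
        return LatentCode(self.z.copy(), self.radius)


@dataclass
class LatentPrior:
    """Per-dimension statistics of encoded training shapes."""

    min: np.ndarray
    max: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        for name in ("min", "max", "mean", "std"):
            setattr(self, name, np.asarray(getattr(self, name), np.float64))
        if not (self.min <= self.mean).all() or not (self.mean <= self.max).all():
            raise ValueError("prior must satisfy min <= mean <= max")
        if (self.std < 0).any():
            raise ValueError("prior std must be non-negative")

    @property
    def dim(self) -> int:
        return len(self.mean)

    @classmethod
    def from_codes(cls, Z: np.ndarray) -> "LatentPrior":
        return cls(min=Z.min(axis=0), max=Z.max(axis=0),
                   mean=Z.mean(axis=0), std=Z.std(axis=0))


@dataclass
class TrainedCoder:
    """Encoder/decoder layer stacks plus training provenance."""

    encoder: list
    decoder: list
    latent_dim: int
    channels: tuple
    seed: int
    trained: bool = False
    threshold: float = BINARIZE_THRESHOLD
    loss_curve: list = field(default_factory=list)
    val_loss_curve: list = field(default_factory=list)
    train_config: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return (_nn.parameter_count(self.encoder)
                + _nn.parameter_count(self.decoder))


def build_coder(latent_dim: int = DEFAULT_LATENT_DIM, grid: int = GRID_SIZE,
                channels: tuple = DEFAULT_CHANNELS,
                seed: int = 0) -> TrainedCoder:
    """Build an untrained coder (weights seeded, hence reproducible).

    Encoder: [conv(3^3)+ReLU, pool]x3 reducing 31 -> 16 -> 8 -> 4, then a
    dense layer to ``latent_dim``.  Decoder mirrors with nearest upsampling
    and a final 1-channel convolution producing per-voxel logits.
    """
    if latent_dim < 8:
        raise ValueError("latent_dim must be >= 8")
    if grid != GRID_SIZE:
        raise ValueError("only the 31-voxel grid is supported")
    rng = np.random.default_rng(seed)
    c1, c2, c3 = channels
    enc = [
        _nn.Conv3D(1, c1, rng), _nn.ReLU(), _nn.MaxPool3D(),   # 31 -> 16
        _nn.Conv3D(c1, c2, rng), _nn.ReLU(), _nn.MaxPool3D(),  # 16 -> 8
        _nn.Conv3D(c2, c3, rng), _nn.ReLU(), _nn.MaxPool3D(),  # 8 -> 4
        _nn.Flatten(), _nn.Dense(64 * c3, latent_dim, rng),
    ]
    dec = [
        _nn.Dense(latent_dim, 64 * c3, rng), _nn.ReLU(),
        _nn.Reshape((c3, 4, 4, 4)),
        _nn.Upsample3D(), _nn.Conv3D(c3, c2, rng), _nn.ReLU(),   # 8
        _nn.Upsample3D(), _nn.Conv3D(c2, c1, rng), _nn.ReLU(),   # 16
        _nn.Upsample3D(), _nn.Crop3D(GRID_SIZE),                 # 32 -> 31
        _nn.Conv3D(c1, 1, rng),
    ]
    # bias the output toward the typical envelope sparsity so the first
    # epochs are not spent learning the background class
    dec[-1].params["b"][:] = -1.5
    return TrainedCoder(encoder=enc, decoder=dec, latent_dim=latent_dim,
                        channels=tuple(channels), seed=seed)


def _stack(grids: list[VoxelGrid]) -> np.ndarray:
    return np.stack([g.occupancy for g in grids])[:, None].astype(np.float32)


def _encode_batch(coder: TrainedCoder, x: np.ndarray,
                  train: bool = False) -> np.ndarray:
    return _nn.run_forward(coder.encoder, x, train=train)


def _decode_logits(coder: TrainedCoder, z: np.ndarray,
                   train: bool = False) -> np.ndarray:
    return _nn.run_forward(coder.decoder, z.astype(np.float32), train=train)


def train(coder: TrainedCoder, dataset, epochs: int = 10, batch: int = 8,
          seed: int = 0, lr: float = 1e-3,
          patience: int = 5) -> tuple[TrainedCoder, LatentPrior]:
    """Train the coder on a shape corpus; returns it with a LatentPrior.

    ``dataset`` is either a ShapeDataset (its split is used) or a plain
    list of grids (a 90/10 split is drawn from ``seed``).  Per-voxel binary
    cross-entropy is minimized with Adam; training stops early when the
    held-out loss has not improved for ``patience`` epochs, and the best
    weights by validation loss are restored.  Deterministic given the seed
    in single-threaded mode.
    """
    from .voxel_shapes import ShapeDataset

    rng = np.random.default_rng(seed)
    if isinstance(dataset, ShapeDataset):
        grids = dataset.grids
        train_idx = np.asarray(dataset.train_indices)
        val_idx = np.asarray(dataset.val_indices)
    else:
        grids = list(dataset)
        perm = rng.permutation(len(grids))
        n_val = max(1, len(grids) // 10)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(grids) < 100:
        raise ValueError("training requires at least 100 grids")

    X = _stack(grids)
    Xtr, Xval = X[train_idx], X[val_idx]
    layers = coder.encoder + coder.decoder
    opt = _nn.Adam(layers, lr=lr)

    def val_loss() -> float:
        total = 0.0
        for i in range(0, len(Xval), 16):
            xb = Xval[i:i + 16]
            logits = _decode_logits(coder, _encode_batch(coder, xb))
            loss, _ = _nn.bce_loss_and_grad(logits, xb)
            total += loss * len(xb)
        return total / len(Xval)

    best_val = val_loss()
    initial_val = best_val
    best_state = _nn.get_state(layers)
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(Xtr))
        ep_loss = 0.0
        for i in range(0, len(order), batch):
            xb = Xtr[order[i:i + batch]]
            z = _encode_batch(coder, xb, train=True)
            logits = _decode_logits(coder, z, train=True)
            loss, dlogits = _nn.bce_loss_and_grad(logits, xb)
            dz = _nn.run_backward(coder.decoder, dlogits)
            _nn.run_backward(coder.encoder, dz, need_input_grad=False)
            opt.step()
            ep_loss += loss * len(xb)
        vl = val_loss()
        coder.loss_curve.append(ep_loss / len(Xtr))
        coder.val_loss_curve.append(vl)
        if vl < best_val:
            best_val, best_state, stale = vl, _nn.get_state(layers), 0
        else:
            stale += 1
            if stale >= patience:
                break
    _nn.set_state(layers, best_state)
    if best_val >= initial_val:
        raise RuntimeError("training failed to reduce the validation loss")

    coder.trained = True
    coder.train_config = {"epochs": epochs, "batch": batch, "seed": seed,
                          "lr": lr, "patience": patience,
                          "n_train": int(len(train_idx)),
                          "n_val": int(len(val_idx))}
    Ztr = np.concatenate([_encode_batch(coder, Xtr[i:i + 32])
                          for i in range(0, len(Xtr), 32)])
    prior = LatentPrior.from_codes(Ztr.astype(np.float64))
    return coder, prior


def encode(coder: TrainedCoder, grid: VoxelGrid) -> LatentCode:
    """Compress one envelope to its latent vector (radius carried over)."""
    if not coder.trained:
        raise UntrainedCoderError("encode requires a trained coder")
    z = _encode_batch(coder, _stack([grid]))[0]
    return LatentCode(z.astype(np.float64), radius=grid.radius)


def decode(coder: TrainedCoder, code: LatentCode) -> VoxelGrid:
    """Decode a latent vector to a binary envelope.

    Sigmoid output is thresholded at ``coder.threshold``; the grid radius
    is taken from the code when set, else the 50 A reference.  An empty
    decoded grid is permitted (downstream fitness handles it).
    """
    if not coder.trained:
        raise UntrainedCoderError("decode requires a trained coder")
    occ = decode_batch(coder, code.z[None, :])[0]
    radius = code.radius if code.radius is not None else REFERENCE_RADIUS
    return VoxelGrid(occ, radius=radius)


def decode_batch(coder: TrainedCoder, Z: np.ndarray) -> np.ndarray:
    """Batched decode to binary occupancy arrays (B, 31, 31, 31).

    Processed in sub-batches so the im2col workspaces of the full-volume
    decoder convolutions stay small.
    """
    Z = np.asarray(Z, dtype=np.float32)
    out = []
    for i in range(0, len(Z), 8):
        logits = _decode_logits(coder, Z[i:i + 8])
        prob = _nn.sigmoid(logits[:, 0])
        out.append((prob >= coder.threshold).astype(np.uint8))
    return np.concatenate(out)


def encode_decode_cc(coder: TrainedCoder, grids: list[VoxelGrid]) -> np.ndarray:
    """Overlap cc between each grid and its encode-decode round trip."""
    from .compare import overlap_cc

    Z = np.concatenate([_encode_batch(coder, _stack(grids[i:i + 32]))
                        for i in range(0, len(grids), 32)])
    occ = np.concatenate([decode_batch(coder, Z[i:i + 32])
                          for i in range(0, len(Z), 32)])
    out = []
    for g, o in zip(grids, occ):
        if o.sum() == 0:
            out.append(0.0)
        else:
            out.append(overlap_cc(g, VoxelGrid(o, radius=g.radius)))
    return np.array(out)


def interpolate_latent(coder: TrainedCoder, a: LatentCode, b: LatentCode,
                       steps: int) -> list[VoxelGrid]:
    """Decode convex combinations (1-t) a + t b at uniform t in [0, 1].

    The endpoints equal decode(a) and decode(b); intermediate frames morph
    one envelope into the other through the latent manifold.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    ts = np.linspace(0.0, 1.0, steps)
    Z = np.array([(1 - t) * a.z + t * b.z for t in ts])
    occ = decode_batch(coder, Z)
    radius = a.radius if a.radius is not None else REFERENCE_RADIUS
    return [VoxelGrid(o, radius=radius) for o in occ]


# ---------------------------------------------------------------------------
# persistence

def save_coder(path, coder: TrainedCoder,
               prior: LatentPrior | None = None) -> None:
    """Persist weights, config and (optionally) the latent prior to .npz."""
    payload: dict[str, np.ndarray] = {
        "format_version": np.array(1),
        "latent_dim": np.array(coder.latent_dim),
        "channels": np.array(coder.channels),
        "seed": np.array(coder.seed),
        "trained": np.array(int(coder.trained)),
        "threshold": np.array(coder.threshold),
        "loss_curve": np.array(coder.loss_curve),
        "val_loss_curve": np.array(coder.val_loss_curve),
    }
    for side, layers in (("enc", coder.encoder), ("dec", coder.decoder)):
        for i, ly in enumerate(layers):
            for k, v in ly.params.items():
                payload[f"{side}{i}_{k}"] = v
    if prior is not None:
        for k in ("min", "max", "mean", "std"):
            payload[f"prior_{k}"] = getattr(prior, k)
    np.savez_compressed(path, **payload)


def load_coder(path) -> tuple[TrainedCoder, LatentPrior | None]:
    with np.load(path) as f:
        coder = build_coder(latent_dim=int(f["latent_dim"]),
                            channels=tuple(int(c) for c in f["channels"]),
                            seed=int(f["seed"]))
        for side, layers in (("enc", coder.encoder), ("dec", coder.decoder)):
            for i, ly in enumerate(layers):
                for k in ly.params:
                    ly.params[k] = f[f"{side}{i}_{k}"].copy()
        coder.trained = bool(int(f["trained"]))
        coder.threshold = float(f["threshold"])
        coder.loss_curve = list(f["loss_curve"])
        coder.val_loss_curve = list(f["val_loss_curve"])
        prior = None
        if "prior_mean" in f:
            prior = LatentPrior(min=f["prior_min"], max=f["prior_max"],
                                mean=f["prior_mean"], std=f["prior_std"])
    return coder, prior
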