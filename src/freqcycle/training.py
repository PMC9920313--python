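"""Unpaired patch-based CycleGAN training and whole-volume inference.

The trainer follows the published recipe: Adam (beta1 0.5, beta2 0.999) with
discriminator lr 0.0002 and generator lr 0.0004, batch size 1, 30,000
iterations with the learning rate fixed for the first half and decayed
linearly to zero over the second, 16x320x320 patches sampled from randomly
chosen CBCT and CT scans (any patient with any patient), and cycle /
frequency lambdas of 5.  Domain A is CBCT, domain B is CT: G maps A -> B,
F maps B -> A, with discriminators D_B (is it a real CT?) and D_A.

Online preprocessing per draw: body masking, CT field-of-view truncation to
the CBCT, air padding up to the patch size, patch extraction with the patch
centre inside the body, and clip-and-scale normalisation into [-1, 1].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .losses import (
    LossBreakdown,
    LossWeights,
    adversarial_loss,
    cycle_consistency_loss,
    structure_loss_interface,
    total_objective,
)
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)
from .dataset_prep import ScanRecord
from .volume import (
    AIR_HU,
    DEFAULT_BODY_THRESHOLD_HU,
    Volume3D,
    apply_mask,
    clip_and_scale,
    compute_body_mask,
    read_volume,
    truncate_fov,
)

__all__ = [
    "TrainConfig",
    "TrainState",
    "lr_schedule",
    "sample_scan_pair",
    "sample_unpaired_patch_pair",
    "init_state",
    "train_step",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "translate",
    "translate_volume",
    "sliding_window_apply",
    "blend_weight_map",
    "ImagePool",
]


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class TrainConfig:
    """Every knob of the training recipe; defaults follow the published table."""

    lr_discriminator: float = 0.0002
    lr_generator: float = 0.0004
    batch_size: int = 1
    total_iterations: int = 30000
    patch_size: tuple = (16, 320, 320)  # (z, x, y) voxels
    optimizer_betas: tuple = (0.5, 0.999)
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    image_pool_size: int = 50
    adversarial: str = "least_squares"  # or "vanilla"
    structure_loss: str = "frequency_l1"  # none | frequency_l1 | frequency_l2
    clip_window: tuple = (-1000.0, 2000.0)  # HU window mapped onto [-1, 1]
    body_threshold: float = DEFAULT_BODY_THRESHOLD_HU
    checkpoint_every: int = 1000
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)

    def __post_init__(self):
        if self.lr_discriminator <= 0 or self.lr_generator <= 0:
            raise ValueError("learning rates must be positive")
        if self.total_iterations <= 0:
            raise ValueError("total_iterations must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        div = self.generator.divisibility()
        for n, d, name in zip(self.patch_size, div, "zxy"):
            if n % d != 0:
                raise ValueError(
                    f"patch {name}-size {n} not divisible by the generator factor {d}"
                )

    def to_dict(self) -> dict:
        d = {
            "lr_discriminator": self.lr_discriminator,
            "lr_generator": self.lr_generator,
            "batch_size": self.batch_size,
            "total_iterations": self.total_iterations,
            "patch_size": list(self.patch_size),
            "optimizer_betas": list(self.optimizer_betas),
            "lambda_A": self.weights.lambda_A,
            "lambda_B": self.weights.lambda_B,
            "lambda_fA": self.weights.lambda_fA,
            "lambda_fB": self.weights.lambda_fB,
            "seed": self.seed,
            "image_pool_size": self.image_pool_size,
            "adversarial": self.adversarial,
            "structure_loss": self.structure_loss,
            "clip_window": list(self.clip_window),
            "body_threshold": self.body_threshold,
            "checkpoint_every": self.checkpoint_every,
            "normalization": self.generator.norm,
            "generator": dataclasses.asdict(self.generator),
            "discriminator": dataclasses.asdict(self.discriminator),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if gen:
            gen = {k: tuple(v) if isinstance(v, list) else v for k, v in gen.items()}
        disc = d.pop("discriminator", {})
        d.pop("normalization", None)
        weights = LossWeights(
            lambda_A=d.pop("lambda_A", 5.0),
            lambda_B=d.pop("lambda_B", 5.0),
            lambda_fA=d.pop("lambda_fA", 5.0),
            lambda_fB=d.pop("lambda_fB", 5.0),
        )
        for key in ("patch_size", "optimizer_betas", "clip_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(weights=weights,
                   generator=GeneratorSpec(**gen) if gen else GeneratorSpec(),
                   discriminator=DiscriminatorSpec(**disc) if disc else DiscriminatorSpec(),
                   **d)


def lr_schedule(iteration: int, total: int, base_lr: float) -> float:
    """Constant for the first half of training, then linear decay to zero."""
    if not 0 <= iteration <= total:
        raise ValueError(f"iteration {iteration} outside [0, {total}]")
    half = total / 2.0
    if iteration <= half:
        return float(base_lr)
    return float(base_lr * (total - iteration) / (total - half))


# ------------------------------------------------------------------- sampling
def sample_scan_pair(cbct_pool, ct_pool, rng: np.random.Generator):
    """Independently uniformly choose one scan record from each pool."""
    if not cbct_pool or not ct_pool:
        raise ValueError("scan pools must be non-empty")
    cbct = cbct_pool[int(rng.integers(len(cbct_pool)))]
    ct = ct_pool[int(rng.integers(len(ct_pool)))]
    return cbct, ct


class _VolumeCache:
    """Read + body-mask volumes once per path."""

    def __init__(self, body_threshold: float = DEFAULT_BODY_THRESHOLD_HU):
        self.body_threshold = body_threshold
        self._store: dict = {}

    def get(self, path_or_vol):
        if isinstance(path_or_vol, Volume3D):
            vol = path_or_vol
            key = id(path_or_vol)
        else:
            vol = None
            key = str(path_or_vol)
        if key not in self._store:
            if vol is None:
                vol = read_volume(key)
            mask = compute_body_mask(vol, self.body_threshold)
            self._store[key] = (apply_mask(vol, mask, AIR_HU), mask)
        return self._store[key]


def _pad_to(data: np.ndarray, target, fill: float) -> np.ndarray:
    pads = []
    for n, t in zip(data.shape, target):
        extra = max(0, t - n)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        return np.pad(data, pads, constant_values=fill)
    return data


def _extract_patch(vol: Volume3D, mask_data: np.ndarray, patch_zyx, rng) -> np.ndarray:
    data = _pad_to(vol.data, patch_zyx, AIR_HU)
    mdata = _pad_to(mask_data.astype(np.float64), patch_zyx, 0.0) > 0.5
    ranges = [data.shape[a] - patch_zyx[a] for a in range(3)]
    for _ in range(64):  # rejection-sample a patch whose centre is in the body
        start = tuple(int(rng.integers(r + 1)) for r in ranges)
        center = tuple(start[a] + patch_zyx[a] // 2 for a in range(3))
        if mdata[center]:
            break
    sl = tuple(slice(s, s + p) for s, p in zip(start, patch_zyx))
    return data[sl]


def sample_unpaired_patch_pair(cbct_pool, ct_pool, patch_size, rng,
                               cache: _VolumeCache | None = None,
                               clip_window=(-1000.0, 2000.0),
                               body_threshold: float = DEFAULT_BODY_THRESHOLD_HU):
    """Draw one normalized (CBCT patch, CT patch) training pair.

    ``patch_size`` is (z, x, y).  The pipeline per draw: pick a random scan
    from each pool, body-mask both, truncate the CT field-of-view to the
    CBCT, air-pad up to the patch size, and extract a patch whose centre
    lies inside the body; patches are then clipped and scaled to [-1, 1].
    Pool entries may be :class:`ScanRecord` (read from disk) or in-memory
    :class:`Volume3D`.
    """
    cache = cache or _VolumeCache(body_threshold)
    rec_cbct, rec_ct = sample_scan_pair(cbct_pool, ct_pool, rng)
    cbct, cbct_mask = cache.get(rec_cbct.path if isinstance(rec_cbct, ScanRecord) else rec_cbct)
    ct, ct_mask = cache.get(rec_ct.path if isinstance(rec_ct, ScanRecord) else rec_ct)
    ct = truncate_fov(ct, cbct)
    ct_mask_t = truncate_fov(
        Volume3D(ct_mask.data.astype(np.float64), ct_mask.spacing, ct_mask.origin), cbct,
        fill_value=0.0)

    pz, px, py = patch_size
    patch_zyx = (pz, py, px)
    cb_patch = _extract_patch(cbct, cbct_mask.data, patch_zyx, rng)
    ct_patch = _extract_patch(ct, ct_mask_t.data > 0.5, patch_zyx, rng)
    lo, hi = clip_window
    cb_vol = clip_and_scale(Volume3D(cb_patch, cbct.spacing, cbct.origin), lo, hi, "to_normalized")
    ct_vol = clip_and_scale(Volume3D(ct_patch, ct.spacing, ct.origin), lo, hi, "to_normalized")
    return cb_vol, ct_vol


# ----------------------------------------------------------------- image pool
class ImagePool:
    """History buffer of generated volumes for discriminator updates.

    With probability 1/2 a query returns a stored historical fake (and stores
    the new one); size 0 disables the pool entirely.
    """

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = int(size)
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, image: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return image
        if len(self.images) < self.size:
            self.images.append(image.copy())
            return image
        if self.rng.random() < 0.5:
            idx = int(self.rng.integers(self.size))
            out = self.images[idx].copy()
            self.images[idx] = image.copy()
            return out
        return image


# -------------------------------------------------------------------- state
@dataclass
class TrainState:
    config: TrainConfig
    G: nn.Module
    F: nn.Module
    D_A: nn.Module
    D_B: nn.Module
    opt_G: nn.Adam
    opt_F: nn.Adam
    opt_D_A: nn.Adam
    opt_D_B: nn.Adam
    pool_A: ImagePool
    pool_B: ImagePool
    rng: np.random.Generator
    iteration: int = 0


def init_state(config: TrainConfig) -> TrainState:
    seed = config.seed
    G = build_generator(config.generator, seed=seed)
    F_ = build_generator(config.generator, seed=seed + 1)
    D_A = build_discriminator(config.discriminator, seed=seed + 2)
    D_B = build_discriminator(config.discriminator, seed=seed + 3)
    betas = config.optimizer_betas
    rng = np.random.default_rng(seed + 4)
    return TrainState(
        config=config, G=G, F=F_, D_A=D_A, D_B=D_B,
        opt_G=nn.Adam(G.parameters(), lr=config.lr_generator, betas=betas),
        opt_F=nn.Adam(F_.parameters(), lr=config.lr_generator, betas=betas),
        opt_D_A=nn.Adam(D_A.parameters(), lr=config.lr_discriminator, betas=betas),
        opt_D_B=nn.Adam(D_B.parameters(), lr=config.lr_discriminator, betas=betas),
        pool_A=ImagePool(config.image_pool_size, np.random.default_rng(seed + 5)),
        pool_B=ImagePool(config.image_pool_size, np.random.default_rng(seed + 6)),
        rng=rng,
    )


def _sigmoid(t: Tensor) -> Tensor:
    return 1.0 / (1.0 + (-t).exp())


def _d_scores(net, x: Tensor, variant: str) -> Tensor:
    out = net(x)
    return _sigmoid(out) if variant == "vanilla" else out


def train_step(batch, state: TrainState) -> LossBreakdown:
    """One optimisation step: generators G and F jointly, then both
    discriminators on pooled historical fakes.  Deterministic given the
    state's RNG and batch.  Raises on a non-finite loss, naming the term."""
    cfg = state.config
    w = cfg.weights
    variant = cfg.adversarial
    cb, ct = batch
    real_A = Tensor(np.asarray(cb.data if isinstance(cb, Volume3D) else cb)[None, None])
    real_B = Tensor(np.asarray(ct.data if isinstance(ct, Volume3D) else ct)[None, None])

    # ---- generators ----
    for net in (state.G, state.F, state.D_A, state.D_B):
        net.zero_grad()
    fake_B = state.G(real_A)
    rec_A = state.F(fake_B)
    fake_A = state.F(real_B)
    rec_B = state.G(fake_A)

    adv_G = adversarial_loss(None, _d_scores(state.D_B, fake_B, variant), variant, "generator")
    adv_F = adversarial_loss(None, _d_scores(state.D_A, fake_A, variant), variant, "generator")
    cyc_A = cycle_consistency_loss(real_A, rec_A)
    cyc_B = cycle_consistency_loss(real_B, rec_B)
    use_freq = cfg.structure_loss != "none" and (w.lambda_fA > 0 or w.lambda_fB > 0)
    if use_freq:
        freq_A = structure_loss_interface(cfg.structure_loss, fake_B, real_A)
        freq_B = structure_loss_interface(cfg.structure_loss, fake_A, real_B)
    else:
        freq_A = freq_B = 0.0

    loss_G = adv_G + adv_F + w.lambda_A * cyc_A + w.lambda_B * cyc_B
    if use_freq:
        loss_G = loss_G + w.lambda_fA * freq_A + w.lambda_fB * freq_B
    breakdown = total_objective(adv_G, adv_F, cyc_A, cyc_B, freq_A, freq_B, w)
    loss_G.backward()
    state.opt_G.step()
    state.opt_F.step()

    # ---- discriminators (on detached, pooled fakes) ----
    for name, disc, opt, pool, real, fake in (
        ("D_B", state.D_B, state.opt_D_B, state.pool_B, real_B, fake_B),
        ("D_A", state.D_A, state.opt_D_A, state.pool_A, real_A, fake_A),
    ):
        pooled = Tensor(pool.query(fake.data))
        disc.zero_grad()
        loss_D = 0.5 * adversarial_loss(
            _d_scores(disc, real.detach(), variant),
            _d_scores(disc, pooled, variant),
            variant, "discriminator")
        if not np.isfinite(loss_D.item()):
            raise FloatingPointError(f"non-finite discriminator loss for {name}")
        loss_D.backward()
        opt.step()

    state.iteration += 1
    return breakdown


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(path, state: TrainState) -> None:
    arrays = {}
    for prefix, net in (("G", state.G), ("F", state.F), ("D_A", state.D_A), ("D_B", state.D_B)):
        for k, v in net.state_dict().items():
            arrays[f"{prefix}|{k}"] = v
    opt_meta = {}
    for prefix, opt in (("optG", state.opt_G), ("optF", state.opt_F),
                        ("optDA", state.opt_D_A), ("optDB", state.opt_D_B)):
        sd = opt.state_dict()
        opt_meta[prefix] = {"t": sd["t"], "lr": sd["lr"], "n": len(sd["m"])}
        for i, (m, v) in enumerate(zip(sd["m"], sd["v"])):
            arrays[f"{prefix}|m|{i}"] = m
            arrays[f"{prefix}|v|{i}"] = v
    for tag, pool in (("poolA", state.pool_A), ("poolB", state.pool_B)):
        for i, img in enumerate(pool.images):
            arrays[f"{tag}|{i}"] = img
    meta = {
        "iteration": state.iteration,
        "config": state.config.to_dict(),
        "optimizers": opt_meta,
        "pool_sizes": {"poolA": len(state.pool_A.images), "poolB": len(state.pool_B.images)},
        "rng_state": state.rng.bit_generator.state,
        "pool_rng_A": state.pool_A.rng.bit_generator.state,
        "pool_rng_B": state.pool_B.rng.bit_generator.state,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> TrainState:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    config = TrainConfig.from_dict(meta["config"])
    state = init_state(config)
    for prefix, net in (("G", state.G), ("F", state.F), ("D_A", state.D_A), ("D_B", state.D_B)):
        sd = {k.split("|", 1)[1]: v for k, v in arrays.items()
              if k.startswith(prefix + "|") and k.count("|") == 1 and not k.split("|", 1)[1].isdigit()}
        net.load_state_dict(sd)
    for prefix, opt in (("optG", state.opt_G), ("optF", state.opt_F),
                        ("optDA", state.opt_D_A), ("optDB", state.opt_D_B)):
        om = meta["optimizers"][prefix]
        n = om["n"]
        opt.load_state_dict({
            "t": om["t"], "lr": om["lr"],
            "m": [arrays[f"{prefix}|m|{i}"] for i in range(n)],
            "v": [arrays[f"{prefix}|v|{i}"] for i in range(n)],
        })
    for tag, pool in (("poolA", state.pool_A), ("poolB", state.pool_B)):
        n = meta.get("pool_sizes", {}).get(tag, 0)
        pool.images = [arrays[f"{tag}|{i}"] for i in range(n)]
    state.iteration = int(meta["iteration"])
    state.rng.bit_generator.state = meta["rng_state"]
    state.pool_A.rng.bit_generator.state = meta["pool_rng_A"]
    state.pool_B.rng.bit_generator.state = meta["pool_rng_B"]
    return state


# ------------------------------------------------------------------ training
def train(config: TrainConfig, cbct_pool, ct_pool, out_dir,
          resume_from=None, log_name: str = "loss_log.csv",
          stop_after: int | None = None) -> TrainState:
    """Run (or resume) training; writes a per-iteration CSV loss log and
    periodic checkpoints under ``out_dir``; the last checkpoint is always
    valid (written atomically via a temp file).  ``stop_after`` interrupts
    the run at the given iteration without touching the schedule horizon,
    from which ``resume_from`` continues bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state = load_checkpoint(resume_from) if resume_from else init_state(config)
    config = state.config
    cache = _VolumeCache(config.body_threshold)
    log_path = out_dir / log_name
    header = "iteration,lr,adv_G,adv_F,cycle_A,cycle_B,freq_A,freq_B,total\n"
    mode = "a" if (resume_from and log_path.exists()) else "w"
    with open(log_path, mode) as log:
        if mode == "w":
            log.write(header)
        while state.iteration < config.total_iterations:
            if stop_after is not None and state.iteration >= stop_after:
                break
            it = state.iteration
            lr_g = lr_schedule(it, config.total_iterations, config.lr_generator)
            lr_d = lr_schedule(it, config.total_iterations, config.lr_discriminator)
            state.opt_G.lr = state.opt_F.lr = lr_g
            state.opt_D_A.lr = state.opt_D_B.lr = lr_d
            batch = sample_unpaired_patch_pair(
                cbct_pool, ct_pool, config.patch_size, state.rng, cache=cache,
                clip_window=config.clip_window, body_threshold=config.body_threshold)
            bd = train_step(batch, state)
            log.write(f"{it},{lr_g:.8g},{bd.adv_G:.8g},{bd.adv_F:.8g},{bd.cycle_A:.8g},"
                      f"{bd.cycle_B:.8g},{bd.freq_A:.8g},{bd.freq_B:.8g},{bd.total:.8g}\n")
            if (state.iteration % config.checkpoint_every == 0
                    or state.iteration >= config.total_iterations):
                _atomic_checkpoint(out_dir / "checkpoint.npz", state)
    _atomic_checkpoint(out_dir / "checkpoint.npz", state)
    return state


def _atomic_checkpoint(path: Path, state: TrainState) -> None:
    tmp = path.with_suffix(".tmp.npz")
    save_checkpoint(tmp, state)
    tmp.replace(path)


# ----------------------------------------------------------------- inference
def blend_weight_map(shape, patch_size, overlap=None):
    """Normalised blending weights of the sliding-window tiling.

    Returns (weight_sum, positions): the accumulated raw weights per voxel
    (>= 1 everywhere, used as the normaliser) and the list of patch start
    indices.  After normalisation the per-voxel weights sum to exactly 1.
    """
    starts_per_axis = []
    for n, p in zip(shape, patch_size):
        if n < p:
            raise ValueError(f"volume axis {n} smaller than patch {p}; pad first")
        ov = p // 2 if overlap is None else overlap
        step = max(1, p - ov)
        starts = list(range(0, n - p + 1, step))
        if starts[-1] != n - p:
            starts.append(n - p)
        starts_per_axis.append(starts)
    wsum = np.zeros(shape)
    positions = []
    for s0 in starts_per_axis[0]:
        for s1 in starts_per_axis[1]:
            for s2 in starts_per_axis[2]:
                positions.append((s0, s1, s2))
                wsum[s0:s0 + patch_size[0], s1:s1 + patch_size[1], s2:s2 + patch_size[2]] += 1.0
    return wsum, positions


def sliding_window_apply(data: np.ndarray, fn, patch_size, overlap=None) -> np.ndarray:
    """Apply ``fn`` (patch -> same-shape patch) over overlapping tiles with
    weighted blending (uniform weights normalised to a partition of unity)."""
    wsum, positions = blend_weight_map(data.shape, patch_size, overlap)
    out = np.zeros_like(data, dtype=np.float64)
    for (s0, s1, s2) in positions:
        sl = (slice(s0, s0 + patch_size[0]), slice(s1, s1 + patch_size[1]),
              slice(s2, s2 + patch_size[2]))
        out[sl] += fn(data[sl])
    return out / wsum


def translate_volume(vol: Volume3D, network, clip_window=(-1000.0, 2000.0),
                     patch_size=(16, 320, 320), overlap=None) -> Volume3D:
    """Whole-volume translation with any patch network (callable on a
    (1, 1, z, y, x) Tensor).  Input is normalised through ``clip_window``,
    tiled, translated, blended, and mapped back to HU; spacing and origin
    are copied from the input."""
    lo, hi = clip_window
    norm = clip_and_scale(vol, lo, hi, "to_normalized")
    pz, px, py = patch_size
    patch_zyx = (pz, py, px)
    padded = _pad_to(norm.data, patch_zyx, -1.0)

    def fn(patch):
        out = network(Tensor(patch[None, None]))
        arr = out.data if isinstance(out, Tensor) else np.asarray(out)
        return arr[0, 0]

    blended = sliding_window_apply(padded, fn, patch_zyx, overlap)
    # crop any padding back off (centred)
    crop = tuple(slice((blended.shape[a] - norm.data.shape[a]) // 2,
                       (blended.shape[a] - norm.data.shape[a]) // 2 + norm.data.shape[a])
                 for a in range(3))
    result = Volume3D(np.clip(blended[crop], -1.0, 1.0), vol.spacing, vol.origin, "normalized")
    return clip_and_scale(result, lo, hi, "to_hu")


def translate(vol: Volume3D, checkpoint, direction: str = "cbct_to_ct",
              patch_size=None, overlap=None) -> Volume3D:
    """Translate a volume using a trained checkpoint (path or TrainState)."""
    if direction not in ("cbct_to_ct", "ct_to_cbct"):
        raise ValueError(f"direction must be 'cbct_to_ct' or 'ct_to_cbct', got {direction!r}")
    state = checkpoint if isinstance(checkpoint, TrainState) else load_checkpoint(checkpoint)
    net = state.G if direction == "cbct_to_ct" else state.F
    cfg = state.config
    return translate_volume(vol, net, clip_window=cfg.clip_window,
                            patch_size=patch_size or cfg.patch_size, overlap=overlap)
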