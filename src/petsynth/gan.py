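"""Conditional GAN for full-acquisition-time PET synthesis.

A coarse-to-fine generator translates normalized 2.5D slices of the
ultra-short scan (optionally fused with CT) into the corresponding
full-time slice, trained against a 3-scale patch discriminator with a
least-squares GAN objective plus a feature-matching loss (L1 between
discriminator activations for real and generated images, weight
``feature_matching_weight``).

Three model variants are supported:

* ``M1`` — PET-only input (3 channels);
* ``M2`` — PET/CT input (6 channels), plain first convolution;
* ``M3`` — PET/CT input with a 2-group first convolution, so PET and CT
  are processed by disjoint filter groups in the opening layer.

The public surface follows a model/results convention: build a
:class:`Pix2PixHD` from input/target sample arrays, call :meth:`~Pix2PixHD.fit`,
and get a :class:`Pix2PixHDResults` with the trained generator, the
per-epoch training log and a ``summary()``. :func:`fit_cross_validation`
trains one model per fold (folds split by patient, never by slice) and
returns an :class:`EnsembleResults` whose predictions average the fold
generators in (-1, 1) space before mapping back to SUV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .grid import VolumeGrid
from .nn import Adam, Generator, PatchDiscriminator
from .preprocess import NormSpec, Sample25D, postprocess_prediction, volume_to_samples

__all__ = [
    "NetConfig",
    "MODEL_VARIANTS",
    "variant_config",
    "build_generator",
    "build_discriminators",
    "feature_matching_loss",
    "Pix2PixHD",
    "Pix2PixHDResults",
    "train_fold",
    "fit_cross_validation",
    "EnsembleResults",
    "predict_ensemble",
    "save_generator",
    "load_generator",
]


@dataclass
class NetConfig:
    """Architecture and training hyperparameters.

    Training hyperparameters default to the published protocol: batch size
    4, learning rate 0.002 held for 50 epochs then decayed linearly to zero
    at epoch 100, five cross-validation folds, feature-matching weight 10,
    7x7 opening convolution, average-pooling downsampling, grayscale
    output, three discriminator scales. Width/depth parameters
    (``base_width``, ``n_downsamples``, ``n_resblocks``, ``ndf``) default to
    a small CPU-friendly scale; :meth:`full_scale` restores the full-size
    network.
    """

    input_channels: int = 3
    use_group_conv: bool = False
    initial_filter_size: int = 7
    output_channels: int = 1
    n_discriminator_scales: int = 3
    batch_size: int = 4
    learning_rate: float = 0.002
    epochs: int = 100
    decay_start_epoch: int = 50
    n_folds: int = 5
    feature_matching_weight: float = 10.0
    base_width: int = 16
    n_downsamples: int = 2
    n_resblocks: int = 2
    n_local_resblocks: int = 1
    ndf: int = 16
    n_discriminator_layers: int = 2
    image_size: int = 64
    seed: int = 0
    zero_init_final: bool = False

    def __post_init__(self) -> None:
        if self.input_channels not in (3, 6):
            raise ValueError(f"input_channels must be 3 or 6, got {self.input_channels}")
        if self.use_group_conv and self.input_channels != 6:
            raise ValueError("group convolution requires the 6-channel PET/CT input")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.epochs < self.decay_start_epoch:
            raise ValueError("epochs must be >= decay_start_epoch")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        # the deepest discriminator scale must still see a non-empty patch
        # grid: image_size / 2^(scales-1) / 2^(strided layers) >= 2
        min_size = 2 ** (self.n_discriminator_scales - 1 + self.n_discriminator_layers) * 2
        if self.image_size < min_size:
            raise ValueError(
                f"image_size {self.image_size} too small for "
                f"{self.n_discriminator_scales} discriminator scales with "
                f"{self.n_discriminator_layers} strided layers (need >= {min_size})"
            )

    def lr_at(self, epoch: int) -> float:
        """Learning rate at a 1-indexed epoch: constant, then linear to 0.

        Under the published protocol (100 epochs, decay after 50) the rate
        is 0.002 at epoch 50 and exactly 0 at epoch 100.
        """
        if epoch <= self.decay_start_epoch or self.epochs == self.decay_start_epoch:
            return self.learning_rate
        frac = (self.epochs - epoch) / (self.epochs - self.decay_start_epoch)
        return self.learning_rate * max(frac, 0.0)

    @classmethod
    def desk_scale(cls, **overrides) -> "NetConfig":
        """A few-epoch configuration for CPU smoke runs."""
        base = dict(epochs=6, decay_start_epoch=3, image_size=64)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def full_scale(cls, **overrides) -> "NetConfig":
        """Full-size network (224 px, wide generator, 3-layer discriminators)."""
        base = dict(
            base_width=64,
            n_downsamples=3,
            n_resblocks=9,
            n_local_resblocks=3,
            ndf=64,
            n_discriminator_layers=3,
            image_size=224,
        )
        base.update(overrides)
        return cls(**base)


#: The three model variants: input modalities and first-layer grouping.
MODEL_VARIANTS = {
    "M1": dict(input_channels=3, use_group_conv=False),
    "M2": dict(input_channels=6, use_group_conv=False),
    "M3": dict(input_channels=6, use_group_conv=True),
}


def variant_config(name: str, base: NetConfig | None = None) -> NetConfig:
    """Config for variant M1 (PET), M2 (PET/CT) or M3 (PET/CT, group conv)."""
    if name not in MODEL_VARIANTS:
        raise ValueError(f"unknown variant {name!r}; expected one of {sorted(MODEL_VARIANTS)}")
    base = base or NetConfig()
    return replace(base, **MODEL_VARIANTS[name])


def build_generator(cfg: NetConfig) -> Generator:
    """Coarse-to-fine generator for a config (see :class:`~petsynth.nn.Generator`)."""
    return Generator(
        in_channels=cfg.input_channels,
        base_width=cfg.base_width,
        n_downsamples=cfg.n_downsamples,
        n_resblocks=cfg.n_resblocks,
        n_local_resblocks=cfg.n_local_resblocks,
        initial_filter_size=cfg.initial_filter_size,
        out_channels=cfg.output_channels,
        groups=2 if cfg.use_group_conv else 1,
        seed=cfg.seed,
        zero_init_final=cfg.zero_init_final,
    )


def build_discriminators(cfg: NetConfig) -> list[PatchDiscriminator]:
    """One patch discriminator per image scale (full, 1/2, 1/4, ...).

    Each receives the (condition, output-or-target) channel concatenation,
    i.e. ``input_channels + output_channels`` channels.
    """
    cin = cfg.input_channels + cfg.output_channels
    return [
        PatchDiscriminator(cin, ndf=cfg.ndf, n_layers=cfg.n_discriminator_layers, seed=cfg.seed + s)
        for s in range(cfg.n_discriminator_scales)
    ]


def feature_matching_loss(real_feats, fake_feats) -> float:
    """Mean absolute difference between discriminator activations.

    ``real_feats``/``fake_feats`` are lists (one per discriminator) of lists
    of feature maps. The final score map of each discriminator is excluded;
    the L1 differences are averaged over layers and discriminators. The
    feature-matching weight is applied by the caller, not here.
    """
    if len(real_feats) != len(fake_feats):
        raise ValueError("feature lists differ in number of discriminators")
    total, count = 0.0, 0
    for fr_list, ff_list in zip(real_feats, fake_feats):
        if len(fr_list) != len(ff_list):
            raise ValueError("feature lists differ in number of layers")
        for fr, ff in zip(fr_list[:-1], ff_list[:-1]):
            if fr.shape != ff.shape:
                raise ValueError(f"feature shape mismatch: {fr.shape} vs {ff.shape}")
            total += float(np.mean(np.abs(fr - ff)))
            count += 1
    if count == 0:
        return 0.0
    return total / count


def _pool_pair(pair: np.ndarray, times: int) -> np.ndarray:
    for _ in range(times):
        n, c, h, w = pair.shape
        pair = pair.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    return pair


def _unpool_grad(grad: np.ndarray, times: int) -> np.ndarray:
    for _ in range(times):
        grad = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
    return grad


def _as_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Accept (inputs, targets) arrays or a list of (Sample25D, target)."""
    if isinstance(pairs, tuple) and len(pairs) == 2:
        x, y = pairs
        return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.float32)
    xs, ys = [], []
    for sample, target in pairs:
        img = sample.image if isinstance(sample, Sample25D) else np.asarray(sample)
        t = np.asarray(target, dtype=np.float32)
        if t.ndim == 2:
            t = t[None]
        xs.append(np.asarray(img, dtype=np.float32))
        ys.append(t)
    if not xs:
        raise ValueError("empty training fold")
    return np.stack(xs), np.stack(ys)


class Pix2PixHD:
    """Image-translation model over preprocessed 2.5D samples.

    Parameters
    ----------
    inputs : ndarray, shape (n, C, H, W)
        Conditioned inputs in (-1, 1); C matches ``config.input_channels``.
    targets : ndarray, shape (n, 1, H, W)
        Reference full-time center slices in (-1, 1).
    config : NetConfig
    """

    def __init__(self, inputs: np.ndarray, targets: np.ndarray, config: NetConfig) -> None:
        self.inputs = np.asarray(inputs, dtype=np.float32)
        self.targets = np.asarray(targets, dtype=np.float32)
        if self.inputs.ndim != 4 or self.targets.ndim != 4:
            raise ValueError("inputs and targets must be (n, C, H, W)")
        if len(self.inputs) == 0:
            raise ValueError("empty training set")
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets differ in length")
        if self.inputs.shape[1] != config.input_channels:
            raise ValueError(
                f"config expects {config.input_channels} input channels, "
                f"data has {self.inputs.shape[1]}"
            )
        self.config = config

    @classmethod
    def from_samples(cls, pairs, config: NetConfig) -> "Pix2PixHD":
        x, y = _as_arrays(pairs)
        return cls(x, y, config)

    def fit(
        self,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        verbose: bool = False,
    ) -> "Pix2PixHDResults":
        """Alternating generator/discriminator optimization.

        Each step updates the discriminators on (real, fake) pairs under the
        least-squares GAN loss, then the generator under GAN +
        feature-matching losses. Both optimizers are Adam (beta1=0.5) with
        the schedule of :meth:`NetConfig.lr_at`. The log records per-epoch
        mean losses and, when ``validation`` is given, the validation MAE in
        SUV over non-air target pixels.
        """
        cfg = self.config
        lam = cfg.feature_matching_weight
        gen = build_generator(cfg)
        discs = build_discriminators(cfg)
        opt_g = Adam(gen, lr=cfg.learning_rate)
        opt_d = Adam(discs, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 10_000)
        n = len(self.inputs)
        bs = min(cfg.batch_size, n)
        n_fm_layers = discs[0].n_feature_layers - 1
        rows = []
        for epoch in range(1, cfg.epochs + 1):
            lr = cfg.lr_at(epoch)
            order = rng.permutation(n)
            ep_d, ep_gan, ep_fm, n_batches = 0.0, 0.0, 0.0, 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                x = self.inputs[idx]
                y = self.targets[idx]
                fake = gen.forward(x)
                real_pair = np.concatenate([x, y], axis=1)
                fake_pair = np.concatenate([x, fake], axis=1)

                # ---- discriminator step (fake detached)
                loss_d = 0.0
                for d in discs:
                    d.zero_grad()
                for s, d in enumerate(discs):
                    rp = _pool_pair(real_pair, s)
                    fp = _pool_pair(fake_pair, s)
                    score_r, _ = d.forward(rp)
                    diff_r = score_r - 1.0
                    loss_d += 0.5 * float(np.mean(diff_r**2))
                    d.backward(diff_r / diff_r.size)
                    score_f, _ = d.forward(fp)
                    loss_d += 0.5 * float(np.mean(score_f**2))
                    d.backward(score_f / score_f.size)
                if lr > 0:
                    opt_d.step(lr)

                # ---- generator step
                gen.zero_grad()
                dfake = np.zeros_like(fake)
                loss_gan, fm_total, fm_count = 0.0, 0.0, 0
                for s, d in enumerate(discs):
                    d.zero_grad()  # gradients below are discarded
                    rp = _pool_pair(real_pair, s)
                    fp = _pool_pair(fake_pair, s)
                    _, feats_r = d.forward(rp)
                    score_f, feats_f = d.forward(fp)
                    diff = score_f - 1.0
                    loss_gan += float(np.mean(diff**2))
                    dscore = 2.0 * diff / diff.size
                    dfeats: list[np.ndarray | None] = [None] * len(feats_f)
                    for li in range(n_fm_layers):
                        fr, ff = feats_r[li], feats_f[li]
                        fm_total += float(np.mean(np.abs(ff - fr)))
                        fm_count += 1
                        dfeats[li] = (
                            lam
                            * np.sign(ff - fr)
                            / (ff.size * n_fm_layers * len(discs))
                        ).astype(np.float32)
                    dpair = d.backward(dscore, dfeats)
                    dfake += _unpool_grad(dpair, s)[:, cfg.input_channels :]
                gen.backward(dfake)
                if lr > 0:
                    opt_g.step(lr)
                ep_d += loss_d
                ep_gan += loss_gan
                ep_fm += fm_total / max(fm_count, 1)
                n_batches += 1
            row = {
                "epoch": epoch,
                "lr": lr,
                "loss_d": ep_d / n_batches,
                "loss_g_gan": ep_gan / n_batches,
                "loss_g_fm": ep_fm / n_batches,
            }
            if validation is not None:
                row["val_mae_suv"] = _validation_mae_suv(gen, *validation)
            rows.append(row)
            if verbose:
                print(
                    "epoch {epoch:3d} lr {lr:.5f} D {loss_d:.4f} "
                    "G-gan {loss_g_gan:.4f} G-fm {loss_g_fm:.4f}".format(**row)
                )
        return Pix2PixHDResults(gen, discs, pd.DataFrame(rows), cfg)


def _predict_batched(gen: Generator, inputs: np.ndarray, batch: int = 8) -> np.ndarray:
    outs = [gen.forward(inputs[i : i + batch]) for i in range(0, len(inputs), batch)]
    return np.concatenate(outs, axis=0)


def _validation_mae_suv(
    gen: Generator, inputs: np.ndarray, targets: np.ndarray, suv_max: float = 50.0
) -> float:
    """MAE in SUV between predictions and targets over non-air target pixels."""
    pred = _predict_batched(gen, inputs)
    mask = targets > -1.0 + 1e-3
    if not mask.any():
        return float("nan")
    diff = np.abs(pred - targets)[mask]
    return float(diff.mean()) * suv_max / 2.0


@dataclass
class Pix2PixHDResults:
    """Trained generator, discriminators, per-epoch log, and config."""

    generator: Generator
    discriminators: list[PatchDiscriminator]
    log: pd.DataFrame
    config: NetConfig

    def predict(self, inputs: np.ndarray, batch: int = 8) -> np.ndarray:
        """Generator outputs in (-1, 1) for a batch of preprocessed inputs."""
        return _predict_batched(self.generator, np.asarray(inputs, dtype=np.float32), batch)

    def summary(self) -> str:
        cfg = self.config
        last = self.log.iloc[-1]
        lines = [
            "Conditional PET-synthesis GAN (coarse-to-fine generator)",
            "=" * 58,
            f"input channels      {cfg.input_channels}"
            + ("  (2-group first conv)" if cfg.use_group_conv else ""),
            f"generator params    {self.generator.n_parameters():,}",
            f"discriminators      {len(self.discriminators)} scales, "
            f"{cfg.n_discriminator_layers}+1 conv blocks",
            f"epochs              {cfg.epochs} (lr {cfg.learning_rate}, "
            f"decay after {cfg.decay_start_epoch})",
            f"final losses        D {last['loss_d']:.4f}  G-gan {last['loss_g_gan']:.4f}  "
            f"G-fm {last['loss_g_fm']:.4f}",
        ]
        if "val_mae_suv" in self.log.columns:
            lines.append(f"final val MAE (SUV) {last['val_mae_suv']:.4f}")
        return "\n".join(lines)


def train_fold(pairs, cfg: NetConfig, fold_id: int = 0, val_pairs=None) -> Pix2PixHDResults:
    """Train one cross-validation fold.

    ``pairs`` is a list of (Sample25D, target-slice) tuples or an
    ``(inputs, targets)`` array pair; the fold id perturbs the seed so folds
    are independent. Folds must be assembled per patient by the caller —
    :func:`fit_cross_validation` does this and never splits by slice.
    """
    x, y = _as_arrays(pairs)
    model = Pix2PixHD(x, y, replace(cfg, seed=cfg.seed + 100 * fold_id))
    validation = _as_arrays(val_pairs) if val_pairs else None
    return model.fit(validation=validation)


@dataclass
class EnsembleResults:
    """Per-fold results plus mean-ensemble volume prediction."""

    fold_results: list[Pix2PixHDResults]
    fold_assignment: dict[str, int]
    config: NetConfig

    @property
    def generators(self) -> list[Generator]:
        return [r.generator for r in self.fold_results]

    def predict_volume(
        self,
        extreme: VolumeGrid,
        ct: VolumeGrid | None = None,
        norm: NormSpec = NormSpec(),
    ) -> VolumeGrid:
        samples = volume_to_samples(extreme, ct, norm=norm, pad_to=self.config.image_size)
        return predict_ensemble(self.generators, samples, extreme, norm)

    def summary(self) -> str:
        parts = [f"{len(self.fold_results)}-fold cross-validation ensemble", ""]
        for i, r in enumerate(self.fold_results):
            last = r.log.iloc[-1]
            extra = (
                f"  val MAE {last['val_mae_suv']:.4f} SUV"
                if "val_mae_suv" in r.log.columns
                else ""
            )
            parts.append(f"fold {i}: D {last['loss_d']:.4f} G-gan {last['loss_g_gan']:.4f}{extra}")
        return "\n".join(parts)


def fit_cross_validation(
    patient_data: dict[str, tuple[np.ndarray, np.ndarray]],
    cfg: NetConfig,
    verbose: bool = False,
) -> EnsembleResults:
    """K-fold cross-validation with folds split by patient.

    ``patient_data`` maps patient id to its ``(inputs, targets)`` sample
    arrays. Patients are shuffled with the config seed and dealt into
    ``cfg.n_folds`` folds; each fold's model trains on the other folds and
    validates on its own patients. All slices of a patient stay in one fold.
    """
    pids = sorted(patient_data)
    if len(pids) < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} patients, got {len(pids)}")
    rng = np.random.default_rng(cfg.seed)
    order = [pids[i] for i in rng.permutation(len(pids))]
    assignment = {pid: i % cfg.n_folds for i, pid in enumerate(order)}
    results = []
    for fold in range(cfg.n_folds):
        train_x = [patient_data[p][0] for p in pids if assignment[p] != fold]
        train_y = [patient_data[p][1] for p in pids if assignment[p] != fold]
        val_x = [patient_data[p][0] for p in pids if assignment[p] == fold]
        val_y = [patient_data[p][1] for p in pids if assignment[p] == fold]
        pairs = (np.concatenate(train_x), np.concatenate(train_y))
        val = (np.concatenate(val_x), np.concatenate(val_y)) if val_x else None
        res = train_fold(pairs, cfg, fold_id=fold, val_pairs=val)
        if verbose:
            print(f"fold {fold}: {res.log.iloc[-1].to_dict()}")
        results.append(res)
    return EnsembleResults(results, assignment, cfg)


def predict_ensemble(
    generators: Sequence[Generator],
    samples: Sequence[Sample25D] | np.ndarray,
    template: VolumeGrid,
    norm: NormSpec = NormSpec(),
) -> VolumeGrid:
    """Mean-ensemble prediction mapped back to an SUV volume.

    Per-slice outputs of each fold generator are averaged voxelwise in
    (-1, 1) space, then post-processed to SUV on the template grid.
    """
    if len(generators) == 0:
        raise ValueError("need at least one generator")
    if isinstance(samples, np.ndarray):
        inputs = np.asarray(samples, dtype=np.float32)
    else:
        inputs = np.stack([s.image for s in samples]).astype(np.float32)
    cins = {g.in_channels for g in generators}
    if len(cins) != 1 or inputs.shape[1] not in cins:
        raise ValueError(f"inconsistent input channel counts: models {cins}, data {inputs.shape[1]}")
    acc = np.zeros((len(inputs), 1, inputs.shape[2], inputs.shape[3]), dtype=np.float64)
    for gen in generators:
        acc += _predict_batched(gen, inputs)
    acc /= len(generators)
    return postprocess_prediction(acc, template, norm)


def save_generator(results: Pix2PixHDResults, path: str) -> None:
    """Checkpoint a trained generator (weights npz + embedded config yaml)."""
    arrays = {}
    for i, lyr in enumerate(results.generator.layers()):
        for key, val in lyr.params.items():
            arrays[f"{i}:{key}"] = val
    arrays["__config__"] = np.frombuffer(
        yaml.safe_dump(vars(results.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_generator(path: str) -> tuple[Generator, NetConfig]:
    data = np.load(path)
    cfg = NetConfig(**yaml.safe_load(bytes(data["__config__"]).decode()))
    gen = build_generator(cfg)
    for i, lyr in enumerate(gen.layers()):
        for key in lyr.params:
            lyr.params[key] = data[f"{i}:{key}"]
    return gen, cfg
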