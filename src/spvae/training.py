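"""Training: balanced sampling, KL annealing, Adam optimization.

The objective is the negative evidence lower bound summed over groups:
for each group, the expected negative-binomial mixture log-likelihood
minus the (annealed) KL divergences of the joint shared posterior z^PoE
and the private posterior z^p from the standard-normal prior.  Supervised
runs balance minibatches over cell-type labels with inverse-frequency
sampling weights; unsupervised (OT) runs use plain random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import nn
from .autograd import Tensor
from .data import GroupedExpressionBundle
from .encoder import EncoderConfig
from .model import GroupBatch, Mode, SharedPrivateVAE


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    dropout_rate: float = 0.1
    weight_decay: float = 1e-6
    batch_size: int = 256
    epochs: int | Literal["auto"] = "auto"
    kl_warmup_fraction: float = 1.0 / 3.0
    # hold the private path off for the first fifth of the steps so the
    # joint shared posterior and the mixing weights specialize first
    private_warmup_fraction: float = 0.2
    train_fraction: float = 0.9
    seed: int = 0
    mode: Mode = "supervised"
    ot_epsilon: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must be in (0, 1]")
        if not 0.0 < self.kl_warmup_fraction <= 1.0:
            raise ValueError("kl_warmup_fraction must be in (0, 1]")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if not 0.0 <= self.private_warmup_fraction < 1.0:
            raise ValueError("private_warmup_fraction must be in [0, 1)")


def sampler_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weight per cell (balanced label sampling)."""
    labels = np.asarray(labels)
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def kl_weight(step: int, total_warmup_steps: int) -> float:
    """Linear KL annealing ramp: 0 at step 0, 1 from the end of warmup on."""
    if step < 0:
        raise ValueError("step must be nonnegative")
    if total_warmup_steps <= 0:
        return 1.0
    return min(1.0, step / total_warmup_steps)


def default_epochs(n_total_cells: int) -> int:
    """Cell-count-based default training length: 400 epochs at 20k cells,
    scaled inversely with dataset size, capped at 400 and floored at 1."""
    if n_total_cells <= 0:
        raise ValueError("cell count must be positive")
    return max(1, min(int(round(400 * 20_000 / n_total_cells)), 400))


def elbo_loss(
    batches: list[GroupBatch],
    model: SharedPrivateVAE,
    kl_weight: float,
) -> tuple[Tensor, dict[str, float]]:
    """Negative ELBO (mean per cell, summed over groups) plus components."""
    outputs = model.forward(batches)
    loss = None
    recon_total = kl_poe_total = kl_private_total = 0.0
    for out in outputs:
        recon = out.log_likelihood.mean()
        klp = out.kl_private.mean()
        klj = out.kl_poe.mean()
        group_loss = -(recon - kl_weight * (klj + klp))
        loss = group_loss if loss is None else loss + group_loss
        recon_total += float(recon.data)
        kl_poe_total += float(klj.data)
        kl_private_total += float(klp.data)
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            "non-finite loss: "
            f"reconstruction={recon_total}, kl_poe={kl_poe_total}, "
            f"kl_private={kl_private_total}"
        )
    components = {
        "loss": float(loss.data),
        "reconstruction": -recon_total,
        "kl_poe": kl_poe_total,
        "kl_private": kl_private_total,
        "kl_weight": kl_weight,
    }
    return loss, components


@dataclass
class TrainingHistory:
    records: list[dict] = field(default_factory=list)

    def log(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _common_gene_indices(
    bundle: GroupedExpressionBundle, min_common: int
) -> list[np.ndarray] | None:
    """Aligned index arrays of genes shared by both groups, if enough exist.

    Matched features let the OT matching run on data space instead of the
    untrained latent space; below ``min_common`` genes the overlap is too
    thin to define a useful cost.
    """
    names0 = bundle.groups[0].gene_names
    names1 = bundle.groups[1].gene_names
    common = sorted(set(names0) & set(names1))
    if len(common) < min_common:
        return None
    if len(common) > 1024:
        # the cost only needs enough genes to resolve the shared structure
        common = [common[i] for i in np.linspace(0, len(common) - 1, 1024).astype(int)]
    lookup0 = {g: i for i, g in enumerate(names0)}
    lookup1 = {g: i for i, g in enumerate(names1)}
    return [
        np.array([lookup0[g] for g in common]),
        np.array([lookup1[g] for g in common]),
    ]


def _moment_dispersion(
    counts: np.ndarray, lib: np.ndarray, proportions: np.ndarray
) -> np.ndarray:
    """Method-of-moments per-gene NB inverse dispersion for initialization.

    Under x_ng ~ NB(mean tau_n * p_g, theta_g): Var = mu + mu^2/theta, so
    theta_g = sum(mu^2) / (sum((x - mu)^2) - sum(mu)) per gene.
    """
    mu = lib[:, None].astype(np.float64) * proportions[None, :]
    resid = (counts - mu) ** 2
    excess = resid.sum(axis=0) - mu.sum(axis=0)
    theta = mu_sq = (mu**2).sum(axis=0)
    theta = np.divide(
        mu_sq, np.maximum(excess, 1e-8),
        out=np.full(counts.shape[1], 1e3), where=excess > 0,
    )
    return np.clip(theta, 0.05, 1e3)


def _make_batch(record, lib, indices, label_codes) -> GroupBatch:
    onehot = np.zeros((len(indices), record.n_batches), dtype=np.float32)
    onehot[np.arange(len(indices)), record.batch_codes[indices]] = 1.0
    return GroupBatch(
        x=record.counts[indices].astype(np.float32),
        s=onehot,
        tau=lib[indices],
        labels=None if label_codes is None else label_codes[indices],
    )


def train(
    bundle: GroupedExpressionBundle,
    encoder_config: EncoderConfig | None = None,
    config: TrainingConfig | None = None,
) -> tuple[SharedPrivateVAE, TrainingHistory]:
    """Fit the model on a validated bundle.

    Performs a train/validation split per group, then per-minibatch Adam
    updates of all encoders and decoders jointly under the annealed
    objective.  Deterministic given ``config.seed``.
    """
    config = config or TrainingConfig()
    config.validate()
    encoder_config = encoder_config or EncoderConfig(
        dropout_rate=config.dropout_rate
    )
    if config.mode == "supervised" and bundle.label_vocabulary is None:
        raise ValueError("supervised mode requires labels; use an OT mode instead")

    rng = np.random.default_rng(config.seed)
    scale_init, theta_init = [], []
    for g, record in enumerate(bundle.groups):
        p = record.counts.sum(axis=0).astype(np.float64)
        p = np.maximum(p / p.sum(), 1e-10)
        scale_init.append(np.log(p))
        theta_init.append(
            _moment_dispersion(record.counts, bundle.library_sizes[g], p)
        )
    common_indices = None
    if config.mode != "supervised" and bundle.n_groups == 2:
        common_indices = _common_gene_indices(bundle, min_common=64)
    model = SharedPrivateVAE(
        n_genes_per_group=[g.n_genes for g in bundle.groups],
        n_batches_per_group=[g.n_batches for g in bundle.groups],
        encoder_config=encoder_config,
        mode=config.mode,
        ot_epsilon=config.ot_epsilon,
        seed=int(rng.integers(2**31)),
        scale_logit_init=scale_init,
        theta_init=theta_init,
        common_gene_indices=common_indices,
    )

    label_codes = [
        bundle.label_codes(g) if bundle.groups[g].labels is not None else None
        for g in range(bundle.n_groups)
    ]
    train_idx, val_idx, weights = [], [], []
    for g, record in enumerate(bundle.groups):
        perm = rng.permutation(record.n_cells)
        n_train = max(1, int(round(config.train_fraction * record.n_cells)))
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
        if config.mode == "supervised":
            w = sampler_weights(label_codes[g][perm[:n_train]])
            weights.append(w / w.sum())
        else:
            weights.append(None)

    total_cells = sum(g.n_cells for g in bundle.groups)
    n_epochs = (
        default_epochs(total_cells) if config.epochs == "auto" else int(config.epochs)
    )
    steps_per_epoch = max(
        1, max(int(np.ceil(len(t) / config.batch_size)) for t in train_idx)
    )
    warmup_steps = max(
        1, int(round(config.kl_warmup_fraction * n_epochs * steps_per_epoch))
    )
    # shared-first curriculum: the private path is switched off while the
    # shared path and its mixing weights specialize, then released
    private_off_steps = int(
        round(config.private_warmup_fraction * n_epochs * steps_per_epoch)
    )

    optimizer = nn.Adam(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    history = TrainingHistory()
    step = 0
    for epoch in range(n_epochs):
        model.train()
        epoch_stats: list[dict[str, float]] = []
        for _ in range(steps_per_epoch):
            klw = kl_weight(step, warmup_steps)
            model.private_path_scale = 0.0 if step < private_off_steps else 1.0
            batches = []
            for g, record in enumerate(bundle.groups):
                idx_pool = train_idx[g]
                size = min(config.batch_size, len(idx_pool))
                if weights[g] is not None:
                    chosen = rng.choice(idx_pool, size=size, p=weights[g])
                else:
                    chosen = rng.choice(idx_pool, size=size, replace=False)
                batches.append(
                    _make_batch(record, bundle.library_sizes[g], chosen, label_codes[g])
                )
            loss, components = elbo_loss(batches, model, klw)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_stats.append(components)
            step += 1
        entry = {
            key: float(np.mean([s[key] for s in epoch_stats]))
            for key in epoch_stats[0]
        }
        entry["epoch"] = epoch
        if epoch % 5 == 0 or epoch == n_epochs - 1:
            entry["validation_loss"] = _validation_loss(
                model, bundle, val_idx, label_codes, entry["kl_weight"]
            )
        else:
            entry["validation_loss"] = float("nan")
        history.log(**entry)
    model.private_path_scale = 1.0
    model.eval()
    return model, history


def _validation_loss(model, bundle, val_idx, label_codes, klw) -> float:
    if any(len(v) == 0 for v in val_idx):
        return float("nan")
    model.eval()
    batches = []
    for g, record in enumerate(bundle.groups):
        idx = val_idx[g]
        batches.append(
            _make_batch(record, bundle.library_sizes[g], idx, label_codes[g])
        )
    _, components = elbo_loss(batches, model, klw)
    model.train()
    return components["loss"]
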