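"""The shared/private grouped VAE: wiring of encoders, PoE and decoders.

One :class:`SharedPrivateVAE` owns, per group, an inference network and a
negative-binomial mixture decoder, plus the supervision device that builds
the joint shared posterior: a label-wise Product of Experts in supervised
mode, or an entropic optimal-transport matching (hard one-to-one by
default, soft aggregation optionally) in unsupervised mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .data import GroupedExpressionBundle
from .decoder import GroupDecoder
from .encoder import EncoderConfig, GaussianPosterior, GroupEncoder, reparameterize
from .poe import assemble_poe_tensor, class_aggregate, combine_class_stats
from .transport import (
    TransportPlan,
    compute_transport_plan,
    hard_match,
    poe_from_matches,
    soft_match_params,
)

Mode = Literal["supervised", "ot_hard", "ot_soft"]

EVAL_CHUNK = 2048


@dataclass
class GroupBatch:
    """One group's minibatch, ready for a forward pass."""

    x: np.ndarray            # counts, cells x genes
    s: np.ndarray            # batch one-hot
    tau: np.ndarray          # library sizes
    labels: np.ndarray | None = None   # class codes (supervised mode)


@dataclass
class GroupForward:
    """Per-group forward-pass results."""

    private: GaussianPosterior
    shared: GaussianPosterior
    poe: GaussianPosterior
    log_likelihood: Tensor   # per cell
    kl_private: Tensor       # per cell
    kl_poe: Tensor           # per cell
    pi: Tensor


def gaussian_kl_standard(posterior: GaussianPosterior):
    """KL( N(mean, var) || N(0, I) ), summed over dimensions, per cell."""
    mean, var = posterior.mean, posterior.var
    if isinstance(mean, Tensor) or isinstance(var, Tensor):
        return ag.gaussian_kl(mean, var)
    return 0.5 * (mean**2 + var - 1.0 - np.log(var)).sum(axis=1)


class SharedPrivateVAE(nn.Module):
    def __init__(
        self,
        n_genes_per_group: list[int],
        n_batches_per_group: list[int],
        encoder_config: EncoderConfig,
        mode: Mode = "supervised",
        ot_epsilon: float = 1.0,
        seed: int = 0,
        mixing_hidden: int = 256,
        scale_logit_init: list[np.ndarray] | None = None,
        theta_init: list[np.ndarray] | None = None,
        common_gene_indices: list[np.ndarray] | None = None,
    ):
        super().__init__()
        if mode not in ("supervised", "ot_hard", "ot_soft"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode != "supervised" and len(n_genes_per_group) != 2:
            raise ValueError("optimal-transport matching supports exactly two groups")
        self.mode = mode
        self.ot_epsilon = ot_epsilon
        self.encoder_config = encoder_config
        # with matched features the transport cost lives in data space
        # (log1p counts over the common genes), which decouples the cell
        # matching from the not-yet-trained latent geometry; without a
        # usable common gene set the cost falls back to the shared
        # posterior means
        self.common_gene_indices = common_gene_indices
        # curriculum knob set by the training loop: 0 disables the private
        # path (shared-first phase), 1 is normal operation
        self.private_path_scale = 1.0
        param_rng = np.random.default_rng(seed)
        self.noise_rng = np.random.default_rng(param_rng.integers(2**31))
        self.encoders = [
            GroupEncoder(g, b, encoder_config, param_rng)
            for g, b in zip(n_genes_per_group, n_batches_per_group)
        ]
        self.decoders = [
            GroupDecoder(
                g,
                encoder_config.d_private,
                encoder_config.d_shared,
                b,
                param_rng,
                mixing_hidden=mixing_hidden,
                dropout_rate=encoder_config.dropout_rate,
                scale_logit_init=None if scale_logit_init is None else scale_logit_init[i],
                theta_init=None if theta_init is None else theta_init[i],
            )
            for i, (g, b) in enumerate(zip(n_genes_per_group, n_batches_per_group))
        ]

    @property
    def n_groups(self) -> int:
        return len(self.encoders)

    # -- joint shared posterior ------------------------------------------------
    def _poe_supervised(
        self, shared: list[GaussianPosterior], batches: list[GroupBatch]
    ) -> list[GaussianPosterior]:
        stats = [
            class_aggregate(post, batch.labels)
            for post, batch in zip(shared, batches)
        ]
        class_poe = combine_class_stats(stats)
        return [
            assemble_poe_tensor(class_poe, batch.labels) for batch in batches
        ]

    def _poe_transport(
        self,
        shared: list[GaussianPosterior],
        match_features: list[np.ndarray] | None = None,
    ) -> list[GaussianPosterior]:
        if match_features is not None:
            f1, f2 = match_features
        else:
            f1 = shared[0].mean.data if isinstance(shared[0].mean, Tensor) else shared[0].mean
            f2 = shared[1].mean.data if isinstance(shared[1].mean, Tensor) else shared[1].mean
        plan = compute_transport_plan(
            f1, f2, epsilon=self.ot_epsilon, max_iters=200, tol=1e-7,
            normalize_cost=True,
        )
        # cost and marginals are symmetric, so the reverse plan is the transpose
        plans = [
            plan,
            TransportPlan(plan.T.T.copy(), plan.epsilon, plan.converged, plan.n_iters),
        ]
        out = []
        for g, (local, pl) in enumerate(zip(shared, plans)):
            other = shared[1 - g]
            if self.mode == "ot_hard":
                partner = hard_match(pl)
                matched = GaussianPosterior(
                    mean=ag.take_rows(ag.as_tensor(other.mean), partner),
                    var=ag.take_rows(ag.as_tensor(other.var), partner),
                )
            else:
                matched = soft_match_params(pl, other)
            out.append(poe_from_matches(local, matched))
        return out

    def _match_features(self, xs: list[np.ndarray]) -> list[np.ndarray] | None:
        if self.common_gene_indices is None:
            return None
        return [
            np.log1p(x[:, idx].astype(np.float32))
            for x, idx in zip(xs, self.common_gene_indices)
        ]

    # -- forward ---------------------------------------------------------------
    def forward(self, batches: list[GroupBatch]) -> list[GroupForward]:
        if len(batches) != self.n_groups:
            raise ValueError("one minibatch per group is required")
        private: list[GaussianPosterior] = []
        shared: list[GaussianPosterior] = []
        for enc, batch in zip(self.encoders, batches):
            p, s = enc(batch.x, batch.s)
            private.append(p)
            shared.append(s)
        if self.mode == "supervised":
            if any(b.labels is None for b in batches):
                raise ValueError("supervised mode requires labels in every batch")
            poes = self._poe_supervised(shared, batches)
        else:
            poes = self._poe_transport(
                shared, self._match_features([b.x for b in batches])
            )

        results: list[GroupForward] = []
        for g, (batch, dec) in enumerate(zip(batches, self.decoders)):
            z_p = reparameterize(private[g], self.noise_rng)
            if self.private_path_scale != 1.0:
                z_p = z_p * float(self.private_path_scale)
            z_poe = reparameterize(poes[g], self.noise_rng)
            pi, rho, gamma = dec(z_p, z_poe, batch.s)
            ll = ag.nb_two_part_mixture_loglik(
                batch.x, pi, batch.tau, rho, gamma, dec.theta
            )
            results.append(
                GroupForward(
                    private=private[g],
                    shared=shared[g],
                    poe=poes[g],
                    log_likelihood=ll,
                    kl_private=gaussian_kl_standard(private[g]),
                    kl_poe=gaussian_kl_standard(poes[g]),
                    pi=pi,
                )
            )
        return results

    # -- latent extraction (evaluation mode, posterior means) -------------------
    def _encode_all(
        self, bundle: GroupedExpressionBundle
    ) -> tuple[list[GaussianPosterior], list[GaussianPosterior]]:
        self.eval()
        private, shared = [], []
        for g, record in enumerate(bundle.groups):
            s_onehot = record.batch_onehot()
            p_means, p_vars, s_means, s_vars = [], [], [], []
            for start in range(0, record.n_cells, EVAL_CHUNK):
                sl = slice(start, start + EVAL_CHUNK)
                p, s = self.encoders[g](record.counts[sl], s_onehot[sl])
                p_means.append(p.mean.data)
                p_vars.append(p.var.data)
                s_means.append(s.mean.data)
                s_vars.append(s.var.data)
            private.append(
                GaussianPosterior(np.vstack(p_means), np.vstack(p_vars))
            )
            shared.append(GaussianPosterior(np.vstack(s_means), np.vstack(s_vars)))
        return private, shared

    def get_latents(self, bundle: GroupedExpressionBundle) -> dict:
        """Posterior means for downstream analysis.

        Returns per-group private means, per-group per-cell shared posterior
        means (pre-PoE), and per-group per-cell joint z^PoE means built with
        the model's supervision device over the full dataset.
        """
        private, shared = self._encode_all(bundle)
        if self.mode == "supervised":
            stats = [
                class_aggregate(shared[g], bundle.label_codes(g))
                for g in range(self.n_groups)
            ]
            class_poe = combine_class_stats(stats)
            poes = [
                assemble_poe_tensor(class_poe, bundle.label_codes(g))
                for g in range(self.n_groups)
            ]
        else:
            poes = self._poe_transport(
                shared, self._match_features([g.counts for g in bundle.groups])
            )
        return {
            "private": [p.numpy().mean for p in private],
            "shared_posterior": [s.numpy().mean for s in shared],
            "poe": [p.numpy().mean for p in poes],
        }

    def mixing_parameters(self, bundle: GroupedExpressionBundle, group: int) -> np.ndarray:
        """Mixing probabilities pi (cells x genes) at posterior means."""
        private, shared = self._encode_all(bundle)
        if self.mode == "supervised":
            stats = [
                class_aggregate(shared[g], bundle.label_codes(g))
                for g in range(self.n_groups)
            ]
            class_poe = combine_class_stats(stats)
            poe = assemble_poe_tensor(class_poe, bundle.label_codes(group))
        else:
            poe = self._poe_transport(
                shared, self._match_features([g.counts for g in bundle.groups])
            )[group]
        record = bundle.groups[group]
        s_onehot = record.batch_onehot()
        z_p = private[group].numpy().mean
        z_poe = poe.numpy().mean
        out = []
        self.eval()
        for start in range(0, record.n_cells, EVAL_CHUNK):
            sl = slice(start, start + EVAL_CHUNK)
            pi, _, _ = self.decoders[group](z_p[sl], z_poe[sl], s_onehot[sl])
            out.append(pi.data)
        return np.vstack(out)
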