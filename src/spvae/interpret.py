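"""Interpretation of the linear decoders: gene loadings and mixing weights.

Because each scale decoder is a single affine map followed by batch
normalization, the effective contribution of latent dimension k to gene g
is the raw weight rescaled by the batch-norm statistics:

    loadings = diag( gamma_bn / sqrt(running_var + eps) ) . W

Batch-covariate columns are excluded; only the latent part of the decoder
is reported.  The nonlinear mixing network yields no loadings; its output
pi is exposed directly per cell and gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data import GroupedExpressionBundle
from .decoder import GroupDecoder
from .model import SharedPrivateVAE

Subspace = Literal["shared", "private"]


@dataclass
class LoadingsMatrix:
    values: np.ndarray     # dims x genes
    gene_names: list[str]
    subspace: Subspace
    group: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[f"dim{k}" for k in range(self.values.shape[0])],
            columns=self.gene_names,
        )


def decoder_loadings(
    decoder: GroupDecoder,
    subspace: Subspace,
    gene_names: list[str] | None = None,
    group: int = 0,
) -> LoadingsMatrix:
    """Batch-norm-corrected loadings of one group's linear scale decoder."""
    scale_dec = decoder.rho_decoder if subspace == "private" else decoder.gamma_decoder
    bn = scale_dec.bn
    if bn.n_updates == 0:
        raise RuntimeError(
            "batch-normalization statistics are untrained; fit the model first"
        )
    correction = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
    W = scale_dec.latent.weight.data  # (d, genes)
    values = correction[None, :] * W
    names = gene_names or [f"gene_{i}" for i in range(values.shape[1])]
    return LoadingsMatrix(
        values=np.asarray(values, dtype=np.float64),
        gene_names=list(names),
        subspace=subspace,
        group=group,
    )


def model_loadings(
    model: SharedPrivateVAE, bundle: GroupedExpressionBundle, group: int, subspace: Subspace
) -> LoadingsMatrix:
    return decoder_loadings(
        model.decoders[group],
        subspace,
        gene_names=bundle.groups[group].gene_names,
        group=group,
    )


def top_genes(
    loadings: LoadingsMatrix,
    dim: int,
    k: int,
    by: Literal["signed", "absolute"] = "absolute",
) -> list[str]:
    """Top-k genes of one latent dimension; ties break by gene name."""
    if not 0 <= dim < loadings.values.shape[0]:
        raise IndexError(f"dimension {dim} out of range")
    row = loadings.values[dim]
    if k > len(row):
        warnings.warn(
            f"k={k} exceeds the {len(row)} genes available; truncating",
            stacklevel=2,
        )
        k = len(row)
    score = row if by == "signed" else np.abs(row)
    order = sorted(
        range(len(row)), key=lambda i: (-score[i], loadings.gene_names[i])
    )
    return [loadings.gene_names[i] for i in order[:k]]


def global_gene_importance(loadings: LoadingsMatrix) -> pd.Series:
    """L2 norm of each gene's loading column across latent dimensions."""
    return pd.Series(
        np.linalg.norm(loadings.values, axis=0), index=loadings.gene_names
    )


def gene_loading_contrast(
    shared: LoadingsMatrix,
    private: LoadingsMatrix,
    aggregate: Literal["max_abs", "median_abs"] = "max_abs",
) -> pd.Series:
    """Per-gene |shared| minus |private| loading, aggregated over dimensions.

    Positive values flag genes driven by the shared space, negative values
    genes driven by the private space.
    """
    if shared.gene_names != private.gene_names:
        raise ValueError("loadings matrices cover different gene sets")
    agg = {"max_abs": np.max, "median_abs": np.median}[aggregate]
    s = agg(np.abs(shared.values), axis=0)
    p = agg(np.abs(private.values), axis=0)
    return pd.Series(s - p, index=shared.gene_names)


def mixing_parameter(
    model: SharedPrivateVAE,
    bundle: GroupedExpressionBundle,
    genes: list[str],
    group: int,
) -> pd.DataFrame:
    """Per-cell mixing probability pi for the named genes, at posterior means.

    pi near 1 means the gene's expression in that cell is routed through the
    shared decoder path; near 0, through the private path.
    """
    record = bundle.groups[group]
    lookup = {g: i for i, g in enumerate(record.gene_names)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise KeyError(f"genes not present in group {group}: {missing}")
    cols = [lookup[g] for g in genes]
    pi = model.mixing_parameters(bundle, group)
    return pd.DataFrame(pi[:, cols], index=record.cell_names, columns=genes)
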