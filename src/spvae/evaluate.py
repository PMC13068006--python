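"""Quantitative evaluation of latent representations.

Two diagnostics: (1) *linear probing* - a ridge classifier under 5-fold
stratified cross-validation quantifies how much label information a frozen
latent space encodes; (2) the *matched cell-type distance* - the median
cross-group Euclidean distance between cells of the same class in the
shared space, compared against distances from classes unique to one group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler


@dataclass
class ProbingReport:
    latent_tag: str
    target: str
    n_folds: int
    fold_accuracies: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def __str__(self) -> str:
        return (
            f"probe[{self.latent_tag} -> {self.target}]: "
            f"{self.mean_accuracy:.3f} +/- {self.sd_accuracy:.3f} "
            f"({self.n_folds} folds)"
        )


def linear_probe(
    latent: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    latent_tag: str = "latent",
    target: str = "label",
) -> ProbingReport:
    """Ridge-classifier probing accuracy under stratified cross-validation.

    Features are standardized inside each training fold; the regularization
    strength is fixed at 1.0.
    """
    latent = np.asarray(latent)
    labels = np.asarray(labels)
    if latent.shape[0] != labels.shape[0]:
        raise ValueError("latent rows and labels must align")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"a class has only {counts.min()} members; "
            f"use at most {counts.min()} folds"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accuracies = []
    for train, test in splitter.split(latent, labels):
        clf = make_pipeline(StandardScaler(), RidgeClassifier(alpha=1.0))
        clf.fit(latent[train], labels[train])
        accuracies.append(float(clf.score(latent[test], labels[test])))
    return ProbingReport(
        latent_tag=latent_tag,
        target=target,
        n_folds=n_folds,
        fold_accuracies=accuracies,
    )


def stack_private_latents(private_latents: list[np.ndarray]) -> np.ndarray:
    """Combine per-group private coordinates into one probing matrix.

    Each group's private space has its own, mutually incomparable axes, so
    the groups are placed in disjoint column blocks (cells x sum of private
    dims) with zeros outside a cell's own block.  This is the standard way
    to probe group-specific subspaces jointly: a linear classifier can use
    each block independently without pretending the axes align.
    """
    dims = [z.shape[1] for z in private_latents]
    total = sum(dims)
    blocks = []
    offset = 0
    for z, d in zip(private_latents, dims):
        out = np.zeros((z.shape[0], total), dtype=z.dtype)
        out[:, offset : offset + d] = z
        blocks.append(out)
        offset += d
    return np.vstack(blocks)


@dataclass
class DistanceReport:
    matched: dict[str, float]                      # class -> median cross-group distance
    unmatched: dict[tuple[str, str], float]        # (unique class, other class) -> median

    @property
    def matched_median(self) -> float:
        return float(np.median(list(self.matched.values())))

    @property
    def unmatched_median(self) -> float:
        return float(np.median(list(self.unmatched.values())))


def matched_celltype_distance(
    shared_latents: list[np.ndarray],
    labels: list[np.ndarray],
) -> DistanceReport:
    """Median cross-group distances between matching (and unique) classes.

    For a class present in both groups, the median of all pairwise
    Euclidean distances between its group-1 and group-2 cells.  For a class
    unique to one group, the median distance to each other class's cells in
    the opposite group.
    """
    if len(shared_latents) != 2 or len(labels) != 2:
        raise ValueError("exactly two groups are expected")
    z1, z2 = (np.asarray(z) for z in shared_latents)
    l1, l2 = (np.asarray(l) for l in labels)
    if z1.shape[1] != z2.shape[1]:
        raise ValueError("shared latent dimensionality differs between groups")
    classes1, classes2 = set(l1), set(l2)
    matched, unmatched = {}, {}
    for c in sorted(classes1 | classes2):
        in1, in2 = c in classes1, c in classes2
        if in1 and in2:
            d = cdist(z1[l1 == c], z2[l2 == c])
            matched[c] = float(np.median(d))
        elif in1 or in2:
            # class unique to one group: distances to every other class
            # in the opposite group
            own_z, other_z, other_l = (
                (z1[l1 == c], z2, l2) if in1 else (z2[l2 == c], z1, l1)
            )
            for other_class in sorted(set(other_l)):
                d = cdist(own_z, other_z[other_l == other_class])
                unmatched[(c, other_class)] = float(np.median(d))
    return DistanceReport(matched=matched, unmatched=unmatched)
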