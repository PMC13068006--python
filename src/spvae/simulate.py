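"""Synthetic grouped scRNA-seq counts with planted shared and private structure.

The generator emulates the statistical structure of a Splat-style "groups"
simulation: every cell belongs to one of ``n_cell_types`` shared cell types
(differential expression over the shared genes, identical in both groups)
and, within its group, to one of that group's private *gene programs*.
Programs live on a common block of extra genes appended to the shared
genes; each program boosts its own random subset of that block, so the
block only carries a group's program structure in the owning group.
Counts are Poisson draws of a
library-size-scaled multinomial rate, with separate expected depths for
the deeply sequenced cell-type block (``lib_loc_shared``, Splat's default
location 11, about 60k counts) and the shallow program block
(``lib_loc``, location 6, about 400 counts).

The Splat model is not reproduced exactly (no mean-variance BCV trend, no
dropout layer); only the structure the downstream disentanglement task
depends on is planted.  Hyperparameters that Splat leaves implicit are
fixed, documented constants below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GroupRecord, GroupedExpressionBundle, assemble_bundle

# Fixed shape constants of the generator (documented design choices):
GAMMA_SHAPE = 0.6   # per-gene base-mean Gamma shape
GAMMA_RATE = 0.3    # per-gene base-mean Gamma rate
DE_SIGMA = 0.4      # log-normal sigma of all DE factors
DE_FRACTION = 0.1   # fraction of shared genes that are DE per cell type
LIB_SIGMA = 0.2     # log-normal sigma of the expected library size


@dataclass
class SimulationConfig:
    n_cells_per_group: int = 2500
    n_shared_genes: int = 2000
    n_program_genes: int = 500
    n_cell_types: int = 5
    n_programs_per_group: int = 2
    de_scale_shared: float = 0.1
    de_scale_program: float = 0.85
    lib_loc: float = 6.0           # program-block expected log library size
    lib_loc_shared: float = 11.0   # cell-type-block expected log library size
    seed: int = 0
    n_groups: int = 2

    def validate(self) -> None:
        for name in (
            "n_cells_per_group",
            "n_shared_genes",
            "n_program_genes",
            "n_cell_types",
            "n_programs_per_group",
            "n_groups",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.de_scale_shared < 0 or self.de_scale_program < 0:
            raise ValueError("DE scales must be nonnegative")


@dataclass
class SimulationTruth:
    """Planted assignments, in bundle order (group 0 cells, then group 1, ...)."""

    cell_type: np.ndarray   # shared vocabulary across groups
    program: np.ndarray     # group-specific vocabulary
    group: np.ndarray       # owning group of each cell
    # generator metadata: per program, the gene indices it boosts
    program_de_genes: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        per_group_programs = {
            g: set(self.program[self.group == g]) for g in np.unique(self.group)
        }
        groups = sorted(per_group_programs)
        for a in groups:
            for b in groups:
                if a != b and per_group_programs[a] & per_group_programs[b]:
                    raise ValueError("programs must be disjoint across groups")


def _de_factors(
    rng: np.random.Generator, n_genes: int, scale: float, fraction: float
) -> np.ndarray:
    """Multiplicative DE factor vector.

    ``scale`` is the log-normal location; ``scale == 0`` disables DE
    entirely (factor 1 for every gene) so that a zero-effect simulation is
    exactly exchangeable between groups.
    """
    factors = np.ones(n_genes)
    if scale > 0:
        n_de = max(1, int(round(fraction * n_genes)))
        de_genes = rng.choice(n_genes, size=n_de, replace=False)
        factors[de_genes] = rng.lognormal(mean=scale, sigma=DE_SIGMA, size=n_de)
    return factors


def simulate_grouped_counts(
    config: SimulationConfig,
) -> tuple[GroupedExpressionBundle, SimulationTruth]:
    """Generate the grouped simulation; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_shared_genes + config.n_program_genes
    gene_names = [f"gene_{i:05d}" for i in range(n_genes)]
    shared_slice = slice(0, config.n_shared_genes)

    # per-gene base expression, common to all groups
    base_mean = rng.gamma(shape=GAMMA_SHAPE, scale=1.0 / GAMMA_RATE, size=n_genes)
    base_mean = np.maximum(base_mean, 1e-8)

    # cell-type DE factors over the shared genes, identical across groups
    type_factors = np.ones((config.n_cell_types, n_genes))
    for t in range(config.n_cell_types):
        type_factors[t, shared_slice] = _de_factors(
            rng, config.n_shared_genes, config.de_scale_shared, DE_FRACTION
        )

    # one program block common to all programs; each program boosts its own
    # random ~10% subset of the block's genes (Splat-style DE probability)
    program_factors: dict[str, np.ndarray] = {}
    program_de_genes: dict[str, np.ndarray] = {}
    program_names_per_group: list[list[str]] = []
    for g in range(config.n_groups):
        names = []
        for p in range(config.n_programs_per_group):
            name = f"group{g}_prog{p}"
            factors = np.ones(n_genes)
            block = _de_factors(
                rng, config.n_program_genes, config.de_scale_program, DE_FRACTION
            )
            factors[config.n_shared_genes :] = block
            program_factors[name] = factors
            program_de_genes[name] = (
                np.flatnonzero(block != 1.0) + config.n_shared_genes
            )
            names.append(name)
        program_names_per_group.append(names)

    records: list[GroupRecord] = []
    all_types: list[np.ndarray] = []
    all_programs: list[np.ndarray] = []
    all_groups: list[np.ndarray] = []
    for g in range(config.n_groups):
        n = config.n_cells_per_group
        types = rng.integers(config.n_cell_types, size=n)
        progs = rng.integers(config.n_programs_per_group, size=n)
        prog_names = np.array(
            [program_names_per_group[g][p] for p in progs], dtype=object
        )
        lib_shared = rng.lognormal(config.lib_loc_shared, LIB_SIGMA, size=n)
        lib_program = rng.lognormal(config.lib_loc, LIB_SIGMA, size=n)

        prog_factor_matrix = np.stack(
            [program_factors[name] for name in program_names_per_group[g]]
        )
        mean = base_mean[None, :] * type_factors[types] * prog_factor_matrix[progs]
        n_sh = config.n_shared_genes
        rate = np.empty_like(mean)
        rate[:, :n_sh] = mean[:, :n_sh] / mean[:, :n_sh].sum(axis=1, keepdims=True)
        rate[:, :n_sh] *= lib_shared[:, None]
        rate[:, n_sh:] = mean[:, n_sh:] / mean[:, n_sh:].sum(axis=1, keepdims=True)
        rate[:, n_sh:] *= lib_program[:, None]
        counts = rng.poisson(rate)

        type_labels = np.array([f"type{t}" for t in types], dtype=object)
        records.append(
            GroupRecord(
                counts=counts,
                gene_names=gene_names,
                cell_names=[f"group{g}_cell_{i:05d}" for i in range(n)],
                labels=type_labels,
                name=f"group{g}",
            )
        )
        all_types.append(type_labels)
        all_programs.append(prog_names)
        all_groups.append(np.full(n, f"group{g}", dtype=object))

    truth = SimulationTruth(
        cell_type=np.concatenate(all_types),
        program=np.concatenate(all_programs),
        group=np.concatenate(all_groups),
        program_de_genes=program_de_genes,
    )
    bundle = assemble_bundle(records, supervised=True)
    return bundle, truth


def truth_tables(truth: SimulationTruth) -> list[pd.DataFrame]:
    """Per-group tables of planted labels, aligned to bundle cell order."""
    tables = []
    for g in pd.unique(truth.group):
        mask = truth.group == g
        tables.append(
            pd.DataFrame(
                {
                    "cell_type": truth.cell_type[mask],
                    "program": truth.program[mask],
                    "group": truth.group[mask],
                }
            ).reset_index(drop=True)
        )
    return tables
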