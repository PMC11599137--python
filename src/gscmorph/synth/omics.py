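"""Synthetic expression / CRISPR-dependency tables with planted structure.

The expression table emulates log2(TPM+1) values whose per-gene means are
drawn from a two-component Gaussian mixture (the bimodal basal-expression
structure the gating step exploits).  The dependency table emulates
depletion fold changes from a pooled CRISPR screen: background genes sit
near zero, an essential anchor set is planted at a strongly negative median,
a non-essential anchor set at a planted (typically zero) median, a few
highly expressed genes are marked core-fitness with uniform strong
depletion, and one designated gene gets an extreme depletion in a single
cell line (a context-specific dependency for the prioritization stage to
recover).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gscmorph.errors import ValidationError

__all__ = ["OmicsSimSpec", "OmicsTables", "OmicsTruth", "generate_omics_tables"]


@dataclass
class OmicsSimSpec:
    """Parameters of the omics simulation (log2(TPM+1) scale for expression)."""

    n_genes: int = 500
    n_lines: int = 48
    low_component: tuple[float, float] = (1.0, 0.5)  # (mean, sd)
    high_component: tuple[float, float] = (5.0, 1.0)
    high_fraction: float = 0.6
    expr_line_sd: float = 0.3
    essential_anchor_fc: float = -0.8
    nonessential_anchor_fc: float = 0.0
    n_anchor_genes: int = 30
    anchor_noise_sd: float = 0.05
    dep_background_sd: float = 0.1
    n_core_fitness: int = 3
    planted_dependent_gene: str = "GENE0001"
    planted_line_index: int = 0
    planted_depletion_scale: float = 1.5  # x essential anchor median
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValidationError("n_lines must be >= 2")
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if not (self.low_component[1] > 0 and self.high_component[1] > 0):
            raise ValidationError("component sds must be > 0")
        if not 0.0 < self.high_fraction <= 1.0:
            raise ValidationError("high_fraction must be in (0, 1]")
        if not 0 <= self.planted_line_index < self.n_lines:
            raise ValidationError("planted_line_index out of range")


@dataclass
class OmicsTruth:
    """Planted assignments, the oracle for recovery tests."""

    high_genes: set[str]
    gene_means: pd.Series
    planted_gene: str
    planted_line: str
    essential_anchors: set[str]
    nonessential_anchors: set[str]
    core_fitness: set[str]


@dataclass
class OmicsTables:
    expression: pd.DataFrame  # genes x lines, log2(TPM+1)
    dependency: pd.DataFrame  # genes x lines, depletion fold change
    core_fitness: set[str] = field(default_factory=set)
    truth: OmicsTruth | None = None


def generate_omics_tables(spec: OmicsSimSpec) -> OmicsTables:
    """Generate expression and dependency tables plus the core-fitness set.

    The dependency table holds the expression genes and both anchor sets.
    With ``anchor_noise_sd = 0`` the anchor-set medians equal the planted
    fold changes exactly; the planted dependent gene always carries the
    minimum depletion value of its designated line.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i:04d}" for i in range(1, spec.n_genes + 1)]
    lines = [f"LINE{j:02d}" for j in range(1, spec.n_lines + 1)]

    is_high = rng.random(spec.n_genes) < spec.high_fraction
    means = np.where(
        is_high,
        rng.normal(*spec.high_component, size=spec.n_genes),
        rng.normal(*spec.low_component, size=spec.n_genes),
    )
    expr = means[:, None] + rng.normal(0.0, spec.expr_line_sd, size=(spec.n_genes, spec.n_lines))
    expression = pd.DataFrame(np.clip(expr, 0.0, None), index=genes, columns=lines)

    # force the planted gene into the high component so it survives the gate
    planted = spec.planted_dependent_gene
    if planted not in genes:
        raise ValidationError(f"planted_dependent_gene {planted!r} not among generated genes")
    p_idx = genes.index(planted)
    if not is_high[p_idx]:
        is_high[p_idx] = True
        means[p_idx] = spec.high_component[0]
        row = means[p_idx] + rng.normal(0.0, spec.expr_line_sd, size=spec.n_lines)
        expression.iloc[p_idx] = np.clip(row, 0.0, None)

    ess = [f"ESSA{i:03d}" for i in range(1, spec.n_anchor_genes + 1)]
    non = [f"NONA{i:03d}" for i in range(1, spec.n_anchor_genes + 1)]
    dep_rows = {}
    for g in genes:
        dep_rows[g] = rng.normal(0.0, spec.dep_background_sd, size=spec.n_lines)
    for g in ess:
        dep_rows[g] = spec.essential_anchor_fc + rng.normal(
            0.0, spec.anchor_noise_sd, size=spec.n_lines
        )
    for g in non:
        dep_rows[g] = spec.nonessential_anchor_fc + rng.normal(
            0.0, spec.anchor_noise_sd, size=spec.n_lines
        )
    dependency = pd.DataFrame(dep_rows, index=lines).T
    dependency = dependency.loc[genes + ess + non]

    # core-fitness genes: highly expressed, uniformly depleted across lines
    high_gene_names = [g for g, h in zip(genes, is_high) if h and g != planted]
    core = set()
    if spec.n_core_fitness > 0 and high_gene_names:
        chosen = rng.choice(
            high_gene_names, size=min(spec.n_core_fitness, len(high_gene_names)), replace=False
        )
        core = set(str(g) for g in chosen)
        for g in core:
            dependency.loc[g] = spec.essential_anchor_fc + rng.normal(
                0.0, spec.anchor_noise_sd, size=spec.n_lines
            )

    planted_line = lines[spec.planted_line_index]
    extreme = spec.planted_depletion_scale * spec.essential_anchor_fc
    line_min = float(dependency[planted_line].min())
    dependency.loc[planted, planted_line] = min(extreme, line_min - 0.1)

    truth = OmicsTruth(
        high_genes={g for g, h in zip(genes, is_high) if h},
        gene_means=pd.Series(means, index=genes),
        planted_gene=planted,
        planted_line=planted_line,
        essential_anchors=set(ess),
        nonessential_anchors=set(non),
        core_fitness=set(core),
    )
    return OmicsTables(
        expression=expression, dependency=dependency, core_fitness=set(core), truth=truth
    )
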