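"""Data-driven gene prioritization for context-specific dependencies.

The procedure that singled out ADD3 in glioblastoma: intersect a
differential-expression list with a curated morphoregulator list, test the
over-representation of a gene family with an upper-tail hypergeometric
(one-sided Fisher) test, gate genes on basal expression with a two-component
Gaussian mixture (the bimodal log2(TPM+1) structure of cell-line panels),
exclude pan-cancer core-fitness genes, rescale CRISPR depletion fold
changes so that the median of essential anchors maps to -1 and of
non-essential anchors to 0, and rank the survivors by their strongest
(most negative) scaled depletion across cell lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from gscmorph.errors import ValidationError

__all__ = [
    "EnrichmentResult",
    "IntersectionResult",
    "MixtureFit",
    "ScaledDependency",
    "SignatureCorrelation",
    "fit_bimodal_gate",
    "hypergeom_upper_tail",
    "intersect_gene_sets",
    "normalize_symbols",
    "prioritize",
    "scale_dependency",
    "signature_correlation_test",
]


def normalize_symbols(symbols: Iterable[str]) -> set[str]:
    """Upper-case and strip gene symbols; duplicates collapse."""
    return {str(s).strip().upper() for s in symbols if str(s).strip()}


@dataclass
class IntersectionResult:
    shared: set[str]
    coverage_a: float  # |shared| / |a|
    coverage_b: float


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric test of family over-representation."""

    N: int
    n: int
    k: int
    x: int
    p_value: float


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fit of per-gene mean expression."""

    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    weight_high: float
    posteriors_high: pd.Series
    gated_high: set[str]
    converged: bool
    seed: int


@dataclass
class ScaledDependency:
    """Depletion fold changes rescaled to the [-1, 0] anchor convention."""

    m_ess: pd.Series  # per-line median of essential anchors
    m_non: pd.Series
    scaled: pd.DataFrame


@dataclass
class SignatureCorrelation:
    """Focal-gene correlations of a DE signature against the all-pairs null."""

    set_correlations: pd.Series
    mean_correlation: float
    t_statistic: float
    p_value: float
    null_mean: float
    null_size: int
    excluded: list[str] = field(default_factory=list)


def intersect_gene_sets(a: Iterable[str], b: Iterable[str]) -> IntersectionResult:
    """Exact intersection of two normalized gene sets, with per-input coverage."""
    sa, sb = normalize_symbols(a), normalize_symbols(b)
    shared = sa & sb
    return IntersectionResult(
        shared=shared,
        coverage_a=len(shared) / len(sa) if sa else 0.0,
        coverage_b=len(shared) / len(sb) if sb else 0.0,
    )


def hypergeom_upper_tail(N: int, n: int, k: int, x: int) -> EnrichmentResult:
    """P(X >= x) for X ~ Hypergeometric(N, n, k).

    Equivalent to the one-sided Fisher exact enrichment p-value: the
    probability of drawing at least ``x`` of the ``n`` population successes
    in a sample of ``k`` from ``N``.
    """
    if not (0 <= n <= N and 0 <= k <= N):
        raise ValidationError("need 0 <= n <= N and 0 <= k <= N")
    if not 0 <= x <= min(n, k):
        raise ValidationError("need 0 <= x <= min(n, k)")
    if x == 0:
        p = 1.0
    else:
        # sf is computed from logpmf internally; exact enough down to ~1e-300
        p = float(stats.hypergeom.sf(x - 1, N, n, k))
    return EnrichmentResult(N=N, n=n, k=k, x=x, p_value=p)


def fit_bimodal_gate(
    mean_expression: pd.Series,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    manual_threshold: float | None = None,
) -> MixtureFit:
    """Gate genes as "highly expressed" via a two-component Gaussian mixture.

    EM with seeded k-means++ initialization, best of ``n_init`` restarts by
    likelihood; a gene is gated high when its posterior for the
    higher-mean component exceeds 0.5.  ``manual_threshold`` bypasses the
    mixture and gates on a fixed expression cutoff instead (for users who
    prefer a visual threshold).  All-identical values raise, as no gate is
    identifiable.
    """
    values = pd.Series(mean_expression).astype(float)
    if len(values) < 10:
        raise ValidationError("need at least 10 genes to fit a mixture")
    if not np.all(np.isfinite(values)):
        raise ValidationError("mean expression contains non-finite values")
    if float(values.max() - values.min()) == 0.0:
        raise ValidationError(
            "all expression values identical: distribution is degenerate, no gate"
        )
    if manual_threshold is not None:
        post = (values > manual_threshold).astype(float)
        gated = set(values.index[values > manual_threshold])
        low = values[values <= manual_threshold]
        high = values[values > manual_threshold]
        return MixtureFit(
            mean_low=float(low.mean()) if len(low) else float("nan"),
            mean_high=float(high.mean()) if len(high) else float("nan"),
            sd_low=float(low.std(ddof=0)) if len(low) else float("nan"),
            sd_high=float(high.std(ddof=0)) if len(high) else float("nan"),
            weight_high=len(high) / len(values),
            posteriors_high=pd.Series(post, index=values.index),
            gated_high=gated,
            converged=True,
            seed=seed,
        )

    x = values.to_numpy()[:, None]
    gmm = GaussianMixture(
        n_components=2,
        n_init=n_init,
        init_params="k-means++",
        max_iter=max_iter,
        random_state=seed,
        reg_covar=1e-9,
    ).fit(x)
    order = np.argsort(gmm.means_.ravel())
    lo, hi = order[0], order[1]
    post_high = gmm.predict_proba(x)[:, hi]
    posteriors = pd.Series(post_high, index=values.index)
    gated = set(values.index[post_high > 0.5])
    return MixtureFit(
        mean_low=float(gmm.means_.ravel()[lo]),
        mean_high=float(gmm.means_.ravel()[hi]),
        sd_low=float(np.sqrt(gmm.covariances_.ravel()[lo])),
        sd_high=float(np.sqrt(gmm.covariances_.ravel()[hi])),
        weight_high=float(gmm.weights_[hi]),
        posteriors_high=posteriors,
        gated_high=gated,
        converged=bool(gmm.converged_),
        seed=seed,
    )


def scale_dependency(
    dependency: pd.DataFrame,
    essential_anchors: Iterable[str],
    nonessential_anchors: Iterable[str],
) -> ScaledDependency:
    """Affinely rescale depletion fold changes per cell line.

    For each line, ``s(x) = (x - m_non) / (m_non - m_ess)`` where ``m_ess``
    and ``m_non`` are the medians of the essential and non-essential anchor
    sets: the non-essential median maps to 0 and the essential median to -1,
    the conventional scale on which -1 means "as depleted as core-fitness
    genes".
    """
    ess = normalize_symbols(essential_anchors)
    non = normalize_symbols(nonessential_anchors)
    if not ess or not non:
        raise ValidationError("both anchor sets must be non-empty")
    index_upper = {str(g).strip().upper() for g in dependency.index}
    for name, anchors in (("essential", ess), ("non-essential", non)):
        missing = anchors - index_upper
        if missing:
            raise ValidationError(
                f"{name} anchors absent from dependency matrix: {sorted(missing)[:5]}"
            )
    upper_index = pd.Index([str(g).strip().upper() for g in dependency.index])
    dep = dependency.set_axis(upper_index, axis=0)
    m_ess = dep.loc[sorted(ess)].median(axis=0)
    m_non = dep.loc[sorted(non)].median(axis=0)
    denom = m_non - m_ess
    bad = denom[denom == 0]
    if len(bad):
        raise ValidationError(
            f"anchor medians coincide in line(s): {list(bad.index)}"
        )
    scaled = dep.sub(m_non, axis=1).div(denom, axis=1)
    return ScaledDependency(m_ess=m_ess, m_non=m_non, scaled=scaled)


def prioritize(
    shared: Iterable[str],
    expression: pd.DataFrame,
    dependency: pd.DataFrame,
    core_fitness: Iterable[str],
    essential_anchors: Iterable[str],
    nonessential_anchors: Iterable[str],
    seed: int = 0,
    manual_threshold: float | None = None,
) -> dict:
    """Rank candidate genes by strongest context-specific dependency.

    Pipeline: mean expression across lines -> bimodal gate -> core-fitness
    exclusion -> anchor-scaled dependency -> rank by minimum scaled
    depletion (most negative first).  The report carries, per gene, the
    arg-min cell line and a context-specificity score
    ``median(scaled) - min(scaled)`` (large when the dependency is driven by
    few lines).  Genes missing from the expression table are reported, not
    fatal.
    """
    shared_set = normalize_symbols(shared)
    expr = expression.set_axis(
        pd.Index([str(g).strip().upper() for g in expression.index]), axis=0
    )
    present = sorted(shared_set & set(expr.index))
    missing = sorted(shared_set - set(expr.index))
    if not present:
        raise ValidationError("none of the shared genes are in the expression matrix")

    mean_expr = expr.loc[present].mean(axis=1)
    fit = fit_bimodal_gate(mean_expr, seed=seed, manual_threshold=manual_threshold)
    core = normalize_symbols(core_fitness)
    survivors = sorted(fit.gated_high - core)
    result = {
        "mixture_fit": fit,
        "missing_genes": missing,
        "gated_high": sorted(fit.gated_high),
        "core_excluded": sorted(fit.gated_high & core),
        "report": pd.DataFrame(
            columns=[
                "gene",
                "mean_expr",
                "min_scaled_dep",
                "argmin_line",
                "context_score",
            ]
        ),
    }
    if not survivors:
        return result

    scaling = scale_dependency(dependency, essential_anchors, nonessential_anchors)
    in_dep = [g for g in survivors if g in scaling.scaled.index]
    absent = sorted(set(survivors) - set(in_dep))
    if absent:
        warnings.warn(
            f"{len(absent)} gated genes absent from dependency matrix", stacklevel=2
        )
    if not in_dep:
        return result
    sub = scaling.scaled.loc[in_dep]
    report = pd.DataFrame(
        {
            "gene": in_dep,
            "mean_expr": mean_expr.loc[in_dep].to_numpy(),
            "min_scaled_dep": sub.min(axis=1).to_numpy(),
            "argmin_line": sub.idxmin(axis=1).to_numpy(),
            "context_score": (sub.median(axis=1) - sub.min(axis=1)).to_numpy(),
        }
    ).sort_values("min_scaled_dep", kind="stable", ignore_index=True)
    result["report"] = report
    result["scaling"] = scaling
    return result


def signature_correlation_test(
    expression: pd.DataFrame,
    focal_gene: str,
    gene_set: Iterable[str],
) -> SignatureCorrelation:
    """Test whether a gene set co-varies with a focal gene beyond the null.

    Expression profiles are standardized per gene (zero mean, unit variance
    across lines); the null is the upper triangle of the all-pairs Pearson
    correlation matrix, and the focal-vs-set correlations are compared to
    it with a two-sample t-test (Welch).  Constant-expression genes are
    excluded with a warning; call once per signature direction
    (up-regulated / down-regulated sets).
    """
    focal = str(focal_gene).strip().upper()
    members = normalize_symbols(gene_set) - {focal}
    expr = expression.set_axis(
        pd.Index([str(g).strip().upper() for g in expression.index]), axis=0
    )
    if focal not in expr.index:
        raise ValidationError(f"focal gene {focal!r} not in expression matrix")
    values = expr.to_numpy(dtype=float)
    sds = values.std(axis=1)
    constant = [g for g, sd in zip(expr.index, sds) if sd == 0.0]
    if constant:
        warnings.warn(
            f"excluded {len(constant)} constant-expression genes", stacklevel=2
        )
        expr = expr.drop(index=constant)
        if focal not in expr.index:
            raise ValidationError("focal gene has constant expression")
    members &= set(expr.index)
    if not members:
        raise ValidationError("gene set has no usable members in the matrix")

    z = stats.zscore(expr.to_numpy(dtype=float), axis=1)
    corr = np.corrcoef(z)
    iu = np.triu_indices_from(corr, k=1)
    null = corr[iu]
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    fi = gene_pos[focal]
    set_corr = pd.Series(
        {g: float(corr[fi, gene_pos[g]]) for g in sorted(members)}
    )
    t_stat, p = stats.ttest_ind(set_corr.to_numpy(), null, equal_var=False)
    return SignatureCorrelation(
        set_correlations=set_corr,
        mean_correlation=float(set_corr.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        null_mean=float(null.mean()),
        null_size=int(null.size),
        excluded=constant,
    )
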