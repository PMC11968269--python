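"""Distance-bias analysis: fold change versus promoter-enhancer distance.

Each gene cluster is regulated by its own enhancer element set (alpha by
HS5-1, beta by HS18-22, gamma by HS5-1bL).  Pairing each gene's fold change
with the linear distance from its 5'-UTR anchor to the assigned element set
turns the extrusion model into a straight line on the log2 scale, whose
slope can be inverted into a processivity change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import LocusAnnotation

__all__ = [
    "CLUSTER_ENHANCERS",
    "assign_enhancer",
    "element_reference_point",
    "promoter_enhancer_distance",
    "make_pairs",
    "fit_distance_trend",
    "recover_processivity_delta",
    "cluster_contrast",
    "DistanceTrendFit",
    "ProcessivityDelta",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

CLUSTER_ENHANCERS: dict[str, tuple[str, ...]] = {
    "alpha": ("HS5-1",),
    "beta": ("HS18-20", "HS21", "HS22"),
    "gamma": ("HS5-1bL",),
}


def assign_enhancer(cluster: str) -> tuple[str, ...]:
    """Enhancer element set regulating a cluster; background genes have none."""
    if cluster == "background":
        return ()
    try:
        return CLUSTER_ENHANCERS[cluster]
    except KeyError:
        raise KeyError(f"unknown cluster {cluster!r}") from None


def element_reference_point(
    annotation: LocusAnnotation, elements: tuple[str, ...], mode: str = "midpoint"
) -> float:
    """Reference coordinate of an element set.

    ``midpoint`` (default): midpoint of the spanning interval of the set.
    ``nearest-edge``: the closest element boundary is resolved per gene by
    :func:`promoter_enhancer_distance`, so here returns the spanning interval.
    """
    if not elements:
        raise ValueError("empty element set")
    ivs = [annotation.enhancer_interval(e) for e in elements]
    lo = min(s for s, _ in ivs)
    hi = max(e for _, e in ivs)
    if mode == "midpoint":
        return (lo + hi) / 2.0
    raise ValueError(f"unknown reference mode {mode!r}")


def promoter_enhancer_distance(
    anchor: float,
    annotation: LocusAnnotation,
    elements: tuple[str, ...],
    mode: str = "midpoint",
) -> float:
    """Linear distance (bp) from a gene anchor to its enhancer element set."""
    if anchor is None or (isinstance(anchor, float) and math.isnan(anchor)):
        raise ValueError("gene anchor is missing")
    if mode == "nearest-edge":
        ivs = [annotation.enhancer_interval(e) for e in elements]
        lo = min(s for s, _ in ivs)
        hi = max(e for _, e in ivs)
        if lo <= anchor < hi:
            return 0.0
        return float(min(abs(anchor - lo), abs(anchor - hi)))
    ref = element_reference_point(annotation, elements, mode=mode)
    return float(abs(anchor - ref))


def make_pairs(
    fc: pd.DataFrame,
    annotation: LocusAnnotation,
    modality: str = "RNA",
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Join fold changes with promoter-enhancer distances by gene name.

    ``fc`` must carry ``gene_id`` and ``log2fc`` columns.  Background genes
    are excluded; cluster genes missing from ``fc`` are dropped with a
    warning.  Duplicate gene ids are an error.
    """
    if fc["gene_id"].duplicated().any():
        dups = fc.loc[fc["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in fold-change table: {dups[:5]}")
    genes = annotation.cluster_genes
    rows = []
    fc_idx = fc.set_index("gene_id")
    for _, g in genes.iterrows():
        gid = g["gene_id"]
        if gid not in fc_idx.index:
            logger.warning("gene %s missing from fold-change table; dropped", gid)
            continue
        elements = assign_enhancer(g["cluster"])
        d = promoter_enhancer_distance(g["anchor"], annotation, elements, mode=mode)
        rows.append(
            {
                "gene_id": gid,
                "cluster": g["cluster"],
                "distance": d,
                "log2fc": float(fc_idx.loc[gid, "log2fc"]),
                "modality": modality,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "distance", "log2fc", "modality"])


@dataclass(frozen=True)
class DistanceTrendFit:
    """OLS fit of log2FC on distance."""

    slope: float  # per bp
    intercept: float
    slope_se: float
    ci_low: float
    ci_high: float
    n: int
    modality: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


def fit_distance_trend(pairs: pd.DataFrame, modality: str | None = None) -> DistanceTrendFit:
    """Ordinary least squares of log2 fold change on genomic distance."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 points to fit a distance trend")
    x = sm.add_constant(pairs["distance"].to_numpy(dtype=float))
    y = pairs["log2fc"].to_numpy(dtype=float)
    res = sm.OLS(y, x).fit()
    ci = res.conf_int(alpha=0.05)
    slope = float(res.params[1])
    return DistanceTrendFit(
        slope=slope,
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        ci_low=min(float(ci[1][0]), slope),
        ci_high=max(float(ci[1][1]), slope),
        n=len(pairs),
        modality=modality or (pairs["modality"].iloc[0] if "modality" in pairs else ""),
    )


@dataclass(frozen=True)
class ProcessivityDelta:
    """Change in inverse processivity implied by a distance-trend slope.

    Positive ``delta_inv_lambda`` means reduced processivity in the mutant.
    """

    delta_inv_lambda: float  # per bp
    lambda_mut: float | None  # bp, given the assumed lambda_wt
    lambda_wt: float
    consistent: bool


def recover_processivity_delta(
    fit: DistanceTrendFit, eta: float = 1.0, lambda_wt: float = 400_000.0
) -> ProcessivityDelta:
    """Invert a fitted slope into a processivity change.

    ``delta(1/lambda) = -slope * ln2 / eta``; the implied mutant
    processivity is ``1 / (1/lambda_wt + delta)``, flagged inconsistent if
    non-positive.
    """
    if eta == 0:
        raise ValueError("expression coupling eta must be non-zero to invert the trend")
    delta = -fit.slope * LN2 / eta
    inv_mut = 1.0 / lambda_wt + delta
    if inv_mut <= 0:
        return ProcessivityDelta(delta, None, lambda_wt, consistent=False)
    return ProcessivityDelta(delta, 1.0 / inv_mut, lambda_wt, consistent=True)


def cluster_contrast(
    fc: pd.DataFrame,
    annotation: LocusAnnotation,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster mean/median log2FC with bootstrap confidence intervals.

    Returns one row per cluster (alpha, beta, gamma) with columns
    n, mean_log2fc, median_log2fc, ci_low, ci_high (95% bootstrap of the
    mean).  Empty clusters are flagged with NaN summaries.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    fc_idx = fc.set_index("gene_id")
    rows = []
    for cluster in ("alpha", "beta", "gamma"):
        ids = annotation.cluster_genes.loc[
            annotation.cluster_genes["cluster"] == cluster, "gene_id"
        ]
        vals = fc_idx.reindex(ids)["log2fc"].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            rows.append(
                {"cluster": cluster, "n": 0, "mean_log2fc": np.nan,
                 "median_log2fc": np.nan, "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        boots = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "cluster": cluster,
                "n": len(vals),
                "mean_log2fc": float(vals.mean()),
                "median_log2fc": float(np.median(vals)),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
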