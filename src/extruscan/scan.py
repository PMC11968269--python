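"""Genome-binned Poisson enrichment scan (the Manhattan statistic).

The genome is partitioned into fixed-width bins (1 Mb by default, with an
optional sliding step), downregulated-gene anchors are counted per bin, a
single Poisson rate is fit by maximum likelihood (the mean count per bin),
and each bin is scored by its upper-tail probability P(X >= k) and fold
enrichment k/lambda.  Tail probabilities are computed in log space and stay
finite far below the double-precision underflow threshold.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.special
from statsmodels.stats.multitest import multipletests

from .core import GenomeSpec

__all__ = [
    "bin_genome",
    "count_hits",
    "poisson_scan",
    "poisson_tail_logp",
    "manhattan_table",
]


def bin_genome(genome: GenomeSpec, width: int = 1_000_000, step: int | None = None) -> pd.DataFrame:
    """Tile each chromosome with half-open bins of ``width`` bp.

    ``step`` defaults to ``width`` (non-overlapping); a smaller step yields
    sliding windows.  The last bin of a chromosome may be short.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    step = width if step is None else step
    if step <= 0:
        raise ValueError("bin step must be positive")
    rows = []
    for chrom, length in genome.chromosomes.items():
        start = 0
        while start < length:
            rows.append({"chrom": chrom, "start": start, "end": min(start + width, length)})
            start += step
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["width"] = width
    bins["step"] = step
    return bins


def count_hits(bins: pd.DataFrame, hits: pd.DataFrame, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Count hit anchors per bin (half-open: a boundary anchor belongs to the
    bin starting there).

    ``hits`` needs chrom and pos columns.  In non-overlapping mode each hit
    lands in exactly one bin and the counts sum to the number of hits; in
    sliding mode a hit is counted in every window covering it.  Anchors
    outside the genome are an error.
    """
    bins = bins.copy()
    bins["k"] = 0
    if len(hits) == 0:
        return bins
    if genome is not None:
        for _, h in hits.iterrows():
            if h["chrom"] not in genome.chromosomes:
                raise ValueError(f"hit on unknown chromosome {h['chrom']!r}")
            if not (0 <= h["pos"] < genome.length(h["chrom"])):
                raise ValueError(f"hit anchor {h['pos']} outside chromosome {h['chrom']}")
    counts = np.zeros(len(bins), dtype=int)
    for chrom, sub in hits.groupby("chrom"):
        sel = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
        if len(sel) == 0:
            raise ValueError(f"hit on chromosome {chrom!r} absent from the bin table")
        starts = bins["start"].to_numpy()[sel]
        ends = bins["end"].to_numpy()[sel]
        pos = sub["pos"].to_numpy()
        inside = (pos[:, None] >= starts[None, :]) & (pos[:, None] < ends[None, :])
        counts[sel] += inside.sum(axis=0)
    bins["k"] = counts
    return bins


def poisson_tail_logp(k: int, lam: float) -> float:
    """Natural-log upper-tail probability ln P(X >= k) for X ~ Poisson(lam).

    Computed from the log pmf series with an explicit geometric tail bound,
    so values far below the smallest positive double (p ~ 1e-3000) remain
    finite in log space.  P(X >= 0) = 1 by convention.
    """
    if lam < 0:
        raise ValueError("Poisson rate must be non-negative")
    k = int(k)
    if k <= 0:
        return 0.0
    if lam == 0:
        return -math.inf
    # log pmf terms from x = k upward; the term ratio lam/(x+1) < 1 once
    # x >= lam, so the remainder is bounded by a geometric series.
    x = max(k, int(math.ceil(lam)))
    # sum exactly from k to x first (few terms when lam > k)
    terms = []
    for xi in range(k, x + 1):
        terms.append(-lam + xi * math.log(lam) - math.lgamma(xi + 1))
    while True:
        x += 1
        t = -lam + x * math.log(lam) - math.lgamma(x + 1)
        terms.append(t)
        r = lam / (x + 1)
        # stop when the geometric remainder bound is negligible vs the head
        if r < 0.5 and t + math.log(r / (1 - r)) < max(terms) - 40:
            break
    return float(scipy.special.logsumexp(terms))


def poisson_scan(
    bins: pd.DataFrame,
    gene_bearing_only: bool = False,
    gene_intervals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score each bin against a genome-wide Poisson null.

    ``lambda`` is the maximum-likelihood rate: total hits divided by the
    number of bins (optionally restricted to bins overlapping at least one
    annotated transcript, via ``gene_bearing_only`` with ``gene_intervals``
    carrying chrom/start/end).  Adds lambda, fold ``k/lambda``, the
    upper-tail p-value, ``minus_log10_p`` and a convenience BH column
    (not used for ranking).
    """
    if len(bins) == 0:
        raise ValueError("empty bin table")
    out = bins.copy()
    denom_mask = np.ones(len(out), dtype=bool)
    if gene_bearing_only:
        if gene_intervals is None:
            raise ValueError("gene_bearing_only requires gene_intervals")
        denom_mask[:] = False
        for chrom, sub in gene_intervals.groupby("chrom"):
            sel = np.flatnonzero((out["chrom"] == chrom).to_numpy())
            if len(sel) == 0:
                continue
            bs = out["start"].to_numpy()[sel]
            be = out["end"].to_numpy()[sel]
            gs = sub["start"].to_numpy()
            ge = sub["end"].to_numpy()
            overlap = (gs[:, None] < be[None, :]) & (ge[:, None] > bs[None, :])
            denom_mask[sel] |= overlap.any(axis=0)
        if not denom_mask.any():
            raise ValueError("no gene-bearing bins found")
    n_bins = int(denom_mask.sum())
    lam = float(out["k"].sum()) / n_bins
    out["lam"] = lam
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold"] = np.where(lam > 0, out["k"] / lam, np.nan)
    logp = np.array([poisson_tail_logp(k, lam) for k in out["k"]])
    out["p"] = np.exp(logp)  # underflows to 0 below ~1e-308; use minus_log10_p
    out["minus_log10_p"] = -logp / math.log(10)
    out["in_denominator"] = denom_mask
    out["padj_bh"] = multipletests(np.minimum(np.exp(logp), 1.0), method="fdr_bh")[1]
    return out


def manhattan_table(results: pd.DataFrame, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Plotting/ranking order for scan results.

    Sorted by genomic position with a cumulative plotting coordinate;
    ``rank`` orders bins by significance (ties broken by genomic position,
    stable).
    """
    if len(results) == 0:
        return results.assign(plot_pos=pd.Series(dtype=float), rank=pd.Series(dtype=int))
    out = results.copy()
    chrom_order = (
        list(genome.chromosomes) if genome is not None else list(pd.unique(out["chrom"]))
    )
    offsets = {}
    cum = 0
    for chrom in chrom_order:
        offsets[chrom] = cum
        sub = out[out["chrom"] == chrom]
        if len(sub):
            cum += int(sub["end"].max())
    out["plot_pos"] = out.apply(lambda r: offsets[r["chrom"]] + (r["start"] + r["end"]) / 2, axis=1)
    out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    order = out.sort_values(
        ["minus_log10_p", "chrom", "start"],
        ascending=[False, True, True],
        kind="stable",
    ).index
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out
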