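"""Synthetic multi-modal datasets from the extrusion-processivity model.

Every modality is driven by the same ground truth: a wild-type and a mutant
processivity (``lambda_wt``, ``lambda_mut``) and the per-gene promoter to
enhancer distances of the synthetic clustered-Pcdh-like locus.

* Expression: negative-binomial replicate counts whose mutant/WT mean ratio
  is the extrusion-delivered contact ratio raised to a coupling exponent.
* Cohesin (RAD21-like) ChIP: per-gene promoter peaks whose mutant intensity
  scales with the same contact ratio; enhancer peaks are attenuated only at
  elements carrying a CTCF site (the HS7 analog is processivity-blind).
* Contacts: Poisson-sampled symmetric matrices combining a distance
  power-law background, planted domain blocks, and exponential
  enhancer-anchored contacts; plus one-viewpoint 4C-style fragment tracks.

All outputs are bit-reproducible given a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import CTCF_SITE_ENHANCERS, ENHANCER_NAMES, LocusAnnotation
from .contacts import ContactMatrix
from .core import (
    ProcessivityParams,
    enhancer_contact,
    expected_expression_log2fc,
    extrusion_contact_ratio,
)
from .distance import assign_enhancer, element_reference_point

__all__ = [
    "CountMatrix",
    "simulate_expression",
    "simulate_contact_matrix",
    "simulate_tad_benchmark_matrix",
    "simulate_chip_and_4c",
    "default_planted_boundaries",
]


@dataclass
class CountMatrix:
    """Replicate count table for one assay.

    counts
        features x samples integer DataFrame (index = feature id).
    samples
        per-sample metadata: sample_id, condition (WT/mut), replicate.
    lengths
        feature lengths in bp (for FPKM).
    library_sizes
        mapped reads per sample (the FPKM denominator).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def condition_columns(self, condition: str) -> list[str]:
        sel = self.samples[self.samples["condition"] == condition]
        return list(sel["sample_id"])

    def write(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def gene_distances(annotation: LocusAnnotation) -> pd.Series:
    """Promoter-to-assigned-enhancer distance (bp) for every cluster gene."""
    genes = annotation.cluster_genes
    refs = {
        cluster: element_reference_point(annotation, assign_enhancer(cluster))
        for cluster in ("alpha", "beta", "gamma")
    }
    d = genes.apply(lambda g: abs(g["anchor"] - refs[g["cluster"]]), axis=1)
    return pd.Series(d.to_numpy(dtype=float), index=genes["gene_id"].to_numpy())


def simulate_expression(
    annotation: LocusAnnotation,
    params: ProcessivityParams,
    *,
    nb_dispersion: float = 0.05,
    depth: float = 20_000_000,
    replicates: int = 3,
    cluster_baseline_fpkm: float = 20.0,
    gene_fpkm_jitter_sd: float = 0.4,
    background_fpkm_median: float = 5.0,
    background_fpkm_log_sd: float = 1.0,
    background_de_fraction: float = 0.05,
    background_de_log2fc: float = 1.5,
    background_de_down_fraction: float = 0.6,
    seed: int = 1234,
) -> tuple[CountMatrix, dict]:
    """Simulate WT and mutant RNA-seq style counts with known fold changes.

    Cluster genes: mutant mean = WT mean times the extrusion contact ratio
    at the gene's enhancer distance raised to ``expression_coupling``, so
    the expected log2FC is ``-eta * d * (1/lambda_mut - 1/lambda_wt)/ln 2``.
    A fraction of background genes receives planted condition effects of
    fixed magnitude (down-biased, emulating a genome-wide DE excess); the
    rest are condition-independent.  Returns the counts and a ground-truth
    dict (distances, expected log2FC per gene, planted DEG ids).
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if nb_dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if replicates < 1:
        raise ValueError("need at least one replicate per condition")

    rng = np.random.default_rng(seed)
    genes = annotation.genes
    gene_ids = genes["gene_id"].to_numpy()
    lengths = pd.Series(genes["length"].to_numpy(dtype=float), index=gene_ids)
    is_cluster = (genes["cluster"] != "background").to_numpy()

    dists = gene_distances(annotation)
    fpkm_to_counts = lengths.to_numpy() * depth / 1e9

    base_fpkm = np.empty(len(genes))
    base_fpkm[is_cluster] = cluster_baseline_fpkm * np.exp(
        rng.normal(0.0, gene_fpkm_jitter_sd, size=int(is_cluster.sum()))
    )
    n_bg = int((~is_cluster).sum())
    base_fpkm[~is_cluster] = background_fpkm_median * np.exp(
        rng.normal(0.0, background_fpkm_log_sd, size=n_bg)
    )

    log2fc_true = np.zeros(len(genes))
    cluster_ids = gene_ids[is_cluster]
    log2fc_true[is_cluster] = expected_expression_log2fc(
        dists.loc[cluster_ids].to_numpy(), params
    )

    planted: list[str] = []
    if n_bg and background_de_fraction > 0:
        bg_idx = np.flatnonzero(~is_cluster)
        n_de = int(round(background_de_fraction * n_bg))
        chosen = rng.choice(bg_idx, size=n_de, replace=False)
        signs = np.where(
            rng.random(n_de) < background_de_down_fraction, -1.0, 1.0
        )
        log2fc_true[chosen] = signs * background_de_log2fc
        planted = [str(g) for g in gene_ids[chosen]]

    mu_wt = base_fpkm * fpkm_to_counts
    mu_mut = mu_wt * 2.0 ** log2fc_true

    cols, data = [], []
    sample_rows = []
    for cond, mu in (("WT", mu_wt), ("mut", mu_mut)):
        for r in range(1, replicates + 1):
            name = f"{cond}_rep{r}"
            cols.append(name)
            data.append(_nb_sample(rng, mu, nb_dispersion))
            sample_rows.append({"sample_id": name, "condition": cond, "replicate": r})

    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    samples = pd.DataFrame(sample_rows)
    library_sizes = pd.Series(float(depth), index=cols)

    truth = {
        "lambda_wt": params.lambda_wt,
        "lambda_mut": params.lambda_mut,
        "expression_coupling": params.expression_coupling,
        "distances": {g: float(dists[g]) for g in cluster_ids},
        "expected_log2fc": dict(zip(gene_ids.tolist(), map(float, log2fc_true))),
        "planted_background_degs": planted,
        "seed": seed,
    }
    cm = CountMatrix(counts=counts, samples=samples, lengths=lengths, library_sizes=library_sizes)
    return cm, truth


# ---------------------------------------------------------------------------
# Contact matrices


def default_planted_boundaries(annotation: LocusAnnotation, region: tuple[int, int]) -> list[int]:
    """Default domain boundaries: TAD-scale (~1 Mb) domains tiling the region
    plus an elevated block bracketing the locus (superTAD)."""
    start, _end = region
    flanking = [start + off for off in
                (700_000, 1_500_000, 2_400_000, 3_200_000, 6_500_000, 7_800_000, 9_000_000)]
    lo, hi = annotation.locus_span
    return sorted(flanking + [lo - 50_000, hi + 100_000])


def simulate_contact_matrix(
    annotation: LocusAnnotation,
    params: ProcessivityParams,
    *,
    bin_size: int = 10_000,
    region: tuple[int, int] | None = None,
    cis_depth: float = 5_000_000,
    condition: str = "WT",
    boundaries: list[int] | None = None,
    tad_elevation: float = 3.0,
    seed: int = 1234,
) -> tuple[ContactMatrix, dict]:
    """Poisson-sampled symmetric contact matrix for a window around the locus.

    Expected counts combine (i) the distance power-law background of the
    contact model, (ii) a ``tad_elevation`` multiplier for bin pairs inside
    the same planted domain, and (iii) for rows anchored at an enhancer
    element, the full enhancer contact term with the condition's
    processivity.  The matrix is scaled so its expected cis total equals
    ``cis_depth`` and sampled Poisson on the upper triangle.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if cis_depth <= 0:
        raise ValueError("cis_depth must be positive")
    chrom = annotation.genes["chrom"].iloc[0]
    if region is None:
        lo, hi = annotation.locus_span
        region = (max(0, lo - 4_000_000), max(0, lo - 4_000_000) + 10_000_000)
    start, end = region
    n = (end - start) // bin_size
    if n < 2:
        raise ValueError("region too small for the requested bin size")

    if boundaries is None:
        boundaries = default_planted_boundaries(annotation, region)
    boundary_bins = sorted(
        {int(round((b - start) / bin_size)) for b in boundaries if start < b < end}
    )

    centers = start + (np.arange(n) + 0.5) * bin_size
    sep = np.abs(centers[:, None] - centers[None, :])
    s = np.maximum(sep, params.background_contact_bin) / params.background_contact_bin
    expected = params.background_contact_scale * s ** (-params.background_contact_exponent)

    domain = np.searchsorted(boundary_bins, np.arange(n), side="right")
    same = domain[:, None] == domain[None, :]
    expected = np.where(same, expected * tad_elevation, expected)

    viewpoints = {}
    for name in annotation.enhancers["name"]:
        lo_e, hi_e = annotation.enhancer_interval(name)
        mid = (lo_e + hi_e) // 2
        if start <= mid < end:
            viewpoints[name] = int((mid - start) // bin_size)
    for name, e in viewpoints.items():
        lo_e, hi_e = annotation.enhancer_interval(name)
        mid = (lo_e + hi_e) / 2.0
        d = np.abs(centers - mid)
        row = enhancer_contact(d, params, condition)
        block = np.where(same[e], tad_elevation, 1.0)
        expected[e, :] = row * block
        expected[:, e] = expected[e, :]

    total = expected.sum()
    if total <= 0:
        raise ValueError("degenerate contact model: zero expected contacts")
    scale = cis_depth / total
    expected *= scale

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n)
    upper = rng.poisson(expected[iu]).astype(float)
    mat = np.zeros((n, n))
    mat[iu] = upper
    mat.T[iu] = upper

    cm = ContactMatrix(matrix=mat, bin_size=bin_size, chrom=chrom, start=start)
    info = {
        "condition": condition,
        "boundaries_bp": [start + b * bin_size for b in boundary_bins],
        "boundary_bins": boundary_bins,
        "tad_elevation": tad_elevation,
        "scale": scale,
        "enhancer_viewpoint_bins": viewpoints,
        "seed": seed,
    }
    return cm, info


def simulate_tad_benchmark_matrix(
    *,
    n_bins: int = 500,
    bin_size: int = 20_000,
    n_boundaries: int = 8,
    min_domain_bins: int = 25,
    tad_elevation: float = 3.0,
    cis_depth: float = 2_000_000,
    power_law_exponent: float = 1.0,
    seed: int = 0,
) -> tuple[ContactMatrix, list[int]]:
    """Planted-boundary benchmark matrix for domain callers.

    Domains tile the whole matrix; boundary bins are drawn uniformly subject
    to a minimum domain width.  Within-domain contacts are elevated by
    ``tad_elevation`` over the distance power-law; counts are Poisson at
    total depth ``cis_depth``.  Returns the matrix and the planted boundary
    bin indices.
    """
    if n_boundaries * min_domain_bins >= n_bins:
        raise ValueError("too many boundaries for the requested minimum domain size")
    rng = np.random.default_rng(seed)
    while True:
        cand = np.sort(rng.choice(np.arange(min_domain_bins, n_bins - min_domain_bins + 1),
                                  size=n_boundaries, replace=False))
        gaps = np.diff(np.concatenate(([0], cand, [n_bins])))
        if (gaps >= min_domain_bins).all():
            boundaries = cand.tolist()
            break

    idx = np.arange(n_bins)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    expected = np.maximum(sep, 1.0) ** (-power_law_exponent)
    domain = np.searchsorted(boundaries, idx, side="right")
    same = domain[:, None] == domain[None, :]
    expected = np.where(same, expected * tad_elevation, expected)
    expected *= cis_depth / expected.sum()

    iu = np.triu_indices(n_bins)
    upper = rng.poisson(expected[iu]).astype(float)
    mat = np.zeros((n_bins, n_bins))
    mat[iu] = upper
    mat.T[iu] = upper
    return ContactMatrix(matrix=mat, bin_size=bin_size), boundaries


# ---------------------------------------------------------------------------
# ChIP peaks and 4C tracks


@dataclass
class ChipSimulation:
    """Peak table plus replicate counts for a cohesin-occupancy ChIP assay."""

    peaks: pd.DataFrame  # peak_id, chrom, start, end, length, kind, gene_id
    counts: CountMatrix
    truth: dict = field(default_factory=dict)


def simulate_chip_and_4c(
    annotation: LocusAnnotation,
    params: ProcessivityParams,
    *,
    nb_dispersion: float = 0.05,
    depth: float = 20_000_000,
    replicates: int = 3,
    peak_baseline_mean: float = 500.0,
    peak_jitter_sd: float = 0.4,
    promoter_halfwidth: int = 500,
    enhancer_peak_attenuation: float = 0.5,
    fourc_viewpoints: tuple[str, ...] = ("HS5-1", "HS18-20", "HS5-1bL"),
    fourc_total_reads: float = 1_000_000,
    fourc_fragment_size: int = 2_000,
    fourc_flank: int = 150_000,
    seed: int = 1234,
) -> tuple[ChipSimulation, dict[tuple[str, str], pd.DataFrame]]:
    """Simulate cohesin ChIP peak counts and one-viewpoint 4C fragment tracks.

    Promoter peaks of cluster genes scale in the mutant by the extrusion
    contact ratio at the gene's enhancer distance.  Enhancer peaks carrying
    a CTCF site are attenuated by ``enhancer_peak_attenuation``; the HS7
    analog lacks a CTCF site and keeps a condition-independent expectation.
    4C tracks tile the locus with fixed-size fragments and draw Poisson
    counts proportional to the enhancer contact profile of the viewpoint.
    """
    for vp in fourc_viewpoints:
        if vp not in ENHANCER_NAMES or vp not in set(annotation.enhancers["name"]):
            raise KeyError(f"unknown 4C viewpoint anchor {vp!r}")
    rng = np.random.default_rng(seed)
    genes = annotation.cluster_genes
    chrom = genes["chrom"].iloc[0]
    dists = gene_distances(annotation)

    peak_rows = []
    mu_wt_list, ratio_list = [], []
    for _, g in genes.iterrows():
        base = peak_baseline_mean * math.exp(rng.normal(0.0, peak_jitter_sd))
        ratio = float(extrusion_contact_ratio(dists[g["gene_id"]], params))
        peak_rows.append(
            {
                "peak_id": g["gene_id"],
                "chrom": chrom,
                "start": int(g["anchor"]) - promoter_halfwidth,
                "end": int(g["anchor"]) + promoter_halfwidth,
                "kind": "promoter",
                "gene_id": g["gene_id"],
            }
        )
        mu_wt_list.append(base)
        ratio_list.append(ratio)
    for _, e in annotation.enhancers.iterrows():
        base = peak_baseline_mean * math.exp(rng.normal(0.0, peak_jitter_sd))
        ratio = enhancer_peak_attenuation if e["name"] in CTCF_SITE_ENHANCERS else 1.0
        peak_rows.append(
            {
                "peak_id": e["name"],
                "chrom": chrom,
                "start": int(e["start"]),
                "end": int(e["end"]),
                "kind": "enhancer",
                "gene_id": "",
            }
        )
        mu_wt_list.append(base)
        ratio_list.append(float(ratio))

    peaks = pd.DataFrame(peak_rows)
    peaks["length"] = peaks["end"] - peaks["start"]
    mu_wt = np.asarray(mu_wt_list)
    mu_mut = mu_wt * np.asarray(ratio_list)

    cols, data, sample_rows = [], [], []
    for cond, mu in (("WT", mu_wt), ("mut", mu_mut)):
        for r in range(1, replicates + 1):
            name = f"{cond}_rep{r}"
            cols.append(name)
            data.append(_nb_sample(rng, mu, nb_dispersion))
            sample_rows.append({"sample_id": name, "condition": cond, "replicate": r})
    counts = pd.DataFrame(
        np.column_stack(data), index=peaks["peak_id"].to_numpy(), columns=cols
    )
    cm = CountMatrix(
        counts=counts,
        samples=pd.DataFrame(sample_rows),
        lengths=pd.Series(peaks["length"].to_numpy(dtype=float), index=peaks["peak_id"]),
        library_sizes=pd.Series(float(depth), index=cols),
    )
    chip = ChipSimulation(
        peaks=peaks,
        counts=cm,
        truth={
            "expected_ratio": dict(zip(peaks["peak_id"], map(float, ratio_list))),
            "seed": seed,
        },
    )

    lo, hi = annotation.locus_span
    frag_start = np.arange(lo - fourc_flank, hi + fourc_flank, fourc_fragment_size)
    frag_mid = frag_start + fourc_fragment_size / 2.0
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    for vp in fourc_viewpoints:
        lo_e, hi_e = annotation.enhancer_interval(vp)
        mid = (lo_e + hi_e) / 2.0
        d = np.abs(frag_mid - mid)
        for cond in ("WT", "mut"):
            intensity = enhancer_contact(d, params, cond)
            mu = fourc_total_reads * intensity / intensity.sum()
            tracks[(vp, cond)] = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": frag_start,
                    "end": frag_start + fourc_fragment_size,
                    "count": rng.poisson(mu),
                }
            )
    return chip, tracks


def write_ground_truth(truth: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
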