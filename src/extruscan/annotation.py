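"""Locus annotation: a clustered-protocadherin-like gene array with enhancers.

The default layout mirrors the architecture of the mouse clustered Pcdh
locus at a schematic level: three tandem gene clusters (14 alpha, 22 beta,
22 gamma variable genes, 58 in total) spanning roughly one megabase,
followed downstream by a battery of named enhancer/hypersensitive elements
(HS5-1, HS7, HS5-1bL, HS18-20, HS21, HS22, HS7L).  Each gene's anchor is
its 5'-UTR position, the reference point for every distance computation.
Background genes are spread over the rest of the chromosome to provide the
genome-wide null for the enrichment scan.

Coordinates are 0-based half-open throughout (BED-native).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomeSpec

__all__ = ["LocusConfig", "LocusAnnotation", "build_locus_annotation", "ENHANCER_NAMES"]

ENHANCER_NAMES = ("HS5-1", "HS7", "HS5-1bL", "HS18-20", "HS21", "HS22", "HS7L")

# Offsets (bp) of each enhancer element inside the enhancer zone that starts
# `enhancer_gap` downstream of the gamma cluster.  Spaced so that distinct
# elements fall in distinct 10-kb contact-matrix bins.
_DEFAULT_ENHANCER_OFFSETS: dict[str, tuple[int, int]] = {
    "HS5-1": (0, 2_000),
    "HS7": (12_000, 14_000),
    "HS5-1bL": (24_000, 26_000),
    "HS18-20": (48_000, 54_000),
    "HS21": (60_000, 62_000),
    "HS22": (72_000, 74_000),
    "HS7L": (84_000, 86_000),
}

# Elements bound by CTCF in the model; HS7 has no CTCF site, so cohesin
# occupancy there is processivity-independent.
CTCF_SITE_ENHANCERS = frozenset(n for n in ENHANCER_NAMES if n not in ("HS7",))


@dataclass(frozen=True)
class LocusConfig:
    """Deterministic geometry of the synthetic locus and background genome."""

    chromosome: str = "chrS"
    genome_length: int = 100_000_000
    locus_start: int = 60_000_000
    cluster_sizes: tuple[int, int, int] = (14, 22, 22)  # alpha, beta, gamma
    gene_spacing: int = 16_000
    gene_length: int = 2_400  # variable-exon length
    intercluster_gap: int = 10_000
    enhancer_gap: int = 20_000
    enhancer_offsets: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_ENHANCER_OFFSETS)
    )
    background_genes: int = 2_000
    background_gene_length: int = 2_000
    background_margin: int = 1_000_000  # keep background genes off chromosome ends

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.gene_spacing <= self.gene_length:
            raise ValueError("gene_spacing must exceed gene_length (genes would overlap)")
        if min(self.cluster_sizes) < 0 or self.background_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if self.gene_length <= 0 or self.background_gene_length <= 0:
            raise ValueError("gene lengths must be positive")
        starts = sorted(self.enhancer_offsets.values())
        for (s0, e0), (s1, e1) in zip(starts, starts[1:]):
            if e0 > s1:
                raise ValueError("enhancer elements overlap")
        for s, e in self.enhancer_offsets.values():
            if e <= s:
                raise ValueError("enhancer intervals must be non-empty half-open ranges")


@dataclass
class LocusAnnotation:
    """Gene and enhancer annotation plus the genome they live on.

    ``genes`` columns: gene_id, cluster (alpha/beta/gamma/background), chrom,
    strand, anchor (5'-UTR bp), exon_start, exon_end, length.
    ``enhancers`` columns: name, chrom, start, end.
    """

    genome: GenomeSpec
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    config: LocusConfig | None = None

    @property
    def cluster_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["cluster"] != "background"]

    @property
    def background_gene_table(self) -> pd.DataFrame:
        return self.genes[self.genes["cluster"] == "background"]

    def enhancer_interval(self, name: str) -> tuple[int, int]:
        row = self.enhancers[self.enhancers["name"] == name]
        if row.empty:
            raise KeyError(f"unknown enhancer element {name!r}")
        return int(row.iloc[0]["start"]), int(row.iloc[0]["end"])

    @property
    def locus_span(self) -> tuple[int, int]:
        """Half-open interval covering cluster genes and enhancers."""
        g = self.cluster_genes
        lo = int(min(g["exon_start"].min(), self.enhancers["start"].min()))
        hi = int(max(g["exon_end"].max(), self.enhancers["end"].max()))
        return lo, hi

    # ---- I/O -------------------------------------------------------------

    def write(self, outdir) -> None:
        """Write genes.bed (+ sidecar TSV), enhancers.bed and chrom.sizes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genes = self.genes
        bed = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["exon_start"],
                "end": genes["exon_end"],
                "name": genes["gene_id"],
                "score": 0,
                "strand": genes["strand"],
            }
        )
        bed.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
        genes[["gene_id", "cluster", "chrom", "anchor", "length"]].to_csv(
            outdir / "genes.tsv", sep="\t", index=False
        )
        enh = pd.DataFrame(
            {
                "chrom": self.enhancers["chrom"],
                "start": self.enhancers["start"],
                "end": self.enhancers["end"],
                "name": self.enhancers["name"],
            }
        )
        enh.to_csv(outdir / "enhancers.bed", sep="\t", header=False, index=False)
        self.genome.to_chrom_sizes(outdir / "chrom.sizes")

    @classmethod
    def read(cls, outdir) -> "LocusAnnotation":
        outdir = Path(outdir)
        genome = GenomeSpec.from_chrom_sizes(outdir / "chrom.sizes")
        bed = pd.read_csv(
            outdir / "genes.bed",
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        sidecar = pd.read_csv(outdir / "genes.tsv", sep="\t")
        genes = sidecar.merge(
            bed[["name", "start", "end", "strand"]],
            left_on="gene_id",
            right_on="name",
        ).drop(columns="name")
        genes = genes.rename(columns={"start": "exon_start", "end": "exon_end"})
        enh = pd.read_csv(
            outdir / "enhancers.bed",
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name"],
        )[["name", "chrom", "start", "end"]]
        return cls(genome=genome, genes=genes, enhancers=enh)


def build_locus_annotation(config: LocusConfig | None = None) -> LocusAnnotation:
    """Lay out the synthetic locus deterministically from ``config``.

    Clusters are placed in order alpha, beta, gamma with fixed intra-cluster
    spacing; all enhancer elements sit downstream of the gamma cluster.  The
    geometry guarantees that beta genes are farther from their assigned
    enhancers (HS18-22) than gamma genes are from theirs (HS5-1bL).
    Background genes are spread evenly over the chromosome outside the locus.
    """
    config = config or LocusConfig()
    config.validate()
    chrom = config.chromosome
    n_alpha, n_beta, n_gamma = config.cluster_sizes

    rows = []
    pos = config.locus_start
    for cluster, n, prefix in (
        ("alpha", n_alpha, "PcdhaS"),
        ("beta", n_beta, "PcdhbS"),
        ("gamma", n_gamma, "PcdhgS"),
    ):
        for i in range(n):
            anchor = pos + i * config.gene_spacing
            rows.append(
                {
                    "gene_id": f"{prefix}{i + 1:02d}",
                    "cluster": cluster,
                    "chrom": chrom,
                    "strand": "+",
                    "anchor": anchor,
                    "exon_start": anchor,
                    "exon_end": anchor + config.gene_length,
                    "length": config.gene_length,
                }
            )
        pos += n * config.gene_spacing + config.intercluster_gap

    zone_start = pos - config.intercluster_gap + config.enhancer_gap
    enh_rows = []
    for name in ENHANCER_NAMES:
        if name not in config.enhancer_offsets:
            continue
        off_s, off_e = config.enhancer_offsets[name]
        enh_rows.append(
            {"name": name, "chrom": chrom, "start": zone_start + off_s, "end": zone_start + off_e}
        )
    enhancers = pd.DataFrame(enh_rows, columns=["name", "chrom", "start", "end"])
    locus_end = int(enhancers["end"].max()) if len(enhancers) else pos

    if locus_end > config.genome_length:
        raise ValueError("locus extends beyond the chromosome")

    # Background genes: even grid over the chromosome, excluding the locus
    # and a margin at each chromosome end.  Deterministic given the config.
    if config.background_genes > 0:
        lo = config.background_margin
        hi = config.genome_length - config.background_margin - config.background_gene_length
        if hi <= lo:
            raise ValueError("chromosome too short for requested background genes")
        candidates = np.linspace(lo, hi, num=int(config.background_genes * 1.2) + 2).astype(int)
        pad = 50_000
        keep = (candidates + config.background_gene_length < config.locus_start - pad) | (
            candidates > locus_end + pad
        )
        candidates = candidates[keep][: config.background_genes]
        if len(candidates) < config.background_genes:
            raise ValueError("could not place the requested number of background genes")
        for j, anchor in enumerate(candidates):
            rows.append(
                {
                    "gene_id": f"BG{j + 1:05d}",
                    "cluster": "background",
                    "chrom": chrom,
                    "strand": "+" if j % 2 == 0 else "-",
                    "anchor": int(anchor),
                    "exon_start": int(anchor),
                    "exon_end": int(anchor) + config.background_gene_length,
                    "length": config.background_gene_length,
                }
            )

    genes = pd.DataFrame(rows)
    _reject_overlaps(genes, enhancers)
    genome = GenomeSpec({chrom: config.genome_length})
    ann = LocusAnnotation(genome=genome, genes=genes, enhancers=enhancers, config=config)
    _check_invariants(ann, config)
    return ann


def _reject_overlaps(genes: pd.DataFrame, enhancers: pd.DataFrame) -> None:
    iv = pd.concat(
        [
            genes[["exon_start", "exon_end"]].rename(
                columns={"exon_start": "start", "exon_end": "end"}
            ),
            enhancers[["start", "end"]],
        ]
    ).sort_values("start")
    starts = iv["start"].to_numpy()
    ends = iv["end"].to_numpy()
    if np.any(ends[:-1] > starts[1:]):
        raise ValueError("annotation intervals overlap; rejecting config")


def _check_invariants(ann: LocusAnnotation, config: LocusConfig) -> None:
    cluster = ann.cluster_genes
    expected = sum(config.cluster_sizes)
    if len(cluster) != expected:
        raise AssertionError(f"expected {expected} cluster genes, got {len(cluster)}")
    anchors = cluster["anchor"].to_numpy()
    if not np.all(np.diff(anchors) > 0):
        raise AssertionError("cluster gene anchors must be strictly increasing")
    if len(ann.enhancers) and anchors.max() >= ann.enhancers["start"].min():
        raise AssertionError("cluster genes must lie upstream of all enhancer elements")
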