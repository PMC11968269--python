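"""Per-modality normalization and condition comparison.

FPKM/RPM computation, replicate fold changes with Welch t-tests and
Benjamini-Hochberg adjustment, DEG calling at the conventional
|log2FC| > 0.5 / padj < 0.05 thresholds, peak-level enrichment, and
virtual-4C per-gene contact quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .annotation import LocusAnnotation
from .contacts import ContactMatrix
from .simulate import CountMatrix

__all__ = [
    "compute_fpkm",
    "fold_change",
    "call_degs",
    "peak_enrichment",
    "rpm_profile",
    "gene_contact_probability",
    "DEGSet",
]


def compute_fpkm(
    counts: pd.DataFrame | CountMatrix,
    lengths: pd.Series | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    ``FPKM = counts * 1e9 / (length_bp * mapped_total)`` per sample.  With a
    :class:`CountMatrix`, lengths and library sizes are taken from it; with
    a bare DataFrame, lengths are required and library sizes default to the
    column sums.
    """
    if isinstance(counts, CountMatrix):
        lengths = counts.lengths if lengths is None else lengths
        library_sizes = counts.library_sizes if library_sizes is None else library_sizes
        counts = counts.counts
    if lengths is None:
        raise ValueError("feature lengths are required")
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths, axis=0).div(library_sizes, axis=1) * 1e9


def peak_enrichment(
    counts: pd.DataFrame | CountMatrix,
    peak_lengths: pd.Series | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM-style enrichment per peak (peak length replaces gene length)."""
    return compute_fpkm(counts, lengths=peak_lengths, library_sizes=library_sizes)


def fold_change(
    levels_wt: pd.DataFrame,
    levels_mut: pd.DataFrame,
    pseudo: float = 0.01,
    modality: str = "RNA",
    equal_var: bool = False,
    log_space: bool = True,
) -> pd.DataFrame:
    """Replicate-level fold changes with t-tests and BH adjustment.

    ``log2FC = log2((mean_mut + pseudo) / (mean_wt + pseudo))``; p-values
    from a two-sample two-tailed t-test across replicates (Welch by
    default, pooled-variance with ``equal_var=True``), adjusted by
    Benjamini-Hochberg within the modality.  By default the t statistic is
    computed on ``log2(level + pseudo)``, the variance-stabilized scale
    customary for FPKM comparisons; ``log_space=False`` tests raw levels.
    With fewer than two replicates on either side, p is NaN (flagged, not
    an error).
    """
    if pseudo < 0:
        raise ValueError("pseudo-count must be non-negative")
    levels_wt, levels_mut = levels_wt.align(levels_mut, join="inner", axis=0)
    wt = levels_wt.to_numpy(dtype=float)
    mut = levels_mut.to_numpy(dtype=float)
    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    log2fc = np.log2((mean_mut + pseudo) / (mean_wt + pseudo))

    if wt.shape[1] >= 2 and mut.shape[1] >= 2:
        if log_space:
            test_wt = np.log2(wt + max(pseudo, 1e-12))
            test_mut = np.log2(mut + max(pseudo, 1e-12))
        else:
            test_wt, test_mut = wt, mut
        tres = scipy.stats.ttest_ind(test_mut, test_wt, axis=1, equal_var=equal_var)
        p = np.asarray(tres.pvalue, dtype=float)
        # zero-variance identical groups yield NaN; identical means -> p = 1
        degenerate = np.isnan(p) & np.isclose(mean_wt, mean_mut)
        p[degenerate] = 1.0
    else:
        p = np.full(len(mean_wt), np.nan)

    padj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene_id": levels_wt.index,
            "modality": modality,
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class DEGSet:
    """Differentially expressed genes at given thresholds."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    lfc_threshold: float
    padj_threshold: float

    @property
    def all(self) -> tuple[str, ...]:
        return self.up + self.down


def call_degs(
    table: pd.DataFrame,
    lfc_threshold: float = 0.5,
    padj_threshold: float = 0.05,
) -> DEGSet:
    """Call DEGs with strict thresholds |log2FC| > lfc and padj < padj.

    Boundary values are excluded (strict inequalities).
    """
    ok = table["padj"].notna() & (table["padj"] < padj_threshold)
    up = table.loc[ok & (table["log2fc"] > lfc_threshold), "gene_id"]
    down = table.loc[ok & (table["log2fc"] < -lfc_threshold), "gene_id"]
    return DEGSet(
        up=tuple(up), down=tuple(down),
        lfc_threshold=lfc_threshold, padj_threshold=padj_threshold,
    )


def rpm_profile(track: pd.DataFrame | np.ndarray, value_col: str = "count") -> pd.DataFrame | np.ndarray:
    """Reads-per-million normalization of a fragment/bin count track.

    Each value becomes ``count * 1e6 / total``; the output sums to 1e6.
    An all-zero track is an error.
    """
    if isinstance(track, pd.DataFrame):
        counts = track[value_col].to_numpy(dtype=float)
    else:
        counts = np.asarray(track, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot RPM-normalize an all-zero track")
    rpm = counts * 1e6 / total
    if isinstance(track, pd.DataFrame):
        out = track.copy()
        out["rpm"] = rpm
        return out
    return rpm


def _overlap_weights(starts: np.ndarray, ends: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Boolean any-overlap (>= 1 bp) of half-open intervals with [lo, hi)."""
    return (starts < hi) & (ends > lo)


def gene_contact_probability(
    source: ContactMatrix | pd.DataFrame,
    anchor_elements: str | tuple[str, ...],
    annotation: LocusAnnotation,
    genes: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-gene contact value from a contact matrix or a 4C track.

    For a matrix, the virtual-4C rows at the anchor elements' midpoint bins
    are RPM-normalized (jointly) and summed over the bins overlapping each
    gene's variable-exon interval.  For a 4C fragment track (DataFrame with
    chrom/start/end and count or rpm), fragment values overlapping the exon
    are summed.  Any-overlap of >= 1 bp in half-open coordinates.
    """
    if isinstance(anchor_elements, str):
        anchor_elements = (anchor_elements,)
    if genes is None:
        genes = annotation.cluster_genes

    if isinstance(source, ContactMatrix):
        rows = []
        for name in anchor_elements:
            lo_e, hi_e = annotation.enhancer_interval(name)
            mid = (lo_e + hi_e) // 2
            rows.append(source.matrix[source.bin_index(int(mid))])
        signal = np.sum(rows, axis=0)
        total = signal.sum()
        if total <= 0:
            raise ValueError("anchor rows carry no signal")
        signal = signal * 1e6 / total
        starts = source.bin_starts()
        ends = starts + source.bin_size
        values = {}
        for _, g in genes.iterrows():
            sel = _overlap_weights(starts, ends, int(g["exon_start"]), int(g["exon_end"]))
            values[g["gene_id"]] = float(signal[sel].sum())
        return pd.Series(values, name="contact")

    track = source
    col = "rpm" if "rpm" in track.columns else "count"
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    vals = track[col].to_numpy(dtype=float)
    values = {}
    for _, g in genes.iterrows():
        sel = _overlap_weights(starts, ends, int(g["exon_start"]), int(g["exon_end"]))
        values[g["gene_id"]] = float(vals[sel].sum())
    return pd.Series(values, name="contact")
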