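"""Coverage-uniformity QC for genomic-DNA contamination.

Genomic DNA in an EV RNA preparation produces near-uniform read coverage
across the genome, whereas genuine RNA-seq coverage is highly peaked (it
tracks expression). The coverage-variance (CV) statistic captures this:
tile each chromosome into large windows, take per-chromosome SD and mean
of the per-tile summed depth, and divide the median of the SDs by the
median of the means. Low CV together with measurable DNA flags a
contaminated sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeIndex, ReadSet, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageStats",
    "tile_coverage",
    "coverage_variance",
    "apply_exclusion",
    "sample_cv",
]

DEFAULT_TILE_SIZE = 1_000_000
DEFAULT_CV_THRESHOLD = 0.5


def tile_coverage(reads: ReadSet, index: GenomeIndex,
                  tile_size: int = DEFAULT_TILE_SIZE) -> dict[str, np.ndarray]:
    """Per-contig tile values: summed per-base depth in each tile.

    A read contributes its overlap length (in nt) to every tile it
    intersects, i.e. the tile value equals the sum of per-base coverage
    over the tile. The last tile of a contig may be shorter than
    ``tile_size``.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    out: dict[str, np.ndarray] = {}
    lengths = index.lengths
    for name, length in index.contigs:
        n_tiles = -(-length // tile_size)
        out[name] = np.zeros(n_tiles, dtype=np.int64)
    df = reads.intervals
    known = df["contig"].isin(lengths.keys()).to_numpy()
    if not known.all():
        logger.warning("sample %s: %d reads on contigs absent from the index "
                       "ignored in coverage tiling", reads.sample_id,
                       int((~known).sum()))
        df = df[known]
    for contig, grp in df.groupby("contig", sort=False):
        tiles = out[contig]
        L = lengths[contig]
        starts = np.minimum(grp["start"].to_numpy(np.int64), L)
        ends = np.minimum(grp["end"].to_numpy(np.int64), L)
        first = starts // tile_size
        last = (ends - 1) // tile_size
        span = last - first + 1
        for k in range(int(span.max()) if len(span) else 0):
            sel = span > k
            t = first[sel] + k
            tile_lo = t * tile_size
            tile_hi = np.minimum(tile_lo + tile_size, L)
            ov = np.minimum(ends[sel], tile_hi) - np.maximum(starts[sel], tile_lo)
            np.add.at(tiles, t, ov)
    return out


@dataclass
class CoverageStats:
    """Per-contig tile summaries and the resulting CV for one sample."""

    sample_id: str
    per_contig: pd.DataFrame   # contig, n_tiles, mean, sd, eligible
    cv: float


def coverage_variance(tiles: dict[str, np.ndarray],
                      tile_size: int | None = None,
                      index: GenomeIndex | None = None) -> float:
    """CV = median over contigs of tile SD / median over contigs of tile mean.

    Per eligible contig the sample SD (n-1 denominator) and mean of tile
    values are computed; a contig is eligible when it has >= 2 complete
    tiles. Ragged final tiles (shorter than ``tile_size``) are excluded
    from the summaries so the last window does not act as a systematic low
    outlier; pass ``tile_size`` and ``index`` to enable that trimming.
    """
    sds, means = [], []
    for contig, values in tiles.items():
        v = np.asarray(values, dtype=float)
        if tile_size is not None and index is not None:
            n_complete = index.lengths[contig] // tile_size
            v = v[:n_complete]
        if len(v) < 2:
            continue
        sds.append(np.std(v, ddof=1))
        means.append(np.mean(v))
    if not sds:
        raise ValueError("insufficient coverage: no contig with >= 2 tiles")
    med_mean = float(np.median(means))
    if med_mean == 0:
        raise ValueError("insufficient coverage: median tile mean is zero")
    return float(np.median(sds)) / med_mean


def sample_cv(reads: ReadSet, index: GenomeIndex,
              tile_size: int = DEFAULT_TILE_SIZE) -> CoverageStats:
    """Convenience wrapper: tile a sample's reads and compute its CV."""
    tiles = tile_coverage(reads, index, tile_size=tile_size)
    rows = []
    for contig, values in tiles.items():
        n_complete = index.lengths[contig] // tile_size
        v = values[:n_complete].astype(float)
        eligible = len(v) >= 2
        rows.append({
            "contig": contig,
            "n_tiles": len(values),
            "mean": float(np.mean(v)) if eligible else np.nan,
            "sd": float(np.std(v, ddof=1)) if eligible else np.nan,
            "eligible": eligible,
        })
    cv = coverage_variance(tiles, tile_size=tile_size, index=index)
    return CoverageStats(sample_id=reads.sample_id,
                         per_contig=pd.DataFrame(rows), cv=cv)


def apply_exclusion(sheet: SampleSheet, cv_by_sample: dict[str, float],
                    cv_threshold: float = DEFAULT_CV_THRESHOLD,
                    ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Discovery-cohort exclusion rule for DNA-contaminated samples.

    A sample is excluded iff it has measurable DNA (``dna_rna_ratio > 0``)
    AND its coverage variance is below ``cv_threshold`` (strict ``<``); the
    conjunction means a low CV alone, or DNA alone, never excludes.

    Returns (retained_ids, excluded_ids, report); the report lists
    per-sample cv, dna_rna_ratio and the decision.
    """
    missing = [s for s in sheet.sample_ids if s not in cv_by_sample]
    if missing:
        raise ValueError(f"missing CV for sample(s): {missing}")
    rows = []
    retained, excluded = [], []
    for r in sheet.rows.itertuples(index=False):
        cv = float(cv_by_sample[r.sample_id])
        out = r.dna_rna_ratio > 0 and cv < cv_threshold
        (excluded if out else retained).append(r.sample_id)
        rows.append({"sample_id": r.sample_id, "group": r.group, "cv": cv,
                     "dna_rna_ratio": r.dna_rna_ratio, "excluded": out})
    report = pd.DataFrame(rows)
    return retained, excluded, report
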