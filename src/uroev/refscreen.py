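"""Screen expressed regions for stable qPCR reference-gene candidates.

A good reference transcript is highly and uniformly expressed across the
cohort. Candidates are runs of genomically consecutive regions whose mean
TPM is high (above a percentile of all region means) and whose worst
coefficient of variation (SD/mean across samples) within the run is low.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneAnnotation
from .regions import TPMMatrix, annotate_regions

logger = logging.getLogger(__name__)

__all__ = ["screen_reference_regions"]


def screen_reference_regions(tpm: TPMMatrix,
                             annotation: GeneAnnotation | None = None,
                             run_length: int = 2,
                             min_mean_percentile: float = 90.0,
                             ) -> pd.DataFrame:
    """Rank runs of consecutive high-expression, low-variability regions.

    Every maximal run of >= ``run_length`` regions that are adjacent in the
    grid (same contig, each region's end equal to the next one's start) and
    whose per-region mean TPM each exceeds the ``min_mean_percentile``-th
    percentile of all region means is scored with
    ``stability = max over the run of (SD/mean)`` (sample SD, n-1); runs
    are returned sorted by stability ascending, annotated with the names of
    genes overlapping the run when an annotation is given.

    Defaults (pair runs, 90th-percentile mean cut, max aggregation) are
    package choices exposed as parameters, not field-standard constants.
    """
    values = tpm.values
    regions = tpm.regions
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sds / means).to_numpy()
    cv = np.where(np.isfinite(cv), cv, np.inf)
    cutoff = np.percentile(means.to_numpy(), min_mean_percentile)
    high = means.to_numpy() > cutoff

    rows = []
    keys = list(regions.index)
    contig = regions["contig"].to_numpy()
    start = regions["start"].to_numpy()
    end = regions["end"].to_numpy()
    i = 0
    n = len(regions)
    while i < n:
        if not high[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and high[j + 1] and contig[j + 1] == contig[j]
               and start[j + 1] == end[j]):
            j += 1
        if j - i + 1 >= run_length:
            run = slice(i, j + 1)
            rows.append({
                "contig": contig[i],
                "start": int(start[i]),
                "end": int(end[j]),
                "n_regions": j - i + 1,
                "region_keys": keys[run],
                "mean_tpm": float(means.to_numpy()[run].mean()),
                "stability": float(cv[run].max()),
            })
        i = j + 1

    if not rows:
        logger.warning("no run of >= %d consecutive regions above the "
                       "%sth-percentile mean", run_length, min_mean_percentile)
        return pd.DataFrame(columns=["rank", "contig", "start", "end",
                                     "n_regions", "region_keys", "mean_tpm",
                                     "stability", "genes"])

    out = pd.DataFrame(rows).sort_values("stability", kind="stable")
    out = out.reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))

    if annotation is not None:
        spans = pd.DataFrame({"contig": out["contig"].to_numpy(),
                              "start": out["start"].to_numpy(),
                              "end": out["end"].to_numpy()},
                             index=[f"run{r}" for r in out["rank"]])
        labels = annotate_regions(spans, annotation)
        out["genes"] = [sorted({name for name, _ in lab})
                        for lab in labels.to_numpy()]
    else:
        out["genes"] = [[] for _ in range(len(out))]
    return out
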