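"""Replicate CT averaging, delta-delta-CT quantification and predictors.

qPCR threshold cycles (CT) halve the template per cycle, so a one-cycle
difference is a two-fold expression difference. Relative levels are
2^(-dCT) with dCT = CT_target - CT_reference for the assay's matched
reference gene; logarithmized levels are the predictors fed to the
diagnostic models (any log base yields the same AUC and p-values, and
IQR-scaled odds ratios are base-invariant).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MAX_CYCLES",
    "validate_ct_table",
    "average_ct",
    "relative_expression",
    "log_predictor",
]

MAX_CYCLES = 45.0
CT_COLUMNS = ["sample_id", "assay_id", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a CT table (sample_id, assay_id, replicate, ct in (0, 45])."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CT table missing column(s): {missing}")
    ct = table["ct"].astype(float)
    if ((ct <= 0) | (ct > MAX_CYCLES)).any():
        raise ValueError(f"CT values must lie in (0, {MAX_CYCLES}]")
    return table


def average_ct(table: pd.DataFrame, discordance_limit: float = 1.0,
               treat_max_as_missing: bool = True) -> pd.DataFrame:
    """Mean CT over replicate reactions per sample x assay.

    Returns a DataFrame with columns sample_id, assay_id, mean_ct,
    n_replicates and flag. Replicate pairs differing by more than
    ``discordance_limit`` cycles are flagged "discordant"; a lone replicate
    is flagged "single replicate". A CT equal to the final cycle (45) means
    no amplification was observed and is treated as missing, not censored;
    groups with no usable replicate yield a missing mean and are logged.
    """
    validate_ct_table(table)
    t = table.copy()
    t["ct"] = t["ct"].astype(float)
    if treat_max_as_missing:
        at_max = t["ct"] >= MAX_CYCLES
        if at_max.any():
            logger.info("%d CT value(s) at the %g-cycle limit treated as "
                        "missing", int(at_max.sum()), MAX_CYCLES)
            t.loc[at_max, "ct"] = np.nan
    rows = []
    for (sid, aid), grp in t.groupby(["sample_id", "assay_id"], sort=False):
        cts = grp["ct"].dropna().to_numpy()
        if len(cts) == 0:
            logger.warning("sample %s assay %s: no usable replicate", sid, aid)
            rows.append({"sample_id": sid, "assay_id": aid, "mean_ct": np.nan,
                         "n_replicates": 0, "flag": "missing"})
            continue
        flag = ""
        if len(cts) == 1:
            flag = "single replicate"
        elif cts.max() - cts.min() > discordance_limit:
            flag = "discordant"
        rows.append({"sample_id": sid, "assay_id": aid,
                     "mean_ct": float(cts.mean()), "n_replicates": len(cts),
                     "flag": flag})
    return pd.DataFrame(rows)


def relative_expression(mean_ct: pd.DataFrame,
                        refmap: dict[str, str]) -> pd.DataFrame:
    """Delta-CT relative levels, 2^-(CT_target - CT_reference).

    ``refmap`` maps each target assay to its reference assay (which must be
    present in the table and may not be its own reference). Samples missing
    either CT get a missing level. Without an inter-run calibrator the
    delta-delta-CT quantity is defined up to a constant factor per assay;
    downstream logistic models absorb that constant into their intercept.
    """
    for target, ref in refmap.items():
        if target == ref:
            raise ValueError(f"assay {target!r} mapped to itself as reference")
        if ref not in set(mean_ct["assay_id"]):
            raise ValueError(f"reference assay {ref!r} absent from CT table")
    wide = mean_ct.pivot(index="sample_id", columns="assay_id",
                         values="mean_ct")
    out = {}
    for target, ref in refmap.items():
        if target not in wide.columns:
            logger.warning("target assay %s absent from CT table", target)
            continue
        dct = wide[target] - wide[ref]
        out[target] = np.power(2.0, -dct)
    return pd.DataFrame(out, index=wide.index)


def log_predictor(levels: pd.DataFrame, base: float = np.e) -> pd.DataFrame:
    """Logarithmized relative levels, the model-ready predictors.

    For base e this is -dCT * ln 2, an affine function of the CT
    difference. Missing levels stay missing; non-positive levels are an
    error (they cannot arise from 2^-dCT).
    """
    vals = levels.to_numpy(dtype=float)
    if (vals[np.isfinite(vals)] <= 0).any():
        raise ValueError("relative levels must be positive")
    return np.log(levels) / np.log(base)
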