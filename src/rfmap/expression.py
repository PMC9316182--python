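"""Relative gene expression from qPCR Ct tables by the 2^-ddCt method.

For each (group, stage) block, dCt = mean Ct of the target gene minus
mean Ct of the reference gene over replicates; the fold change relative
to a calibrator block is 2^-(dCt_sample - dCt_calibrator).  Group
comparisons use a two-sided unequal-variance (Welch) t-test on
per-replicate dCt values, with the usual significance tiers
(* p < 0.05, ** p < 0.01).

Missing Ct values ("expression not detected") stay missing and are
reported as ND, never as zero.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["group", "stage", "gene", "replicate", "ct"]
STAGES = ("LEAF", "S1", "S2", "S3")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated Ct table with columns group/stage/gene/replicate/ct."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df


def write_ct_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="ND")


def delta_ct(
    table: pd.DataFrame, target: str, reference: str
) -> pd.DataFrame:
    """Per-replicate dCt = Ct_target - Ct_reference for every block.

    Replicates are paired by replicate id within each (group, stage).
    """
    tgt = table[table["gene"] == target]
    ref = table[table["gene"] == reference]
    if ref.empty:
        raise ValueError(f"no rows for reference gene {reference!r}")
    if tgt.empty:
        raise ValueError(f"no rows for target gene {target!r}")
    keys = ["group", "stage", "replicate"]
    merged = tgt.merge(ref, on=keys, suffixes=("_target", "_reference"))
    blocks = tgt[["group", "stage"]].drop_duplicates()
    covered = merged[["group", "stage"]].drop_duplicates()
    lost = blocks.merge(covered, how="left", indicator=True)
    lost = lost[lost["_merge"] == "left_only"]
    if not lost.empty:
        raise ValueError(
            "missing reference-gene rows for blocks: "
            + ", ".join(f"{g}/{s}" for g, s in lost[["group", "stage"]].itertuples(index=False))
        )
    merged["dct"] = merged["ct_target"] - merged["ct_reference"]
    return merged[keys + ["dct"]]


def relative_expression(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: tuple[str, str],
) -> pd.DataFrame:
    """2^-ddCt fold change per (group, stage), relative to the calibrator.

    Returns one row per block with the replicate-mean dCt, ddCt and
    fold change; blocks with no detectable target expression have NaN
    fold change (ND).  The calibrator block has fold change 1 exactly.
    """
    dct = delta_ct(table, target, reference)
    means = dct.groupby(["group", "stage"], as_index=False)["dct"].mean()
    cal = means[(means["group"] == calibrator[0]) & (means["stage"] == calibrator[1])]
    if cal.empty:
        raise ValueError(f"calibrator block {calibrator} not present")
    cal_dct = float(cal["dct"].iloc[0])
    means["ddct"] = means["dct"] - cal_dct
    means["fold_change"] = np.power(2.0, -means["ddct"])
    return means


def replicate_fold_changes(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: tuple[str, str],
) -> pd.DataFrame:
    """Per-replicate fold changes (ddCt against the calibrator mean dCt)."""
    dct = delta_ct(table, target, reference)
    cal = dct[(dct["group"] == calibrator[0]) & (dct["stage"] == calibrator[1])]
    if cal.empty:
        raise ValueError(f"calibrator block {calibrator} not present")
    cal_dct = cal["dct"].mean()
    out = dct.copy()
    out["fold_change"] = np.power(2.0, -(out["dct"] - cal_dct))
    return out


def compare_groups(
    dct_a: np.ndarray | list[float], dct_b: np.ndarray | list[float]
) -> tuple[float, str]:
    """Welch t-test on replicate dCt values; returns (p, tier).

    Tiers: 'ns', '*' (p < 0.05), '**' (p < 0.01).
    """
    a = np.asarray(dct_a, dtype=float)
    b = np.asarray(dct_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("at least two replicates per group required")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    tier = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
    return p, tier
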