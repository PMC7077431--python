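"""Relative qPCR expression by the comparative-Ct (delta-delta-Ct) method.

For each sample and freezing condition, the target-gene Ct is compared with
an internal reference ("actin"); the delta-Ct difference between a
treatment condition and the control condition (default 4 degrees C) gives

    fold = 2 ** (-ddCt),   ddCt = dCt_condition - dCt_control

assuming perfect doubling per cycle (amplification efficiency 2.0).
Technical replicates are averaged within each biological replicate first;
the standard error of ddCt is propagated from the biological-replicate
spread of dCt (variances of the two conditions add), and the fold-change
SE is fold * ln(2) * SE(ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "gene_role", "condition", "bio_rep", "tech_rep", "ct")


@dataclass
class FoldChange:
    sample: str
    condition: float
    ddct: float
    fold: float
    se_fold: float
    se_ddct: float
    n_bio: int


def _delta_ct(ct_table: pd.DataFrame, sample, condition):
    """Per-biological-replicate dCt (target - reference) for one cell.

    Returns (mean dCt, variance-of-mean contribution, n biological reps).
    """
    cell = ct_table[(ct_table["sample"] == sample) & (ct_table["condition"] == condition)]
    if (cell["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    per_bio = {}
    for role in ("target", "reference"):
        sub = cell[cell["gene_role"] == role]
        if sub.empty:
            raise ValueError(
                f"missing cell: sample={sample!r} condition={condition!r} role={role!r}"
            )
        per_bio[role] = sub.groupby("bio_rep")["ct"].mean()
    common = per_bio["target"].index.intersection(per_bio["reference"].index)
    if len(common) == 0:
        raise ValueError(
            f"no paired biological replicates for sample={sample!r} condition={condition!r}"
        )
    dct = per_bio["target"].loc[common] - per_bio["reference"].loc[common]
    n = len(dct)
    var_mean = float(dct.var(ddof=1) / n) if n > 1 else 0.0
    return float(dct.mean()), var_mean, n


def delta_delta_ct(
    ct_table: pd.DataFrame,
    sample,
    condition,
    control_condition=4.0,
) -> FoldChange:
    """Fold change of one sample at one condition relative to the control."""
    for col in REQUIRED_COLUMNS:
        if col not in ct_table.columns:
            raise ValueError(f"Ct table lacks required column {col!r}")
    dct_c, var_c, n_c = _delta_ct(ct_table, sample, condition)
    dct_0, var_0, n_0 = _delta_ct(ct_table, sample, control_condition)
    if condition == control_condition:
        ddct, se_ddct = 0.0, math.sqrt(2.0 * var_0)
    else:
        ddct = dct_c - dct_0
        se_ddct = math.sqrt(var_c + var_0)
    fold = 2.0 ** (-ddct)
    return FoldChange(
        sample=sample,
        condition=condition,
        ddct=ddct,
        fold=fold,
        se_fold=fold * math.log(2.0) * se_ddct,
        se_ddct=se_ddct,
        n_bio=min(n_c, n_0),
    )


def expression_profile(
    ct_table: pd.DataFrame, control_condition=4.0
) -> pd.DataFrame:
    """Long fold-change table over every sample x condition in ``ct_table``.

    Samples lacking the control condition are skipped with a warning; the
    control condition's own row has fold identically 1.  Output is sorted by
    (sample, condition) so row order in the input is irrelevant.
    """
    import warnings

    rows = []
    species_of = {}
    if "species" in ct_table.columns:
        species_of = (
            ct_table.drop_duplicates("sample").set_index("sample")["species"].to_dict()
        )
    for sample in sorted(ct_table["sample"].unique()):
        sub = ct_table[ct_table["sample"] == sample]
        if control_condition not in set(sub["condition"]):
            warnings.warn(
                f"sample {sample!r} lacks control condition {control_condition!r}; skipped",
                stacklevel=2,
            )
            continue
        for condition in sorted(sub["condition"].unique()):
            fc = delta_delta_ct(ct_table, sample, condition, control_condition)
            rows.append(
                {
                    "sample": sample,
                    "species": species_of.get(sample, sample),
                    "condition": condition,
                    "ddct": fc.ddct,
                    "fold": fc.fold,
                    "se_fold": fc.se_fold,
                    "n_bio": fc.n_bio,
                }
            )
    return pd.DataFrame(rows)
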