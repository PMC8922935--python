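"""Expression normalization, fold-change calls and qRT-PCR quantities.

FPKM matrices are normalized as log2(FPKM + 1).  Stress induction is called
on linear-scale ratios (stress + pseudocount) / (control + pseudocount)
against a fold threshold (default 2.0, induced if strictly above, repressed
if strictly below its reciprocal).  Relative qRT-PCR expression uses the
2^-ddCt method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FOLD_THRESHOLD = 2.0
#: small FPKM offset keeping ratios finite at zero controls
DEFAULT_PSEUDOCOUNT = 0.01


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); rejects negative FPKM naming the cell."""
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative FPKM at gene {matrix.index[i]!r}, "
            f"column {matrix.columns[j]!r}"
        )
    return pd.DataFrame(
        np.log2(arr + 1.0), index=matrix.index, columns=matrix.columns
    )


def fold_change_calls(
    matrix: pd.DataFrame,
    condition_map: dict,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    replicates: dict | None = None,
) -> pd.DataFrame:
    """Call induced/repressed genes per stress condition.

    ``condition_map`` maps condition -> control column (None marks a control
    itself).  When ``replicates`` maps condition -> list of replicate
    columns, replicate means feed the ratio and a two-sided Welch t-test
    p-value is reported alongside; otherwise p_value is NaN.
    """
    rows = []
    for cond, ctrl in condition_map.items():
        if ctrl is None:
            continue
        if ctrl not in condition_map:
            raise ValueError(f"condition {cond!r}: missing control {ctrl!r}")
        if replicates:
            s_cols = replicates[cond]
            c_cols = replicates[ctrl]
            s_vals = matrix[s_cols].mean(axis=1)
            c_vals = matrix[c_cols].mean(axis=1)
        else:
            s_vals = matrix[cond]
            c_vals = matrix[ctrl]
        ratio = (s_vals + pseudocount) / (c_vals + pseudocount)
        for gene in matrix.index:
            r = float(ratio.loc[gene])
            if r > threshold:
                direction = "induced"
            elif r < 1.0 / threshold:
                direction = "repressed"
            else:
                direction = "none"
            p = float("nan")
            if replicates and len(replicates[cond]) > 1 and len(replicates[ctrl]) > 1:
                p = float(
                    stats.ttest_ind(
                        matrix.loc[gene, replicates[cond]],
                        matrix.loc[gene, replicates[ctrl]],
                        equal_var=False,
                    ).pvalue
                )
            rows.append((gene, cond, r, direction, p))
    return pd.DataFrame(
        rows, columns=["gene", "condition", "ratio", "direction", "p_value"]
    )


def relative_expression(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """2^-ddCt fold change of a target gene against a reference gene."""
    for v in (ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
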