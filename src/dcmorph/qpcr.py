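"""Relative qPCR quantification by the comparative-Ct (2^-ddCt) method.

Target-gene Ct values are normalised per sample to a reference gene
(dCt = Ct_target - Ct_reference), referenced to the mean dCt of a control
condition (ddCt), and expressed as fold change 2^-ddCt.  The control group
then averages to fold 1 on the log scale ("base unit equal to 1").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change"]


def ddct_fold_change(
    ct_table: pd.DataFrame,
    control_condition: str,
    reference_gene: str = "Gapdh",
    target_gene: str | None = None,
) -> pd.DataFrame:
    """Per-sample fold changes 2^-ddCt from a long-form Ct table.

    Parameters
    ----------
    ct_table
        Columns (sample_id, condition, gene, ct); one reference-gene Ct per
        sample is required.
    control_condition
        Condition whose mean dCt is the baseline (its geometric-mean fold
        is exactly 1).
    reference_gene
        Housekeeping gene used for per-sample normalisation.
    target_gene
        The gene to quantify; inferred when the table holds exactly one
        non-reference gene.

    Returns
    -------
    DataFrame with one row per sample: (sample_id, condition, gene, dct,
    ddct, fold_change).
    """
    required = {"sample_id", "condition", "gene", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    genes = set(ct_table["gene"])
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if target_gene is None:
        others = sorted(genes - {reference_gene})
        if len(others) != 1:
            raise ValueError(
                f"cannot infer target gene among {others}; pass target_gene"
            )
        target_gene = others[0]
    if control_condition not in set(ct_table["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in table")

    ref = (
        ct_table[ct_table["gene"] == reference_gene]
        .groupby("sample_id")["ct"]
        .mean()
    )
    tgt = ct_table[ct_table["gene"] == target_gene]
    if tgt.empty:
        raise ValueError(f"no rows for target gene {target_gene!r}")
    rows = []
    for (sid, cond), grp in tgt.groupby(["sample_id", "condition"], sort=False):
        if sid not in ref.index:
            raise ValueError(f"sample {sid!r} lacks a reference-gene Ct")
        rows.append(
            dict(
                sample_id=sid,
                condition=cond,
                gene=target_gene,
                dct=float(grp["ct"].mean() - ref.loc[sid]),
            )
        )
    out = pd.DataFrame(rows)
    control_dct = out.loc[out["condition"] == control_condition, "dct"]
    if control_dct.empty:
        raise ValueError("control condition has no target-gene samples")
    baseline = float(control_dct.mean())
    out["ddct"] = out["dct"] - baseline
    out["fold_change"] = np.power(2.0, -out["ddct"])
    return out
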