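"""Relative quantification of qPCR data by 2^(-ddCT) and concordance with
array-derived fold changes.

CT values are normalized to a reference gene (rice actin-1 by default) and
to the untreated calibrator condition (CK).  Technical replicates are
averaged on the CT scale; relative quantities are averaged across
biological replicates with their standard deviation reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import TREATMENT_TIME_POINTS, FoldChangeTable

__all__ = ["QpcrPlate", "delta_delta_ct", "concordance"]

REQUIRED_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "ct")


@dataclass
class QpcrPlate:
    """Long-format CT records plus the normalization scheme.

    ``records`` columns: gene, condition, bio_rep, tech_rep, ct.  The
    reference gene must be measured in every condition/biological replicate
    that any target gene is measured in.
    """

    records: pd.DataFrame
    reference_gene: str = "actin1"
    calibrator: str = "CK"

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"plate records missing columns: {sorted(missing)}")
        if self.reference_gene not in set(self.records["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} not on plate")

    def targets(self) -> list[str]:
        return sorted(set(self.records["gene"]) - {self.reference_gene})


def delta_delta_ct(plate: QpcrPlate) -> pd.DataFrame:
    """Compute per-(gene, condition) relative quantities by 2^(-ddCT).

    Technical replicates are first averaged to one CT per (gene, condition,
    biological replicate); dCT = CT_target - CT_reference within each
    (condition, bio rep); ddCT = dCT_condition - dCT_calibrator within each
    bio rep; RQ = 2^(-ddCT) is averaged across biological replicates with
    its standard deviation.  Returns columns ``gene, condition, delta_ct,
    dd_ct, rq, log2_rq, rq_sd``.
    """
    rec = plate.records
    ct = (
        rec.groupby(["gene", "condition", "bio_rep"])["ct"].mean().rename("ct")
    )
    try:
        ref = ct.xs(plate.reference_gene, level="gene")
    except KeyError:
        raise ValueError("reference gene has no measurements") from None

    rows = []
    for gene in plate.targets():
        tgt = ct.xs(gene, level="gene")
        dct = tgt - ref.reindex(tgt.index)
        if dct.isna().any():
            missing = dct.index[dct.isna()].tolist()
            raise ValueError(
                f"reference gene missing for {gene} at {missing}"
            )
        conditions = dct.index.get_level_values("condition")
        if plate.calibrator not in set(conditions):
            raise ValueError(f"calibrator {plate.calibrator!r} missing for {gene}")
        cal = dct.xs(plate.calibrator, level="condition")
        for condition in dict.fromkeys(conditions):  # preserve order
            sub = dct.xs(condition, level="condition")
            # pair biological replicates with the calibrator replicate-wise;
            # a bio rep without a calibrator measurement is dropped
            common = sub.index.intersection(cal.index)
            ddct = (sub.loc[common] - cal.loc[common]).to_numpy()
            rq = np.exp2(-ddct)
            rows.append(
                (
                    gene,
                    condition,
                    float(sub.mean()),
                    float(ddct.mean()),
                    float(rq.mean()),
                    float(np.log2(rq.mean())),
                    float(rq.std(ddof=1)) if rq.size > 1 else 0.0,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "condition", "delta_ct", "dd_ct", "rq", "log2_rq", "rq_sd"],
    )


def concordance(
    rq: pd.DataFrame, fct: FoldChangeTable, genes=None
) -> dict:
    """Agreement between qPCR log2 RQ and array log2 fold change.

    Compares, per gene and treatment time point, the sign of the qPCR
    log2 RQ with the sign of the array log2FC, and the Pearson correlation
    of the two concatenated log2FC vectors.  Returns a dict with keys
    ``sign_concordance`` (fraction in [0, 1]), ``pearson_r``, ``n`` and a
    per-observation ``table``.
    """
    if genes is None:
        genes = sorted(set(rq["gene"]) & set(fct.probes))
    genes = [g for g in genes if g in set(rq["gene"]) and g in fct.probes]
    if not genes:
        raise ValueError("no overlapping genes between qPCR and array tables")

    qt = rq.set_index(["gene", "condition"])["log2_rq"]
    rows = []
    for gene in genes:
        for tp in TREATMENT_TIME_POINTS:
            if (gene, tp) not in qt.index:
                continue
            q = float(qt.loc[(gene, tp)])
            a = float(fct.log2fc.loc[gene, tp])
            rows.append((gene, tp, q, a, np.sign(q) == np.sign(a)))
    table = pd.DataFrame(
        rows, columns=["gene", "time_point", "qpcr_log2fc", "array_log2fc", "sign_agree"]
    )
    x = table["qpcr_log2fc"].to_numpy()
    y = table["array_log2fc"].to_numpy()
    if x.size >= 2 and x.std() > 0 and y.std() > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = float("nan")
    return {
        "sign_concordance": float(table["sign_agree"].mean()),
        "pearson_r": r,
        "n": len(table),
        "table": table,
    }
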