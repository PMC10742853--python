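"""Relative quantification by the 2^-ddCt method.

Within each sample, a gene's Ct is normalized to the reference gene
(dCt = Ct_gene - Ct_ref); ddCt subtracts the gene's mean control-group
dCt, and the fold change relative to control is 2^-ddCt, assuming a
doubling of product per cycle.  Because the baseline is the arithmetic
mean of the control dCt values, the *geometric* mean of the
control-group fold changes is exactly 1 — a useful internal check.

Group summaries report both the geometric mean fold (the natural
statistic on this log scale) and the arithmetic mean ± SEM (the form
error bars are usually drawn in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CtMatrix

__all__ = ["RelQuantResult", "compute_delta_ct", "compute_fold_changes"]

logger = logging.getLogger(__name__)


def compute_delta_ct(ct: CtMatrix, reference: str) -> pd.DataFrame:
    """Per-(gene, sample) dCt = Ct_gene - Ct_reference.

    The reference gene must be detected in every sample; undetermined
    target wells propagate as missing dCt.
    """
    if reference not in ct.ct.index:
        raise KeyError(f"reference gene {reference!r} not in matrix")
    ref = ct.ct.loc[reference]
    if ref.isna().any():
        bad = ref.index[ref.isna()].tolist()
        raise ValueError(
            f"reference gene {reference!r} undetermined in samples {bad}"
        )
    return ct.ct.sub(ref, axis=1)


@dataclass
class RelQuantResult:
    """Fold changes and group summaries for one reference gene.

    ``per_sample`` columns: gene, sample, condition, ct, delta_ct,
    delta_delta_ct, fold.  ``per_group`` columns: gene, condition, n,
    geomean_fold, mean_fold, sem_fold.
    """

    per_sample: pd.DataFrame
    per_group: pd.DataFrame
    reference: str
    control_label: str
    dropped_genes: list[str]

    def fold_matrix(self) -> pd.DataFrame:
        """genes x samples frame of fold changes."""
        return self.per_sample.pivot(index="gene", columns="sample", values="fold")


def compute_fold_changes(
    delta_ct: pd.DataFrame,
    condition: pd.Series,
    control_label: str = "control",
    reference: str = "",
    ct: CtMatrix | None = None,
    baseline: str = "mean",
    min_per_group: int = 2,
) -> RelQuantResult:
    """ddCt and 2^-ddCt fold changes from a dCt frame.

    The per-gene baseline is the arithmetic mean (or, optionally, the
    median) of the control-group dCt.  Genes with fewer than
    ``min_per_group`` non-missing control dCt values are dropped with a
    warning.
    """
    if baseline not in ("mean", "median"):
        raise ValueError(f"baseline must be 'mean' or 'median', got {baseline!r}")
    condition = condition.reindex(delta_ct.columns)
    control_samples = [s for s in delta_ct.columns if condition[s] == control_label]
    if not control_samples:
        raise ValueError(
            f"no samples with control label {control_label!r} "
            f"(have {sorted(set(condition))})"
        )

    dropped: list[str] = []
    sample_rows = []
    group_rows = []
    for gene in delta_ct.index:
        dct = delta_ct.loc[gene]
        ctrl = dct[control_samples].dropna()
        if len(ctrl) < min_per_group:
            dropped.append(gene)
            logger.warning(
                "gene %s dropped: only %d control samples with dCt "
                "(need >= %d)", gene, len(ctrl), min_per_group
            )
            continue
        base = float(ctrl.median() if baseline == "median" else ctrl.mean())
        ddct = dct - base
        fold = np.power(2.0, -ddct)
        for s in delta_ct.columns:
            sample_rows.append(
                {
                    "gene": gene,
                    "sample": s,
                    "condition": condition[s],
                    "ct": ct.ct.at[gene, s] if ct is not None else np.nan,
                    "delta_ct": dct[s],
                    "delta_delta_ct": ddct[s],
                    "fold": fold[s],
                }
            )
        for cond in dict.fromkeys(condition):
            f = fold[[s for s in delta_ct.columns if condition[s] == cond]].dropna()
            if len(f) < min_per_group:
                continue
            group_rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "n": len(f),
                    "geomean_fold": float(np.exp(np.log(f).mean())),
                    "mean_fold": float(f.mean()),
                    "sem_fold": float(f.std(ddof=1) / np.sqrt(len(f))),
                }
            )
    return RelQuantResult(
        per_sample=pd.DataFrame(sample_rows),
        per_group=pd.DataFrame(group_rows),
        reference=reference,
        control_label=control_label,
        dropped_genes=dropped,
    )
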