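"""Two-group statistics for expression comparisons.

Per gene: Shapiro-Wilk normality check within each group, an unpaired
two-sided Student's t-test (classic pooled-variance form; Welch
available), and mean ± SEM per group.  Differences are flagged
significant at p <= 0.05.  No multiple-testing correction is applied by
default — mirroring common single-gene qPCR reporting practice — but a
Benjamini-Hochberg adjusted column can be requested; with ~60 genes
tested at once the uncorrected flags should be read accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "compare_groups", "percent_of_control"]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Per-gene two-group comparison results.

    ``table`` columns: gene, n_<group>, mean_<group>, sem_<group>,
    shapiro_p_<group>, t, p, significant (and p_adj if requested).
    """

    table: pd.DataFrame
    scale: str
    skipped_genes: list[str]


def _t_pooled(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classic Student t (pooled variance), handling the degenerate
    zero-variance case explicitly."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # no variation, no difference
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_groups(
    values: pd.DataFrame,
    condition: pd.Series,
    scale: str = "fold",
    welch: bool = False,
    adjust: bool = False,
    alpha: float = ALPHA,
) -> GroupComparison:
    """Compare the two conditions gene by gene.

    ``values`` is a genes x samples frame of the quantity under test
    (fold changes or ddCt, per ``scale``); ``condition`` labels each
    sample.  Genes with fewer than 3 non-missing values in either group
    are skipped with a warning (the Shapiro-Wilk test needs n >= 3).
    """
    if scale not in ("fold", "ddct"):
        raise ValueError(f"scale must be 'fold' or 'ddct', got {scale!r}")
    condition = condition.reindex(values.columns)
    # deterministic group order by label, so t's sign depends only on the
    # label pair, not on column order, and relabelling negates it
    groups = sorted(set(condition))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 conditions, have {groups}")
    ga, gb = groups
    cols_a = [s for s in values.columns if condition[s] == ga]
    cols_b = [s for s in values.columns if condition[s] == gb]

    rows = []
    skipped: list[str] = []
    for gene in values.index:
        a = values.loc[gene, cols_a].dropna().to_numpy(dtype=float)
        b = values.loc[gene, cols_b].dropna().to_numpy(dtype=float)
        if len(a) < 3 or len(b) < 3:
            skipped.append(gene)
            logger.warning(
                "gene %s skipped: group sizes %d/%d below 3", gene, len(a), len(b)
            )
            continue
        if welch:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(t), float(p)
        else:
            t, p = _t_pooled(a, b)
        sw_a = float(stats.shapiro(a).pvalue) if a.std(ddof=1) > 0 else float("nan")
        sw_b = float(stats.shapiro(b).pvalue) if b.std(ddof=1) > 0 else float("nan")
        rows.append(
            {
                "gene": gene,
                f"n_{ga}": len(a),
                f"n_{gb}": len(b),
                f"mean_{ga}": float(a.mean()),
                f"mean_{gb}": float(b.mean()),
                f"sem_{ga}": float(a.std(ddof=1) / np.sqrt(len(a))),
                f"sem_{gb}": float(b.std(ddof=1) / np.sqrt(len(b))),
                f"shapiro_p_{ga}": sw_a,
                f"shapiro_p_{gb}": sw_b,
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        if adjust:
            table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
            table["significant"] = table["p_adj"] <= alpha
        else:
            table["significant"] = table["p"] <= alpha
    return GroupComparison(table, scale, skipped)


def percent_of_control(treated_mean: float, control_mean: float) -> tuple[float, int]:
    """Treated level as a percentage of control.

    Returns ``(exact, rounded)`` — the unrounded percentage and its
    nearest-integer display form.
    """
    if control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    exact = 100.0 * treated_mean / control_mean
    return exact, int(round(exact))
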