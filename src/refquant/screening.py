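"""Expression-level screening of qPCR assays.

Nanoliter-volume chips quantify reliably only genes whose amplification
curve crosses the detection threshold early: an assay is *highly
expressed* when its central Ct falls before cycle 28, *lowly expressed*
between cycles 28 and 34 (inclusive), and *undetected* beyond cycle 34
or when too few wells amplified at all.  Lowly expressed genes are
normally excluded from downstream fold-change analysis unless the cDNA
is preamplified.

The per-assay decision is made on the arithmetic mean Ct of the detected
wells of one basis condition (default: the control group), which yields
a single deterministic class per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CtMatrix

__all__ = ["ExpressionClass", "classify_genes", "filter_by_class", "CLASSES"]

CLASSES = ("high", "low", "undetected")

DEFAULT_THRESHOLDS = (28.0, 34.0)
DEFAULT_MIN_DETECTED = 3


@dataclass
class ExpressionClass:
    """Per-assay expression class with the summary Ct it was based on."""

    classes: pd.Series  # assay -> {"high","low","undetected"}
    summary_ct: pd.Series  # assay -> mean detected Ct (NaN if none)
    thresholds: tuple[float, float]
    basis_condition: str

    def counts(self) -> dict[str, int]:
        """Number of assays per class, in fixed class order."""
        vc = self.classes.value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}


def classify_genes(
    ct: CtMatrix,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    basis_condition: str = "control",
    min_detected: int = DEFAULT_MIN_DETECTED,
) -> ExpressionClass:
    """Assign each assay an expression class from its mean basis-group Ct.

    high:       summary Ct < thresholds[0]
    low:        thresholds[0] <= summary Ct <= thresholds[1]
    undetected: summary Ct > thresholds[1], or fewer than ``min_detected``
                detected wells in the basis condition.
    """
    high_max, low_max = thresholds
    if not high_max < low_max:
        raise ValueError(f"thresholds must increase, got {thresholds}")
    if min_detected < 1:
        raise ValueError("min_detected must be >= 1")
    if ct.ct.empty:
        raise ValueError("empty Ct matrix")
    if basis_condition not in set(ct.condition):
        raise ValueError(
            f"basis condition {basis_condition!r} not in matrix "
            f"(have {sorted(set(ct.condition))})"
        )
    basis = ct.ct[ct.samples_of(basis_condition)]
    n_detected = basis.notna().sum(axis=1)
    summary = basis.mean(axis=1, skipna=True)

    labels = []
    for assay in basis.index:
        if n_detected[assay] < min_detected or np.isnan(summary[assay]):
            labels.append("undetected")
        elif summary[assay] < high_max:
            labels.append("high")
        elif summary[assay] <= low_max:
            labels.append("low")
        else:
            labels.append("undetected")
    classes = pd.Series(labels, index=basis.index, name="class")
    return ExpressionClass(classes, summary.rename("summary_ct"),
                           (float(high_max), float(low_max)), basis_condition)


def filter_by_class(
    ct: CtMatrix,
    classes: ExpressionClass,
    keep: set[str] | frozenset[str] = frozenset({"high"}),
) -> CtMatrix:
    """Restrict the matrix to assays whose class is in ``keep``."""
    if not keep:
        raise ValueError("keep must name at least one class")
    unknown = set(keep) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in keep: {sorted(unknown)}")
    missing = [a for a in ct.assay_ids if a not in classes.classes.index]
    if missing:
        raise ValueError(f"assays without a class: {missing[:5]}")
    keep_assays = [a for a in ct.assay_ids if classes.classes[a] in keep]
    return ct.restrict(assays=keep_assays)


def screen_report(panel_clusters: pd.Series, classes: ExpressionClass) -> pd.DataFrame:
    """Tabular screen outcome: symbol, cluster, class, summary_ct."""
    rows = []
    for assay in classes.classes.index:
        rows.append(
            {
                "symbol": assay,
                "cluster": panel_clusters.get(assay, ""),
                "class": classes.classes[assay],
                "summary_ct": classes.summary_ct[assay],
            }
        )
    return pd.DataFrame(rows)
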