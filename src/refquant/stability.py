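"""Reference-gene stability statistics and their rank aggregation.

Four established algorithms score each candidate housekeeping gene on a
one-condition Ct matrix (lower score = more stable expression):

* **comparative ΔCt** — mean, over all partner genes, of the sample SD
  of the pairwise Ct difference;
* **BestKeeper** — sample SD of the gene's raw Ct (plus a CV%); the only
  one of the four sensitive to per-sample loading offsets, by design;
* **NormFinder** (single-group variant) — model-based estimate of the
  gene's own variance after removing the shared per-sample component,
  via a two-way additive decomposition with heteroscedastic errors;
* **geNorm** — the M-value (identical to the comparative ΔCt score on
  the full set) with iterative exclusion of the least stable gene, plus
  the pairwise-variation series V_k of log2 normalization factors.

Per-method scores become ordinal ranks (ties broken by panel order);
the *comprehensive* score of a gene is the geometric mean of its four
ranks, and the cross-condition *summary* score is the sum of its
comprehensive scores over the two experimental conditions.  The gene
with the minimal summary score is selected as the reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import CtMatrix

__all__ = [
    "METHODS",
    "GenormResult",
    "StabilityTable",
    "SummaryRanking",
    "delta_ct_stability",
    "bestkeeper_stability",
    "normfinder_stability",
    "genorm_stability",
    "rank_scores",
    "comprehensive_ranking",
    "stability_table",
    "summary_score",
]

METHODS = ("delta_ct", "bestkeeper", "normfinder", "genorm")


def _candidate_frame(ct: CtMatrix | pd.DataFrame, min_genes: int = 2) -> pd.DataFrame:
    """Validate a one-condition candidate matrix; return genes x samples."""
    frame = ct.ct if isinstance(ct, CtMatrix) else ct
    frame = frame.astype(float)
    if len(frame.index) < min_genes:
        raise ValueError(f"need at least {min_genes} candidate genes, have {len(frame.index)}")
    if len(frame.columns) < 3:
        raise ValueError(f"need at least 3 samples, have {len(frame.columns)}")
    if frame.isna().any().any():
        bad = [
            (g, s)
            for g in frame.index
            for s in frame.columns
            if pd.isna(frame.at[g, s])
        ]
        raise ValueError(
            "undetermined Ct among stability candidates "
            f"(first: {bad[:3]}); exclude or handle these genes upstream"
        )
    return frame


def _sd(x: np.ndarray) -> float:
    """Sample standard deviation (n-1 divisor)."""
    return float(np.std(x, ddof=1))


# ---------------------------------------------------------------------------
# The four stability statistics
# ---------------------------------------------------------------------------


def delta_ct_stability(ct: CtMatrix | pd.DataFrame) -> pd.Series:
    """Comparative-ΔCt stability: mean pairwise-difference SD per gene."""
    frame = _candidate_frame(ct)
    genes = list(frame.index)
    vals = frame.to_numpy()
    scores = []
    for i in range(len(genes)):
        sds = [
            _sd(vals[i] - vals[j]) for j in range(len(genes)) if j != i
        ]
        scores.append(float(np.mean(sds)))
    return pd.Series(scores, index=genes, name="delta_ct")


def bestkeeper_stability(ct: CtMatrix | pd.DataFrame) -> pd.DataFrame:
    """BestKeeper stability: raw-Ct sample SD (score) and CV% per gene."""
    frame = _candidate_frame(ct)
    sd = frame.std(axis=1, ddof=1)
    cv = 100.0 * sd / frame.mean(axis=1)
    return pd.DataFrame({"score": sd, "cv": cv})


def normfinder_stability(ct: CtMatrix | pd.DataFrame) -> pd.Series:
    """Single-group NormFinder stability value per gene.

    Model: Ct_ij = a_i + b_j + e_ij with Var(e_ij) = s_i^2.  Residuals of
    the two-way additive fit give naive per-gene variances v_i whose
    expectations mix s_i^2 with the other genes'; the moment correction

        s_i^2 = k/(k-2) * (v_i - sum(v)/(k*(k-1)))

    (k genes) unmixes them.  The score is sqrt(max(0, s_i^2)).
    """
    frame = _candidate_frame(ct, min_genes=3)
    x = frame.to_numpy()
    k, n = x.shape
    resid = (
        x
        - x.mean(axis=1, keepdims=True)
        - x.mean(axis=0, keepdims=True)
        + x.mean()
    )
    v = (resid**2).sum(axis=1) / (n - 1)
    sigma2 = (k / (k - 2)) * (v - v.sum() / (k * (k - 1)))
    score = np.sqrt(np.maximum(0.0, sigma2))
    return pd.Series(score, index=frame.index, name="normfinder")


@dataclass
class GenormResult:
    """geNorm output: reported M, exclusion-order rank, V_k series."""

    m: pd.Series  # gene -> M at its removal iteration
    exclusion_rank: pd.Series  # gene -> 1 (most stable) .. n
    pairwise_variation: pd.Series  # k -> V_k, k = 2 .. n-1
    first_pass_m: pd.Series | None = None  # M on the full gene set


def genorm_stability(
    ct: CtMatrix | pd.DataFrame,
    panel_order: Sequence[str] | None = None,
) -> GenormResult:
    """geNorm M-values with iterative worst-gene exclusion.

    At each step the gene with the largest M on the current set is
    removed (ties: the gene later in panel order goes first) until two
    genes remain; those two share the M of their final 2-gene set and
    are ordered by panel order.  V_k is the sample SD of the difference
    of log2 normalization factors built from the k and k+1 most stable
    genes (normalization factor of a sample = mean centered Ct of the
    included genes).
    """
    frame = _candidate_frame(ct, min_genes=3)
    genes = list(frame.index)
    order = list(panel_order) if panel_order is not None else genes
    pos = {g: order.index(g) for g in genes}

    def m_values(sub: list[str]) -> pd.Series:
        vals = frame.loc[sub].to_numpy()
        out = []
        for i in range(len(sub)):
            out.append(
                float(
                    np.mean(
                        [_sd(vals[i] - vals[j]) for j in range(len(sub)) if j != i]
                    )
                )
            )
        return pd.Series(out, index=sub)

    first_pass = m_values(genes)
    reported_m: dict[str, float] = {}
    removal_order: list[str] = []  # first removed (least stable) first
    current = list(genes)
    while len(current) > 2:
        m = m_values(current)
        worst_score = m.max()
        tied = [g for g in current if m[g] == worst_score]
        worst = max(tied, key=lambda g: pos[g])
        reported_m[worst] = float(m[worst])
        removal_order.append(worst)
        current.remove(worst)
    final_m = m_values(current)
    final_pair = sorted(current, key=lambda g: pos[g])
    for g in final_pair:
        reported_m[g] = float(final_m[g])

    ranked = final_pair + list(reversed(removal_order))  # most stable first
    exclusion_rank = pd.Series(
        {g: i + 1 for i, g in enumerate(ranked)}, name="genorm_rank"
    ).reindex(genes)

    # pairwise variation V_k over genes added in stability order
    centered = frame.sub(frame.mean(axis=1), axis=0)
    v_k = {}
    for k in range(2, len(genes)):
        nf_k = centered.loc[ranked[:k]].mean(axis=0)
        nf_k1 = centered.loc[ranked[: k + 1]].mean(axis=0)
        v_k[k] = _sd((nf_k - nf_k1).to_numpy())
    return GenormResult(
        m=pd.Series(reported_m, name="genorm").reindex(genes),
        exclusion_rank=exclusion_rank.astype(int),
        pairwise_variation=pd.Series(v_k, name="V"),
        first_pass_m=first_pass.rename("M"),
    )


# ---------------------------------------------------------------------------
# Rank aggregation
# ---------------------------------------------------------------------------


def rank_scores(
    scores: pd.Series | Mapping[str, float],
    panel_order: Sequence[str] | None = None,
) -> pd.Series:
    """Ordinal ranks (1 = most stable); full-precision ties broken by
    panel order."""
    s = pd.Series(scores, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        bad = [g for g in s.index if not np.isfinite(s[g])]
        raise ValueError(f"non-finite stability scores for: {bad}")
    order = list(panel_order) if panel_order is not None else list(s.index)
    pos = {g: order.index(g) for g in s.index}
    ordered = sorted(s.index, key=lambda g: (s[g], pos[g]))
    return pd.Series(
        {g: i + 1 for i, g in enumerate(ordered)}, name="rank"
    ).reindex(s.index).astype(int)


def comprehensive_ranking(ranks: pd.DataFrame) -> pd.Series:
    """Geometric mean of each gene's per-method rank positions.

    ``ranks`` holds one column per method; every gene must carry all
    four ranks.  Result is unrounded (display precision is 2 d.p.).
    """
    missing_cols = [m for m in METHODS if m not in ranks.columns]
    if missing_cols:
        raise ValueError(f"missing method ranks: {missing_cols}")
    sub = ranks[list(METHODS)]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"genes with missing ranks: {bad}")
    vals = sub.to_numpy(dtype=float)
    comp = np.exp(np.log(vals).mean(axis=1))
    return pd.Series(comp, index=ranks.index, name="comprehensive")


@dataclass
class StabilityTable:
    """Per-gene stability scores, ranks, and comprehensive score for one
    condition.  ``table`` is indexed by gene in panel order."""

    table: pd.DataFrame
    condition: str
    pairwise_variation: pd.Series

    def ranks(self) -> pd.DataFrame:
        return self.table[[f"{m}_rank" for m in METHODS]].rename(
            columns={f"{m}_rank": m for m in METHODS}
        )


def stability_table(
    ct: CtMatrix,
    condition: str,
    candidates: Sequence[str] | None = None,
    panel_order: Sequence[str] | None = None,
) -> StabilityTable:
    """Run all four methods on one condition and aggregate the ranks."""
    if candidates is None:
        candidates = ct.assay_ids
    sub = ct.restrict(assays=candidates, condition=condition)
    frame = sub.ct
    order = list(panel_order) if panel_order is not None else list(candidates)

    dct = delta_ct_stability(frame)
    bk = bestkeeper_stability(frame)
    nf = normfinder_stability(frame)
    gn = genorm_stability(frame, panel_order=order)

    table = pd.DataFrame(index=frame.index)
    table["delta_ct_score"] = dct
    table["delta_ct_rank"] = rank_scores(dct, order)
    table["bestkeeper_score"] = bk["score"]
    table["bestkeeper_cv"] = bk["cv"]
    table["bestkeeper_rank"] = rank_scores(bk["score"], order)
    table["normfinder_score"] = nf
    table["normfinder_rank"] = rank_scores(nf, order)
    table["genorm_score"] = gn.m
    table["genorm_rank"] = gn.exclusion_rank
    table["comprehensive"] = comprehensive_ranking(
        table[[f"{m}_rank" for m in METHODS]].rename(
            columns={f"{m}_rank": m for m in METHODS}
        )
    )
    return StabilityTable(table, condition, gn.pairwise_variation)


@dataclass
class SummaryRanking:
    """Cross-condition summary: per-gene sum of comprehensive scores and
    the selected reference gene (minimal summary; ties by panel order)."""

    table: pd.DataFrame
    selected_reference: str


def summary_score(
    comp_control: pd.Series | StabilityTable,
    comp_treated: pd.Series | StabilityTable,
    panel_order: Sequence[str] | None = None,
) -> SummaryRanking:
    """Sum per-condition comprehensive scores; pick the reference gene."""
    a = (
        comp_control.table["comprehensive"]
        if isinstance(comp_control, StabilityTable)
        else pd.Series(comp_control, dtype=float)
    )
    b = (
        comp_treated.table["comprehensive"]
        if isinstance(comp_treated, StabilityTable)
        else pd.Series(comp_treated, dtype=float)
    )
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(
            f"gene sets differ between conditions: only in first {only_a}, "
            f"only in second {only_b}"
        )
    b = b.reindex(a.index)
    summary = a + b
    order = list(panel_order) if panel_order is not None else list(a.index)
    pos = {g: order.index(g) for g in a.index}
    selected = min(a.index, key=lambda g: (summary[g], pos[g]))
    table = pd.DataFrame(
        {
            "comprehensive_control": a,
            "comprehensive_treated": b,
            "summary": summary,
        }
    ).sort_values("summary", kind="stable")
    return SummaryRanking(table, selected)
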