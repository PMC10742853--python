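"""Reading and writing Ct matrices and gene-panel definitions.

A Ct (cycle-threshold) matrix holds one cycle value per (assay, sample)
well of a high-throughput RT-qPCR chip, together with a per-sample
condition label.  Wells whose amplification curve never crossed the
detection threshold are recorded as "undetermined" and represented
internally as NaN.  Two plain-text layouts are supported:

* ``wide``  — one row per assay, one column per sample, plus a
  ``condition`` header row mapping each sample to its group;
* ``long``  — tidy table with columns ``assay, sample, condition, ct``.

Files are comma- or tab-delimited, auto-detected from the ``.csv`` /
``.tsv`` extension.  Decimal separator is always the dot.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "GenePanel",
    "PanelError",
    "CtTableError",
    "DEFAULT_UNDETERMINED_TOKENS",
    "DEFAULT_MAX_CYCLE",
    "CLUSTER_NAMES",
    "HOUSEKEEPING_CLUSTER",
    "read_ct_table",
    "write_ct_table",
    "read_panel",
    "load_default_panel",
    "default_panel_classes",
]

#: Tokens in a Ct cell that mean "no amplification detected".
DEFAULT_UNDETERMINED_TOKENS = frozenset({"Undetermined", "NA", ""})

#: Detection ceiling of the chip, in cycles.
DEFAULT_MAX_CYCLE = 34.0

#: The eight functional clusters of the target panel.
CLUSTER_NAMES = (
    "Synthesis and degradation of dopamine",
    "Dopamine transport, dopamine receptors, and transcription factors "
    "of dopaminergic neurons",
    "Axonal transport",
    "Vesicular cycle and mediator release",
    "Neuroprotection",
    "Protein degradation",
    "Cell death",
    "Inflammation and glia activation",
)

#: Cluster label reserved for reference-gene candidates.
HOUSEKEEPING_CLUSTER = "Housekeeping"

_VALID_CLUSTERS = frozenset(CLUSTER_NAMES) | {HOUSEKEEPING_CLUSTER}
_VALID_ROLES = frozenset({"target", "housekeeping"})


class CtTableError(ValueError):
    """Malformed Ct table (duplicate wells, bad numbers, label conflicts)."""


class PanelError(ValueError):
    """Malformed gene-panel definition."""


@dataclass
class CtMatrix:
    """Cycle-threshold values for a set of assays over labelled samples.

    Parameters
    ----------
    ct
        ``assays x samples`` float frame; NaN marks an undetermined well.
    condition
        Per-sample group label, indexed like ``ct.columns``.
    max_cycle
        Detection ceiling in cycles.  Values above it are kept verbatim
        (downstream screening flags them); nothing is clamped.
    """

    ct: pd.DataFrame
    condition: pd.Series
    max_cycle: float = DEFAULT_MAX_CYCLE

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        if self.ct.index.has_duplicates:
            dupes = self.ct.index[self.ct.index.duplicated()].tolist()
            raise CtTableError(f"duplicate assay ids: {dupes}")
        if self.ct.columns.has_duplicates:
            dupes = self.ct.columns[self.ct.columns.duplicated()].tolist()
            raise CtTableError(f"duplicate sample ids: {dupes}")
        self.condition = self.condition.reindex(self.ct.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise CtTableError(f"samples without a condition label: {missing}")
        vals = self.ct.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite <= 0) | (finite > 45)).any():
            raise CtTableError("Ct values must lie in (0, 45] cycles")

    # -- convenience accessors -------------------------------------------------

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        if condition not in set(self.condition):
            raise KeyError(f"condition {condition!r} not present")
        return [s for s in self.ct.columns if self.condition[s] == condition]

    def restrict(
        self,
        assays: Sequence[str] | None = None,
        condition: str | None = None,
    ) -> "CtMatrix":
        """Sub-matrix over the given assays and/or one condition."""
        ct = self.ct
        if assays is not None:
            missing = [a for a in assays if a not in ct.index]
            if missing:
                raise KeyError(f"assays not in matrix: {missing}")
            ct = ct.loc[list(assays)]
        cond = self.condition
        if condition is not None:
            keep = self.samples_of(condition)
            ct = ct[keep]
            cond = cond[keep]
        return CtMatrix(ct.copy(), cond.copy(), self.max_cycle)

    def n_undetermined(self) -> int:
        return int(self.ct.isna().to_numpy().sum())


@dataclass
class GenePanel:
    """Assay panel: gene symbols with functional cluster and role.

    ``entries`` has columns ``symbol``, ``cluster``, ``role`` (role in
    {target, housekeeping}); symbol order defines the panel order used
    for deterministic tie-breaking throughout the pipeline.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["symbol", "cluster", "role"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise PanelError(f"panel missing columns: {missing}")
        if self.entries["symbol"].duplicated().any():
            d = self.entries.loc[self.entries["symbol"].duplicated(), "symbol"]
            raise PanelError(f"duplicate symbols in panel: {sorted(set(d))}")
        bad_role = set(self.entries["role"]) - _VALID_ROLES
        if bad_role:
            raise PanelError(f"unknown roles: {sorted(bad_role)}")
        bad_cluster = set(self.entries["cluster"]) - _VALID_CLUSTERS
        if bad_cluster:
            raise PanelError(f"unknown clusters: {sorted(bad_cluster)}")
        self.entries = self.entries.reset_index(drop=True)

    @property
    def symbols(self) -> list[str]:
        return list(self.entries["symbol"])

    @property
    def targets(self) -> list[str]:
        e = self.entries
        return list(e.loc[e["role"] == "target", "symbol"])

    @property
    def housekeeping(self) -> list[str]:
        e = self.entries
        return list(e.loc[e["role"] == "housekeeping", "symbol"])

    def cluster_of(self, symbol: str) -> str:
        e = self.entries.set_index("symbol")
        return str(e.loc[symbol, "cluster"])

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Ct table reading / writing
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _parse_ct_cell(
    raw: object,
    undetermined_tokens: frozenset[str] | set[str],
    where: str,
) -> float:
    """One cell -> float Ct or NaN; anything else is a hard error."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return float("nan")
    text = str(raw).strip()
    if text in undetermined_tokens:
        return float("nan")
    try:
        return float(text)
    except ValueError:
        raise CtTableError(
            f"non-numeric Ct value {text!r} at {where}"
        ) from None


def read_ct_table(
    path: str | Path,
    layout: str = "wide",
    undetermined_tokens: Iterable[str] = DEFAULT_UNDETERMINED_TOKENS,
    max_cycle: float = DEFAULT_MAX_CYCLE,
) -> CtMatrix:
    """Read a Ct matrix from a delimited text file.

    ``wide`` layout: first column holds assay ids (header ``assay``), one
    column per sample, and a mandatory first data row labelled
    ``condition`` giving each sample's group.  ``long`` layout: columns
    ``assay, sample, condition, ct`` in any row order.
    """
    tokens = frozenset(str(t) for t in undetermined_tokens)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    if layout == "wide":
        return _read_wide(path, sep, tokens, max_cycle)
    if layout == "long":
        return _read_long(path, sep, tokens, max_cycle)
    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def _read_wide(
    path: Path, sep: str, tokens: frozenset[str], max_cycle: float
) -> CtMatrix:
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    first = raw.columns[0]
    if raw.empty:
        raise CtTableError(f"{path}: empty table")
    cond_rows = raw[raw[first] == "condition"]
    if len(cond_rows) != 1:
        raise CtTableError(
            f"{path}: wide layout needs exactly one 'condition' row, "
            f"found {len(cond_rows)}"
        )
    condition = cond_rows.iloc[0].drop(first)
    body = raw[raw[first] != "condition"]
    assays = body[first].tolist()
    if len(set(assays)) != len(assays):
        dupes = sorted({a for a in assays if assays.count(a) > 1})
        raise CtTableError(f"{path}: duplicate assay rows: {dupes}")
    samples = [c for c in raw.columns if c != first]
    data = np.empty((len(assays), len(samples)))
    for i, (_, row) in enumerate(body.iterrows()):
        for j, s in enumerate(samples):
            data[i, j] = _parse_ct_cell(
                row[s], tokens, f"assay {assays[i]!r}, sample {s!r}"
            )
    ct = pd.DataFrame(data, index=assays, columns=samples)
    cond = pd.Series(condition.values, index=samples, dtype=object)
    return CtMatrix(ct, cond, max_cycle)


def _read_long(
    path: Path, sep: str, tokens: frozenset[str], max_cycle: float
) -> CtMatrix:
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = ["assay", "sample", "condition", "ct"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise CtTableError(f"{path}: long layout missing columns {missing}")
    seen: dict[tuple[str, str], float] = {}
    cond_map: dict[str, str] = {}
    assay_order: dict[str, None] = {}
    sample_order: dict[str, None] = {}
    for _, row in raw.iterrows():
        key = (row["assay"], row["sample"])
        if key in seen:
            raise CtTableError(
                f"{path}: duplicate cell for assay {key[0]!r}, "
                f"sample {key[1]!r}"
            )
        seen[key] = _parse_ct_cell(
            row["ct"], tokens, f"assay {key[0]!r}, sample {key[1]!r}"
        )
        prev = cond_map.get(row["sample"])
        if prev is not None and prev != row["condition"]:
            raise CtTableError(
                f"{path}: sample {row['sample']!r} labelled both "
                f"{prev!r} and {row['condition']!r}"
            )
        cond_map[row["sample"]] = row["condition"]
        assay_order.setdefault(row["assay"])
        sample_order.setdefault(row["sample"])
    assays = list(assay_order)
    samples = list(sample_order)
    data = np.full((len(assays), len(samples)), np.nan)
    for (a, s), v in seen.items():
        data[assays.index(a), samples.index(s)] = v
    incomplete = [
        (a, s)
        for a in assays
        for s in samples
        if (a, s) not in seen
    ]
    if incomplete:
        raise CtTableError(f"{path}: missing cells {incomplete[:5]}")
    ct = pd.DataFrame(data, index=assays, columns=samples)
    cond = pd.Series([cond_map[s] for s in samples], index=samples, dtype=object)
    return CtMatrix(ct, cond, max_cycle)


def write_ct_table(
    matrix: CtMatrix,
    path: str | Path,
    layout: str = "wide",
    undetermined_token: str = "Undetermined",
) -> None:
    """Write a Ct matrix back out in either supported layout.

    Numbers are written with :func:`repr` precision so a read-back
    reproduces the matrix bit-exactly.
    """
    path = Path(path)
    sep = _sep_for(path)

    def fmt(v: float) -> str:
        return undetermined_token if math.isnan(v) else repr(float(v))

    if layout == "wide":
        lines = [sep.join(["assay"] + matrix.sample_ids)]
        lines.append(
            sep.join(["condition"] + [str(matrix.condition[s]) for s in matrix.sample_ids])
        )
        for a in matrix.assay_ids:
            lines.append(
                sep.join([a] + [fmt(matrix.ct.at[a, s]) for s in matrix.sample_ids])
            )
    elif layout == "long":
        lines = [sep.join(["assay", "sample", "condition", "ct"])]
        for a in matrix.assay_ids:
            for s in matrix.sample_ids:
                lines.append(
                    sep.join([a, s, str(matrix.condition[s]), fmt(matrix.ct.at[a, s])])
                )
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------


def read_panel(path: str | Path) -> GenePanel:
    """Read a panel definition (columns symbol, cluster, role) from text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return GenePanel(df[["symbol", "cluster", "role"]].copy())


def _default_panel_frame() -> pd.DataFrame:
    df = pd.read_csv(
        io.StringIO(DEFAULT_PANEL_CSV), dtype=str, keep_default_na=False
    )
    return df


def load_default_panel() -> GenePanel:
    """The packaged 112-assay study panel: 101 targets in eight functional
    clusters plus 11 housekeeping candidates."""
    return GenePanel(_default_panel_frame()[["symbol", "cluster", "role"]])


def default_panel_classes() -> pd.Series:
    """Published expression class (high/low/undetected) per panel gene.

    Transcription of the chip screen outcome: 57 targets highly
    expressed, 22 lowly expressed, 22 undetectable; housekeeping
    candidates are all highly expressed.
    """
    df = _default_panel_frame()
    return pd.Series(df["class"].values, index=df["symbol"].values, name="class")


# 112-assay panel: symbol, functional cluster, role, published expression
# class.  Cluster 1-8 names follow the study's grouping; housekeeping
# candidates carry their own cluster label.
_C1 = CLUSTER_NAMES[0]
_C2 = CLUSTER_NAMES[1]
_C3 = CLUSTER_NAMES[2]
_C4 = CLUSTER_NAMES[3]
_C5 = CLUSTER_NAMES[4]
_C6 = CLUSTER_NAMES[5]
_C7 = CLUSTER_NAMES[6]
_C8 = CLUSTER_NAMES[7]

_PANEL_ROWS: list[tuple[str, str, str, str]] = [
    # -- Synthesis and degradation of dopamine
    ("Th", _C1, "target", "high"),
    ("Ddc", _C1, "target", "high"),
    ("Comt", _C1, "target", "high"),
    ("Maoa", _C1, "target", "high"),
    ("Maob", _C1, "target", "high"),
    ("Dbh", _C1, "target", "undetected"),
    ("Pnmt", _C1, "target", "undetected"),
    # -- Dopamine transport, receptors, transcription factors
    ("Slc18a2", _C2, "target", "high"),
    ("Slc6a3", _C2, "target", "high"),
    ("Drd2", _C2, "target", "high"),
    ("Nr4a2", _C2, "target", "high"),
    ("Slc29a4", _C2, "target", "low"),
    ("Drd1", _C2, "target", "low"),
    ("Drd3", _C2, "target", "undetected"),
    ("Drd4", _C2, "target", "undetected"),
    ("Drd5", _C2, "target", "undetected"),
    ("Slc18a1", _C2, "target", "undetected"),
    ("Pitx3", _C2, "target", "undetected"),
    # -- Axonal transport
    ("Tubb3", _C3, "target", "high"),
    ("Tuba1a", _C3, "target", "high"),
    ("Dynll1", _C3, "target", "high"),
    ("Kif1a", _C3, "target", "high"),
    ("Kif5a", _C3, "target", "high"),
    ("Dctn1", _C3, "target", "high"),
    ("Map2", _C3, "target", "high"),
    ("Mapt", _C3, "target", "high"),
    ("Kif1b", _C3, "target", "low"),
    ("Dync1h1", _C3, "target", "low"),
    ("Mark2", _C3, "target", "low"),
    ("Kif2c", _C3, "target", "undetected"),
    # -- Vesicular cycle and mediator release
    ("Syn1", _C4, "target", "high"),
    ("Syt1", _C4, "target", "high"),
    ("Snca", _C4, "target", "high"),
    ("Syt11", _C4, "target", "high"),
    ("Rab5a", _C4, "target", "high"),
    ("Rab7", _C4, "target", "high"),
    ("Dnm1l", _C4, "target", "high"),
    ("Vps35", _C4, "target", "high"),
    ("Nsf", _C4, "target", "high"),
    ("Stx1a", _C4, "target", "low"),
    # -- Neuroprotection
    ("Gpx1", _C5, "target", "high"),
    ("Gsr", _C5, "target", "high"),
    ("Sod1", _C5, "target", "high"),
    ("Prdx1", _C5, "target", "high"),
    ("Txnrd1", _C5, "target", "high"),
    ("Nfe2l2", _C5, "target", "high"),
    ("Keap1", _C5, "target", "high"),
    ("Sigmar1", _C5, "target", "high"),
    ("Calb1", _C5, "target", "high"),
    ("Ctnnb1", _C5, "target", "high"),
    ("Ntrk2", _C5, "target", "high"),
    ("Bdnf", _C5, "target", "low"),
    ("Vegfa", _C5, "target", "low"),
    ("Nos1", _C5, "target", "low"),
    ("Agtr2", _C5, "target", "low"),
    ("Ngf", _C5, "target", "undetected"),
    ("Gdnf", _C5, "target", "undetected"),
    ("Cdnf", _C5, "target", "undetected"),
    ("Ntrk1", _C5, "target", "undetected"),
    ("Mmp3", _C5, "target", "undetected"),
    ("Wnt11", _C5, "target", "undetected"),
    ("Ngfr", _C5, "target", "undetected"),
    # -- Protein degradation
    ("Ubb", _C6, "target", "high"),
    ("Uba3", _C6, "target", "high"),
    ("Ube2n", _C6, "target", "high"),
    ("Psmb4", _C6, "target", "high"),
    ("Psmd4", _C6, "target", "high"),
    ("Psmc3", _C6, "target", "high"),
    ("Usp47", _C6, "target", "high"),
    ("Ctsb", _C6, "target", "high"),
    ("Park2", _C6, "target", "low"),
    ("Cacna1d", _C6, "target", "low"),
    ("Trpm2", _C6, "target", "low"),
    # -- Cell death
    ("Parp1", _C7, "target", "high"),
    ("Cib1", _C7, "target", "high"),
    ("Aifm1", _C7, "target", "high"),
    ("Bax", _C7, "target", "high"),
    ("Trp53", _C7, "target", "high"),
    ("Lamp2", _C7, "target", "high"),
    ("Mapk8", _C7, "target", "high"),
    ("Atg5", _C7, "target", "high"),
    ("Casp1", _C7, "target", "low"),
    ("Casp3", _C7, "target", "low"),
    ("Map3k5", _C7, "target", "low"),
    ("Fos", _C7, "target", "low"),
    ("Capn1", _C7, "target", "low"),
    ("Eif2ak3", _C7, "target", "low"),
    ("Atf6", _C7, "target", "low"),
    ("Atg16l1", _C7, "target", "low"),
    ("Tnf", _C7, "target", "undetected"),
    ("Bcl2l11", _C7, "target", "undetected"),
    ("Ern2", _C7, "target", "undetected"),
    # -- Inflammation and glia activation
    ("Gfap", _C8, "target", "high"),
    ("Clk1", _C8, "target", "high"),
    ("Akt1", _C8, "target", "high"),
    ("Cnr1", _C8, "target", "high"),
    ("Tgfb1", _C8, "target", "low"),
    ("Ifng", _C8, "target", "undetected"),
    ("Cxcl11", _C8, "target", "undetected"),
    ("Ptgs2", _C8, "target", "undetected"),
    ("Traf1", _C8, "target", "undetected"),
    # -- Housekeeping candidates
    ("Xpnpep1", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Aars", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Gapvd1", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Osbp", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Gapdh", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Sdha", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Rps27a", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Ube2d2a", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Cyc1", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Rpl13", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
    ("Hprt", HOUSEKEEPING_CLUSTER, "housekeeping", "high"),
]

DEFAULT_PANEL_CSV = "symbol,cluster,role,class\n" + "\n".join(
    ",".join((s, f'"{c}"', r, k)) for s, c, r, k in _PANEL_ROWS
)
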