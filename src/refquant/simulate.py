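"""Synthetic Ct-matrix generator with planted ground truth.

Emulates the study design the pipeline targets: a 112-assay chip run on
two groups of 8 animals, with

* per-gene baseline Ct ``b_g`` placed inside the intended expression
  class (high / low / undetectable);
* a shared per-sample loading offset ``alpha_s ~ N(0, 0.5)`` — exactly
  the artifact ΔCt-type stability statistics must tolerate and
  BestKeeper must be sensitive to;
* a planted expression log2 fold change ``f_g`` (treated vs control);
  an expression change of +f shifts Ct by −f cycles in treated samples;
* Gaussian per-well noise with gene-specific SD ``sigma_g``;
* right-censoring: wells beyond the detection ceiling (34 cycles) are
  emitted as undetermined.

The Ct model is ``Ct_gs = b_g + alpha_s - f_g*[s treated] + eps_gs``.
Among the 11 housekeeping candidates one gene (Rps27a's panel slot) is
planted as the stable reference: minimal noise and no condition effect;
the others carry larger noise or a condition shift.

:func:`make_published_rank_fixture` is unrelated to simulation: it transcribes
the published per-method stability rank positions of the 11 candidates
in both conditions, for testing the rank-aggregation layer against the
printed comprehensive and summary scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import CtMatrix, default_panel_classes, load_default_panel

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_experiment",
    "make_published_rank_fixture",
    "DEFAULT_EFFECT_GENES",
]

#: Target genes carrying the planted expression decrease by default —
#: the 20 genes the study reported as downregulated.
DEFAULT_EFFECT_GENES = (
    "Th", "Ddc", "Maoa", "Comt", "Slc6a3", "Slc18a2", "Drd2", "Nr4a2",
    "Tubb3", "Map2", "Syn1", "Syt1", "Rab7", "Sod1", "Cib1", "Gpx1",
    "Psmd4", "Ubb", "Usp47", "Ctsb",
)

#: Housekeeping candidates given a condition shift instead of (only)
#: extra noise, to make them unstable across conditions.
_SHIFTED_HKGS = {"Gapdh": -0.6, "Osbp": 0.8, "Gapvd1": 0.5}

#: Baseline-Ct windows per planted expression class (cycles).  Chosen so
#: that, at the default noise levels, the mean control Ct of a gene lands
#: inside its class interval with large margin.
_CLASS_WINDOWS = {"high": (20.0, 26.5), "low": (29.0, 33.0), "undetected": (36.0, 40.0)}


@dataclass
class SimulationConfig:
    """Tunable parameters of the synthetic experiment (defaults = the
    emulated study design)."""

    n_per_group: int = 8
    control_label: str = "control"
    treated_label: str = "treated"
    loading_sd: float = 0.5  # SD of per-sample offsets, cycles
    target_sigma: float = 0.3  # per-well noise SD of target genes, cycles
    stable_hkg: str = "Rps27a"
    stable_sigma: float = 0.15
    hkg_sigma_range: tuple[float, float] = (0.3, 1.0)
    shifted_hkg_sigma: float = 0.5
    effect_genes: tuple[str, ...] = DEFAULT_EFFECT_GENES
    effect_log2fc: float = -1.0  # expression halved in treated
    max_cycle: float = 34.0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.loading_sd < 0 or self.target_sigma <= 0 or self.stable_sigma <= 0:
            raise ValueError("noise SDs must be positive")
        lo, hi = self.hkg_sigma_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad hkg_sigma_range {self.hkg_sigma_range}")


@dataclass
class SimulationTruth:
    """Planted parameters of one synthetic experiment.

    ``genes`` is indexed by symbol with columns baseline, sigma, log2fc,
    role (stable-HKG / unstable-HKG / target) and planted_class;
    ``offsets`` maps sample id -> loading offset in cycles.
    """

    genes: pd.DataFrame
    offsets: pd.Series
    seed: int
    n_per_group: int
    max_cycle: float


def generate_experiment(
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[CtMatrix, SimulationTruth]:
    """Draw one synthetic chip experiment; deterministic given ``seed``."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    panel = load_default_panel()
    classes = default_panel_classes()
    hkgs = panel.housekeeping
    if len(hkgs) < 2:
        raise ValueError("need at least 2 housekeeping candidates")
    symbols = panel.symbols

    baseline = {}
    sigma = {}
    log2fc = {}
    role = {}
    for g in symbols:
        cls = classes[g]
        lo, hi = _CLASS_WINDOWS[cls]
        baseline[g] = rng.uniform(lo, hi)
        if g in hkgs:
            if g == cfg.stable_hkg:
                sigma[g], log2fc[g], role[g] = cfg.stable_sigma, 0.0, "stable-HKG"
            elif g in _SHIFTED_HKGS:
                sigma[g] = cfg.shifted_hkg_sigma
                log2fc[g] = _SHIFTED_HKGS[g]
                role[g] = "unstable-HKG"
            else:
                sigma[g] = rng.uniform(*cfg.hkg_sigma_range)
                log2fc[g] = 0.0
                role[g] = "unstable-HKG"
        else:
            sigma[g] = cfg.target_sigma
            log2fc[g] = cfg.effect_log2fc if g in cfg.effect_genes else 0.0
            role[g] = "target"

    n = cfg.n_per_group
    samples = [f"C{i + 1}" for i in range(n)] + [f"T{i + 1}" for i in range(n)]
    labels = [cfg.control_label] * n + [cfg.treated_label] * n
    offsets = rng.normal(0.0, cfg.loading_sd, size=2 * n) if cfg.loading_sd > 0 else np.zeros(2 * n)

    data = np.empty((len(symbols), 2 * n))
    for i, g in enumerate(symbols):
        eps = rng.normal(0.0, sigma[g], size=2 * n)
        treated_shift = np.array([0.0] * n + [-log2fc[g]] * n)
        data[i] = baseline[g] + offsets + treated_shift + eps
    data[data > cfg.max_cycle] = np.nan  # censored: curve never crossed

    ct = CtMatrix(
        pd.DataFrame(data, index=symbols, columns=samples),
        pd.Series(labels, index=samples, dtype=object),
        max_cycle=cfg.max_cycle,
    )
    genes = pd.DataFrame(
        {
            "baseline": pd.Series(baseline),
            "sigma": pd.Series(sigma),
            "log2fc": pd.Series(log2fc),
            "role": pd.Series(role),
            "planted_class": classes.reindex(symbols),
        }
    ).loc[symbols]
    truth = SimulationTruth(
        genes=genes,
        offsets=pd.Series(offsets, index=samples, name="offset"),
        seed=seed,
        n_per_group=n,
        max_cycle=cfg.max_cycle,
    )
    return ct, truth


# ---------------------------------------------------------------------------
# Published stability-rank fixture
# ---------------------------------------------------------------------------

# Per-method rank positions of the 11 candidates as printed, for the
# control and MPTP-lesioned groups.  In the geNorm column the final
# (tied) pair carries rank 1 twice — the convention of the published
# aggregation, which the printed comprehensive scores require.
_PUBLISHED_RANKS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    # gene: (delta_ct, bestkeeper, normfinder, genorm)
    "control": {
        "Rps27a": (2, 1, 2, 1),
        "Sdha": (1, 9, 1, 4),
        "Hprt": (4, 4, 4, 3),
        "Gapvd1": (3, 5, 3, 5),
        "Ube2d2a": (6, 7, 6, 1),
        "Cyc1": (5, 6, 5, 7),
        "Aars": (8, 3, 8, 8),
        "Gapdh": (10, 2, 10, 10),
        "Rpl13": (7, 8, 7, 6),
        "Xpnpep1": (9, 10, 9, 9),
        "Osbp": (11, 11, 11, 11),
    },
    "mptp": {
        "Rps27a": (2, 2, 2, 1),
        "Ube2d2a": (5, 3, 1, 1),
        "Rpl13": (3, 1, 3, 3),
        "Cyc1": (1, 5, 4, 5),
        "Hprt": (4, 4, 6, 4),
        "Xpnpep1": (6, 7, 5, 7),
        "Sdha": (7, 6, 7, 6),
        "Gapdh": (8, 8, 8, 8),
        "Aars": (9, 9, 9, 9),
        "Gapvd1": (10, 10, 10, 10),
        "Osbp": (11, 11, 11, 11),
    },
}


def make_published_rank_fixture() -> pd.DataFrame:
    """Published per-method stability ranks of the 11 HKG candidates.

    Returns a frame indexed by (condition, gene) with one column per
    method (delta_ct, bestkeeper, normfinder, genorm) holding the rank
    position of that gene in that method's printed ordering.  Conditions
    are ``control`` and ``mptp``.
    """
    rows = []
    for cond, genes in _PUBLISHED_RANKS.items():
        for gene, (dct, bk, nf, gn) in genes.items():
            rows.append(
                {
                    "condition": cond,
                    "gene": gene,
                    "delta_ct": dct,
                    "bestkeeper": bk,
                    "normfinder": nf,
                    "genorm": gn,
                }
            )
    return pd.DataFrame(rows).set_index(["condition", "gene"])
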