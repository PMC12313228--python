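"""Nine-gene partial-EMT (p-EMT) score from qPCR cycle-threshold tables.

The score summarises the expression of nine p-EMT marker genes relative to
GAPDH in a cohort of keratinocyte populations:

1. ``dCT = CT_gene - CT_GAPDH`` per (population, gene, replicate), replicates
   then averaged per (population, gene);
2. ``EXP = 2**(-dCT) * 100``;
3. per gene, the cohort extremes ``EXP_min``/``EXP_max`` define a
   normalisation constant ``N_val = (100 * EXP_min - EXP_max) / 99`` which is
   subtracted from every population's EXP, mapping each gene's cohort range
   onto an exact 100-fold span;
4. the nine normalised values are averaged per population, and the cohort of
   averages is linearly rescaled to [0.1, 10].

The population with the maximal raw mean therefore scores exactly 10 and the
minimal one exactly 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PANEL",
    "REFERENCE_GENE",
    "GenePanel",
    "PEMTResult",
    "compute_delta_ct",
    "exp_transform",
    "compute_nval",
    "normalize_gene",
    "pemt_score",
]

REFERENCE_GENE = "GAPDH"

#: Default nine-gene p-EMT panel (configurable; order is cosmetic).
DEFAULT_PANEL = (
    "PDPN", "VIM", "PAI1", "LAMC2", "TGFBI", "THBS1", "MMP1", "MMP10", "ITGA5",
)

SCORE_LO = 0.1
SCORE_HI = 10.0


@dataclass(frozen=True)
class GenePanel:
    """An ordered panel of exactly nine unique marker genes (reference excluded)."""

    genes: tuple[str, ...] = field(default=DEFAULT_PANEL)

    def __post_init__(self) -> None:
        if len(self.genes) != 9:
            raise ValueError(f"panel must contain exactly 9 genes, got {len(self.genes)}")
        if len(set(self.genes)) != 9:
            raise ValueError("panel genes must be unique")
        if REFERENCE_GENE in self.genes:
            raise ValueError(f"reference gene {REFERENCE_GENE} cannot be a panel gene")

    def __iter__(self):
        return iter(self.genes)


@dataclass
class PEMTResult:
    """Per-gene intermediates and per-population scores.

    Attributes
    ----------
    per_gene
        DataFrame indexed by (population_id, gene_id) with columns
        ``delta_ct``, ``exp``, ``n_val``, ``normalized``.
    scores
        DataFrame indexed by population_id with columns ``raw_mean``, ``score``.
    """

    per_gene: pd.DataFrame
    scores: pd.DataFrame

    def score_of(self, population_id: str) -> float:
        return float(self.scores.loc[population_id, "score"])


def _validate_ct_table(ct_table: pd.DataFrame, panel: GenePanel) -> None:
    required = {"population_id", "gene_id", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct_table["ct"].to_numpy(dtype=float)).all():
        raise ValueError("ct table contains non-finite Ct values")
    for pop, block in ct_table.groupby("population_id"):
        genes = set(block["gene_id"])
        absent = [g for g in panel if g not in genes]
        if absent:
            raise ValueError(f"population {pop!r} is missing panel gene(s) {absent}")


def compute_delta_ct(ct_table: pd.DataFrame, panel: GenePanel | None = None) -> pd.DataFrame:
    """Compute ``dCT = CT_gene - CT_GAPDH`` per (population, gene, replicate).

    The reference Ct is matched within the same (population, replicate) block;
    a block lacking GAPDH is an error naming the block.  Returns a long
    DataFrame (population_id, gene_id, replicate, delta_ct).
    """
    panel = panel or GenePanel()
    _validate_ct_table(ct_table, panel)
    ref = ct_table[ct_table["gene_id"] == REFERENCE_GENE]
    ref_map = ref.set_index(["population_id", "replicate"])["ct"]
    if ref_map.index.has_duplicates:
        ref_map = ref_map.groupby(level=[0, 1]).mean()
    genes = ct_table[ct_table["gene_id"].isin(set(panel))].copy()
    keys = pd.MultiIndex.from_frame(genes[["population_id", "replicate"]])
    missing = ~keys.isin(ref_map.index)
    if missing.any():
        bad = sorted(set(keys[missing]))
        raise ValueError(f"missing {REFERENCE_GENE} for (population, replicate) block(s): {bad}")
    genes["delta_ct"] = genes["ct"].to_numpy() - ref_map.loc[keys].to_numpy()
    return genes[["population_id", "gene_id", "replicate", "delta_ct"]].reset_index(drop=True)


def exp_transform(delta_ct):
    """Relative expression ``EXP = 2**(-dCT) * 100``; strictly decreasing in dCT."""
    delta_ct = np.asarray(delta_ct, dtype=float)
    if not np.isfinite(delta_ct).all():
        raise ValueError("delta_ct must be finite")
    out = np.exp2(-delta_ct) * 100.0
    return out if out.ndim else float(out)


def compute_nval(exp_min: float, exp_max: float) -> float:
    """Per-gene normalisation constant ``N_val = (100*EXP_min - EXP_max)/99``.

    Subtracting N_val maps the gene's cohort range onto a 100-fold span:
    ``(EXP_max - N_val) = 100 * (EXP_min - N_val)`` whenever the extremes differ.
    """
    if exp_min > exp_max:
        raise ValueError(f"exp_min ({exp_min}) exceeds exp_max ({exp_max})")
    return (100.0 * exp_min - exp_max) / 99.0


def normalize_gene(exp, n_val: float):
    """Normalised expression ``EXP - N_val``."""
    out = np.asarray(exp, dtype=float) - n_val
    return out if out.ndim else float(out)


def pemt_score(ct_table: pd.DataFrame, panel: GenePanel | None = None) -> PEMTResult:
    """Full scoring chain: dCT -> EXP -> N_val normalisation -> mean -> [0.1, 10].

    Replicate dCTs are averaged per (population, gene) before the EXP
    transform; EXP extremes are taken over these per-population values.  A
    gene whose cohort extremes coincide contributes 0 for every population
    (with a warning) since it carries no discrimination.  Requires >= 2
    populations.  If every population has the identical raw mean the cohort is
    degenerate and all scores are set to the midpoint 5.05 with a warning.
    """
    panel = panel or GenePanel()
    dct = compute_delta_ct(ct_table, panel)
    if dct["population_id"].nunique() < 2:
        raise ValueError("p-EMT scoring needs at least 2 populations")
    agg = dct.groupby(["population_id", "gene_id"], sort=True)["delta_ct"].mean()
    per_gene = agg.reset_index()
    per_gene["exp"] = exp_transform(per_gene["delta_ct"].to_numpy())

    nvals: dict[str, float] = {}
    for gene, block in per_gene.groupby("gene_id"):
        lo, hi = float(block["exp"].min()), float(block["exp"].max())
        if lo == hi:
            warnings.warn(
                f"gene {gene!r}: identical expression in all populations; "
                "normalized values set to 0",
                stacklevel=2,
            )
            nvals[gene] = np.nan  # sentinel: degenerate gene
        else:
            nvals[gene] = compute_nval(lo, hi)
    per_gene["n_val"] = per_gene["gene_id"].map(nvals)
    per_gene["normalized"] = per_gene["exp"] - per_gene["n_val"]
    per_gene.loc[per_gene["n_val"].isna(), "normalized"] = 0.0

    raw = per_gene.groupby("population_id")["normalized"].mean().rename("raw_mean")
    lo, hi = float(raw.min()), float(raw.max())
    if lo == hi:
        warnings.warn("all populations have identical raw means; scores set to 5.05", stacklevel=2)
        score = pd.Series(np.full(len(raw), (SCORE_LO + SCORE_HI) / 2.0), index=raw.index)
    else:
        score = SCORE_LO + (SCORE_HI - SCORE_LO) * (raw - lo) / (hi - lo)
    scores = pd.DataFrame({"raw_mean": raw, "score": score})
    per_gene = per_gene.set_index(["population_id", "gene_id"])[
        ["delta_ct", "exp", "n_val", "normalized"]
    ]
    return PEMTResult(per_gene=per_gene, scores=scores)
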