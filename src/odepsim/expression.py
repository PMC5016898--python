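"""Purity-dependent dilution of housekeeping-normalised gene expression.

A harvested cell pool is a two-component mixture: a fraction ``p`` of
cancer cells and ``1 - p`` of contaminating leukocytes.  Bulk RT-qPCR
reports each gene relative to GAPDH, so the measured ratio is

    R(p) = [p E_c(g) + (1 - p) E_l(g)] / [p G_c + (1 - p) G_l]

with per-cell transcript abundances E (relative to that cell type's
GAPDH) and per-cell GAPDH weights G.  For a drug-resistance gene the
leukocytes do not express (E_l = 0), the measured level is simply
diluted: low purity under-reports the cancer cells' true expression.
The fold-change between a purified and an unpurified arm then encodes
the purity of the unpurified arm, which :func:`implied_purity_from_fold`
recovers in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import pandas as pd

from .errors import ValidationError

__all__ = ["ExpressionParams", "MixtureSample", "mixture_relative_expression",
           "fold_change", "implied_purity_from_fold", "dilution_table",
           "GENES"]

GENES = ("EpCAM", "CD45", "MRP4", "MRP5")


def _default_cancer():
    # per-cell abundance relative to the cell's own GAPDH
    return {"EpCAM": 1.0, "CD45": 0.0, "MRP4": 1.0, "MRP5": 1.0}


def _default_leuko():
    # drug-resistance transporter expression in leukocytes defaults to 0
    return {"EpCAM": 0.0, "CD45": 1.0, "MRP4": 0.0, "MRP5": 0.0}


@dataclass(frozen=True)
class ExpressionParams:
    """Per-cell relative transcript abundances and GAPDH weights."""

    cancer: dict = dfield(default_factory=_default_cancer)
    leukocyte: dict = dfield(default_factory=_default_leuko)
    gapdh_cancer: float = 1.0
    gapdh_leukocyte: float = 1.0

    def __post_init__(self):
        if self.gapdh_cancer <= 0 or self.gapdh_leukocyte <= 0:
            raise ValidationError("per-cell GAPDH weights must be positive")
        for table in (self.cancer, self.leukocyte):
            for g, v in table.items():
                if v < 0:
                    raise ValidationError(f"negative abundance for {g}")

    def abundance(self, cell_type: str, gene: str) -> float:
        table = self.cancer if cell_type == "cancer" else self.leukocyte
        if gene not in table:
            raise ValidationError(f"unknown gene {gene!r}")
        return table[gene]


@dataclass(frozen=True)
class MixtureSample:
    """A harvested pool: cancer fraction by cell count."""

    cancer_fraction: float
    total_cells: int = 0

    def __post_init__(self):
        if not (0.0 <= self.cancer_fraction <= 1.0):
            raise ValidationError("cancer_fraction must lie in [0, 1]")


def mixture_relative_expression(sample: MixtureSample, gene: str,
                                params: ExpressionParams) -> float:
    """GAPDH-normalised expression ratio of ``gene`` in the mixture."""
    p = sample.cancer_fraction
    num = p * params.abundance("cancer", gene) * params.gapdh_cancer \
        + (1 - p) * params.abundance("leukocyte", gene) \
        * params.gapdh_leukocyte
    den = p * params.gapdh_cancer + (1 - p) * params.gapdh_leukocyte
    return num / den


def fold_change(p_purified: float, p_unpurified: float, gene: str,
                params: ExpressionParams) -> float:
    """Ratio of the purified arm's measurement to the unpurified arm's."""
    r_pur = mixture_relative_expression(MixtureSample(p_purified), gene,
                                        params)
    r_unp = mixture_relative_expression(MixtureSample(p_unpurified), gene,
                                        params)
    if r_unp == 0:
        return float("inf") if r_pur > 0 else float("nan")
    return r_pur / r_unp


def implied_purity_from_fold(fold: float, gene: str,
                             params: ExpressionParams | None = None,
                             p_purified: float = 1.0) -> float:
    """Purity of the unpurified arm implied by an observed fold-change.

    Solves ``fold_change(p_purified, p, gene) = fold`` for ``p`` in
    closed form (the ratio is a Moebius function of p, so the equation
    is linear in p).  Under the default assumptions - no leukocyte
    expression of the gene and equal per-cell GAPDH - this reduces to
    ``p = p_purified / fold``.
    """
    params = params or ExpressionParams()
    if fold < 1.0 and params.abundance("leukocyte", gene) == 0:
        raise ValidationError(
            "fold < 1 is inconsistent with zero leukocyte expression")
    ec = params.abundance("cancer", gene) * params.gapdh_cancer
    el = params.abundance("leukocyte", gene) * params.gapdh_leukocyte
    gc, gl = params.gapdh_cancer, params.gapdh_leukocyte
    r_target = mixture_relative_expression(MixtureSample(p_purified), gene,
                                           params) / fold
    # solve [p ec + (1-p) el] = r_target [p gc + (1-p) gl]
    a = (ec - el) - r_target * (gc - gl)
    b = el - r_target * gl
    if a == 0:
        raise ValidationError("fold does not determine a unique purity "
                              "(degenerate parameters)")
    p = -b / a
    if not (-1e-9 <= p <= 1 + 1e-9):
        raise ValidationError(
            f"implied purity {p:.4f} outside [0, 1]: fold inconsistent "
            "with the expression parameters")
    return min(max(p, 0.0), 1.0)


def dilution_table(folds: dict, params: ExpressionParams | None = None,
                   p_purified: float = 1.0) -> pd.DataFrame:
    """Per-gene diagnostic: observed fold, implied purity of the
    unpurified arm, and the model ratios at both purities.  Gene-to-gene
    disagreement in implied purity is surfaced, not averaged."""
    params = params or ExpressionParams()
    rows = []
    for gene, f in folds.items():
        p_unp = implied_purity_from_fold(f, gene, params, p_purified)
        rows.append({
            "gene": gene,
            "fold": f,
            "p_purified": p_purified,
            "implied_purity_unpurified": p_unp,
            "ratio_purified": mixture_relative_expression(
                MixtureSample(p_purified), gene, params),
            "ratio_unpurified": mixture_relative_expression(
                MixtureSample(p_unp), gene, params),
        })
    return pd.DataFrame(rows)
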