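"""Virtual histology and gene-wise screening of regional expression.

Cell-class maps are the mean regional expression of marker-gene sets for
the seven canonical cortical cell classes (astrocytes, endothelial cells,
microglia, excitatory/inhibitory neurons, oligodendrocytes, OPCs); their
correlation with an atrophy-progression map is tested against spatial spin
nulls.  The gene-wise screen selects genes whose expression correlates
with progression after both FDR correction and a spin test, and the
surviving lists feed an overrepresentation analysis (hypergeometric and
Fisher one-sided tails, Bonferroni-adjusted, with fold enrichment =
observed / expected count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import SpinNulls
from .progression import p_adjust
from .spins import apply_spins, spin_pvalue

logger = logging.getLogger(__name__)


def celltype_scores(expr: pd.DataFrame, sets: dict[str, list[str]]) -> pd.DataFrame:
    """Region x class table of mean marker-gene expression.

    Genes missing from the expression matrix are skipped with a logged
    warning; a class with no available genes is an error.
    """
    available = set(expr.columns)
    out = {}
    for cname, genes in sets.items():
        present = [g for g in genes if g in available]
        missing = len(genes) - len(present)
        if not present:
            raise ValueError(f"cell class {cname!r} has no genes in the expression matrix")
        if missing:
            logger.warning("cell class %r: %d gene(s) missing from expression", cname, missing)
        out[cname] = expr[present].to_numpy(dtype=float).mean(axis=1)
    return pd.DataFrame(out, index=expr.index)


def celltype_correlations(
    scores: pd.DataFrame,
    progression: np.ndarray,
    spins: SpinNulls,
    tails: str = "two",
) -> pd.DataFrame:
    """Pearson r of each cell-class map with progression, plus spin p.

    The progression map is the spun quantity; the class maps stay fixed.
    """
    progression = np.asarray(progression, dtype=float)
    if len(scores) != len(progression):
        raise ValueError("scores and progression must cover the same regions")
    if np.ptp(progression) == 0:
        raise ValueError("zero variance in progression map")
    spun = apply_spins(progression, spins)  # (S, n)
    rows = []
    for cname in scores.columns:
        s = scores[cname].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            raise ValueError(f"zero variance in cell-class map {cname!r}")
        r = float(np.corrcoef(s, progression)[0, 1])
        sc = (s - s.mean()) / s.std()
        pc = (spun - spun.mean(axis=1, keepdims=True)) / spun.std(axis=1, keepdims=True)
        r_null = (pc @ sc) / len(s)
        rows.append(
            {
                "cell_class": cname,
                "r": r,
                "p_spin": spin_pvalue(r, r_null, tails),
                "n_spins": spins.n_spins,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GeneScreenResult:
    """Gene-wise correlation screen with joint FDR + spin selection."""

    table: pd.DataFrame  # gene, r, p_raw, p_fdr, p_spin, direction, survives
    positive: list[str]
    negative: list[str]
    n_regions: int


def genewise_screen(
    expr: pd.DataFrame,
    progression: np.ndarray,
    spins: SpinNulls,
    fdr_alpha: float = 0.05,
    spin_alpha: float = 0.05,
    method: str = "pearson",
) -> GeneScreenResult:
    """Correlate every gene's expression map with atrophy progression.

    A gene survives iff its BH-FDR-adjusted parametric p is below
    ``fdr_alpha`` *and* its spin p (shared spins, two-tailed) is below
    ``spin_alpha``; survivors are split by the sign of r.  Constant gene
    columns are excluded with a warning.  ``method='spearman'`` rank
    transforms everything first.
    """
    progression = np.asarray(progression, dtype=float)
    n = len(progression)
    if n < 10:
        raise ValueError("need at least 10 regions")
    if len(expr) != n:
        raise ValueError("expression rows must match progression length")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    x = expr.to_numpy(dtype=float)
    genes = np.array(expr.columns, dtype=object)
    keep = x.std(axis=0) > 0
    if not keep.all():
        logger.warning("%d constant gene column(s) excluded from screen", int((~keep).sum()))
        x, genes = x[:, keep], genes[keep]
    prog = progression
    spun = apply_spins(progression, spins)  # (S, n)
    if method == "spearman":
        x = scipy.stats.rankdata(x, axis=0)
        prog = scipy.stats.rankdata(prog)
        spun = scipy.stats.rankdata(spun, axis=1)

    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    ps = (prog - prog.mean()) / prog.std()
    r = (xs.T @ ps) / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p_raw = 2 * scipy.stats.t.sf(np.abs(t), n - 2)
    p_fdr = p_adjust(p_raw, "bh_fdr")

    spun_s = (spun - spun.mean(axis=1, keepdims=True)) / spun.std(axis=1, keepdims=True)
    r_null = (xs.T @ spun_s.T) / n  # (genes, S)
    p_spin = (1 + (np.abs(r_null) >= np.abs(r)[:, None]).sum(axis=1)) / (1 + spins.n_spins)

    survives = (p_fdr < fdr_alpha) & (p_spin < spin_alpha)
    direction = np.where(r >= 0, "positive", "negative")
    table = pd.DataFrame(
        {
            "gene": genes,
            "r": r,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "p_spin": p_spin,
            "direction": direction,
            "survives": survives,
        }
    )
    positive = [g for g, s, d in zip(genes, survives, direction) if s and d == "positive"]
    negative = [g for g, s, d in zip(genes, survives, direction) if s and d == "negative"]
    return GeneScreenResult(table=table, positive=positive, negative=negative, n_regions=n)


def overrepresentation(
    target_genes,
    background_genes,
    annotation: dict[str, list[str]],
    min_term_size: int = 5,
) -> pd.DataFrame:
    """Term-wise overrepresentation of a target gene list.

    For each annotation term with at least ``min_term_size`` genes in the
    background: observed = |target ∩ term|, expected = |target| * |term ∩
    background| / |background|, fold = observed / expected, with the
    hypergeometric upper-tail p and the (identical-tail) one-sided Fisher
    exact p, Bonferroni-adjusted over the tested terms.
    """
    target = list(dict.fromkeys(target_genes))
    background = list(dict.fromkeys(background_genes))
    if not background:
        raise ValueError("empty background gene list")
    bg = set(background)
    stray = [g for g in target if g not in bg]
    if stray:
        raise ValueError(f"target gene(s) not in background: {stray[:5]}")
    m = len(bg)
    n_target = len(target)
    tset = set(target)
    rows = []
    for term, genes in annotation.items():
        term_bg = set(genes) & bg
        k_term = len(term_bg)
        if k_term < min_term_size:
            continue
        observed = len(term_bg & tset)
        expected = n_target * k_term / m
        fold = observed / expected if expected > 0 else np.nan
        p_hyper = float(scipy.stats.hypergeom.sf(observed - 1, m, k_term, n_target))
        table = [
            [observed, k_term - observed],
            [n_target - observed, m - k_term - n_target + observed],
        ]
        p_fisher = float(scipy.stats.fisher_exact(table, alternative="greater")[1])
        rows.append(
            {
                "term": term,
                "n_term_background": k_term,
                "n_observed": observed,
                "expected": expected,
                "fold_enrichment": fold,
                "p_hyper": p_hyper,
                "p_fisher": p_fisher,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonf"] = np.minimum(1.0, out["p_hyper"] * len(out))
        out = out.sort_values(["p_bonf", "term"], kind="mergesort").reset_index(drop=True)
    return out
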