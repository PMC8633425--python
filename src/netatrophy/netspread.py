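"""Network-spread statistics: neighbourhood atrophy and spin significance.

If a pathological agent propagates along axonal projections, the atrophy
progression of a region should track the atrophy progression of the regions
it is connected to.  The test statistic is the Pearson correlation between
each region's progression and the (weighted) mean progression of its
neighbourhood, assessed against a spatial spin null in which the atrophy
map is rotated on the sphere and both node values and neighbourhood
estimates are recomputed from the spun map (the network stays fixed).

Four neighbourhood definitions are provided: unweighted structural
neighbours, FC-weighted structural neighbours, FC-weighted structurally
*unconnected* regions, and FC-weighted all regions — the latter two isolate
the contribution of functional connectivity.  Dependent correlations are
compared with Zou's confidence interval for the difference of two
overlapping correlations, and a degree-preserving rewired graph serves as a
negative-control network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import Connectome, SpinNulls, as_rng
from .spins import apply_spins, spin_pvalue

logger = logging.getLogger(__name__)

ESTIMATORS = ("sc_unweighted", "fc_weighted_sc", "fc_weighted_nonsc", "fc_weighted_all")
_DENOM_TOL = 1e-8


def _weight_matrix(
    conn: Connectome, estimator: str, weight_mode: str = "raw_fc"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-normalised weight matrix P (estimate = P @ atrophy), flags, counts."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if weight_mode not in ("raw_fc", "clipped_fc"):
        raise ValueError("weight_mode must be 'raw_fc' or 'clipped_fc'")
    n = conn.n_regions
    offdiag = ~np.eye(n, dtype=bool)
    sc_mask = (conn.sc > 0) & offdiag
    if estimator == "sc_unweighted":
        w = sc_mask.astype(float)
    else:
        fc = np.clip(conn.fc, 0.0, None) if weight_mode == "clipped_fc" else conn.fc
        if estimator == "fc_weighted_sc":
            w = fc * sc_mask
        elif estimator == "fc_weighted_nonsc":
            w = fc * (~sc_mask & offdiag)
        else:
            w = fc * offdiag
    counts = (w != 0).sum(axis=1)
    denom = w.sum(axis=1)
    flagged = (counts == 0) | (np.abs(denom) < _DENOM_TOL)
    safe = np.where(flagged, 1.0, denom)
    p = w / safe[:, None]
    p[flagged] = np.nan
    return p, flagged, counts


@dataclass
class NeighbourEstimates:
    """Per-region neighbourhood-atrophy estimates (NaN where flagged)."""

    estimates: dict[str, np.ndarray]
    flagged: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]

    def to_frame(self, region_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.estimates)
        if region_ids is not None:
            df.insert(0, "region", list(region_ids))
        return df


def neighbour_estimates(
    atrophy: np.ndarray,
    conn: Connectome,
    weight_mode: str = "raw_fc",
    estimators: tuple[str, ...] = ESTIMATORS,
) -> NeighbourEstimates:
    """Collective neighbourhood atrophy of every region, per estimator.

    ``sc_unweighted`` is the plain mean over structural neighbours; the
    FC-weighted variants are ``sum_j a_j w_ij / sum_j w_ij`` over the
    respective neighbour sets (self always excluded).  Regions with an
    empty neighbourhood or a near-zero weight sum are flagged (NaN), never
    silently zeroed; if an estimator flags every region that is an error.
    """
    atrophy = np.asarray(atrophy, dtype=float)
    if atrophy.shape != (conn.n_regions,):
        raise ValueError("atrophy length must match connectome size")
    if not np.isfinite(atrophy).all():
        raise ValueError("atrophy map contains non-finite values")
    est, flags, counts = {}, {}, {}
    for name in estimators:
        p, flagged, cnt = _weight_matrix(conn, name, weight_mode)
        if flagged.all():
            raise ValueError(f"estimator {name!r}: every region flagged")
        vals = p @ atrophy
        vals[flagged] = np.nan
        est[name], flags[name], counts[name] = vals, flagged, cnt
    return NeighbourEstimates(estimates=est, flagged=flags, counts=counts)


def _colwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n, m) arrays."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (xc * yc).sum(axis=0) / np.where(denom > 0, denom, 1.0), np.nan)


def node_neighbour_correlation(
    atrophy: np.ndarray,
    conn: Connectome,
    spins: SpinNulls,
    estimators: tuple[str, ...] = ESTIMATORS,
    weight_mode: str = "raw_fc",
    tails: str = "two",
    min_regions: int = 10,
) -> pd.DataFrame:
    """Node-neighbour Pearson correlation per estimator with spin p-values.

    For each spin the atrophy map is rotated and *both* the node values and
    the neighbourhood estimates are recomputed from the spun map, so the
    null preserves the coupling induced purely by spatial proximity.
    """
    atrophy = np.asarray(atrophy, dtype=float)
    spun = apply_spins(atrophy, spins).T  # (n, S)
    rows = []
    for name in estimators:
        p, flagged, _ = _weight_matrix(conn, name, weight_mode)
        mask = ~flagged
        if mask.sum() < min_regions:
            raise ValueError(f"estimator {name!r}: fewer than {min_regions} usable regions")
        obs_est = (p @ atrophy)[mask]
        x = atrophy[mask]
        if np.ptp(x) == 0 or np.ptp(obs_est) == 0:
            raise ValueError("zero variance in node or neighbour values")
        r = float(np.corrcoef(x, obs_est)[0, 1])
        null_est = (p[mask] @ spun)  # (n_mask, S)
        r_null = _colwise_pearson(spun[mask], null_est)
        if np.isnan(r_null).any():
            raise ValueError("NaN among null correlations")
        rows.append(
            {
                "estimator": name,
                "r": r,
                "p_spin": spin_pvalue(r, r_null, tails),
                "n_regions": int(mask.sum()),
                "n_spins": spins.n_spins,
            }
        )
    return pd.DataFrame(rows)


def zou_difference_ci(
    r1: float, r2: float, r12: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Zou (2007) confidence interval for the difference of two overlapping
    dependent correlations r1 = cor(x, y1) and r2 = cor(x, y2).

    Individual Fisher-z confidence limits for r1 and r2 are back-transformed
    and combined using the sampling correlation ``c`` between the two
    correlation estimates, computed from r12 = cor(y1, y2).  Accepts scalars
    or broadcastable arrays.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    r12 = np.asarray(r12, dtype=float)
    if np.any(np.abs(r1) >= 1) or np.any(np.abs(r2) >= 1) or np.any(np.abs(r12) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 4:
        raise ValueError("n must exceed 4")
    z = scipy.stats.norm.ppf(1 - (1 - level) / 2)
    se = 1.0 / np.sqrt(n - 3)
    with np.errstate(divide="raise", invalid="raise"):
        l1 = np.tanh(np.arctanh(r1) - z * se)
        u1 = np.tanh(np.arctanh(r1) + z * se)
        l2 = np.tanh(np.arctanh(r2) - z * se)
        u2 = np.tanh(np.arctanh(r2) + z * se)
    c = (r12 * (1 - r1**2 - r2**2) - 0.5 * r1 * r2 * (1 - r1**2 - r2**2 - r12**2)) / (
        (1 - r1**2) * (1 - r2**2)
    )
    diff = r1 - r2
    lower = diff - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2))
    upper = diff + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2))
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def compare_dependent_correlations(
    x: np.ndarray, y1: np.ndarray, y2: np.ndarray, level: float = 0.95
) -> dict:
    """r1, r2, their difference and Zou CI for overlapping correlations
    sharing the common variable ``x`` (complete finite cases only)."""
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y1) & np.isfinite(y2)
    x, y1, y2 = x[mask], y1[mask], y2[mask]
    n = len(x)
    r1 = float(np.corrcoef(x, y1)[0, 1])
    r2 = float(np.corrcoef(x, y2)[0, 1])
    r12 = float(np.corrcoef(y1, y2)[0, 1])
    lo, hi = zou_difference_ci(r1, r2, r12, n, level)
    return {"r1": r1, "r2": r2, "r12": r12, "n": n, "diff": r1 - r2, "ci": (lo, hi)}


def rewire_degree_preserving(sc: np.ndarray, n_swap_per_edge: int = 10, seed=None) -> np.ndarray:
    """Maslov-Sneppen double-edge-swap rewiring of a binary graph.

    Preserves the degree sequence exactly; produces no self-loops or
    multi-edges.  Used as a negative-control network: it keeps degrees but
    destroys the spatial/topological embedding that carries the spread.
    """
    sc = np.asarray(sc, dtype=float)
    vals = np.unique(sc)
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("rewiring expects a binary adjacency matrix")
    if np.max(np.abs(sc - sc.T)) > 0:
        raise ValueError("adjacency must be symmetric")
    g = nx.from_numpy_array(sc)
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("too few edges to swap")
    rng = as_rng(seed)
    nswap = n_swap_per_edge * m
    nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31 - 1)))
    out = nx.to_numpy_array(g, nodelist=range(sc.shape[0]))
    return out
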