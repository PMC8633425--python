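"""Naive reference implementations for validation.

Every function here recomputes a pipeline quantity by the most direct
route available — explicit per-element loops, textbook formulas, or exact
enumeration — deliberately sharing no code with the vectorised
implementations.  They exist solely so that the fast paths can be checked
against an independent computation on small instances; they are far too
slow for real use.
"""

from __future__ import annotations

import math

import numpy as np


def neighbour_estimates_loop(atrophy, sc, fc, weight_mode: str = "raw_fc") -> dict:
    """Per-node loop version of the four neighbourhood estimators."""
    n = len(atrophy)
    out = {k: np.full(n, np.nan) for k in
           ("sc_unweighted", "fc_weighted_sc", "fc_weighted_nonsc", "fc_weighted_all")}
    for i in range(n):
        sc_nb = [j for j in range(n) if j != i and sc[i, j] > 0]
        non_nb = [j for j in range(n) if j != i and sc[i, j] == 0]
        allr = [j for j in range(n) if j != i]
        if sc_nb:
            out["sc_unweighted"][i] = sum(atrophy[j] for j in sc_nb) / len(sc_nb)
        for name, idxs in (("fc_weighted_sc", sc_nb),
                           ("fc_weighted_nonsc", non_nb),
                           ("fc_weighted_all", allr)):
            ws = [max(fc[i, j], 0.0) if weight_mode == "clipped_fc" else fc[i, j]
                  for j in idxs]
            nz = [(w, atrophy[j]) for w, j in zip(ws, idxs) if w != 0]
            wsum = sum(w for w, _ in nz)
            if nz and abs(wsum) >= 1e-8:
                out[name][i] = sum(w * a for w, a in nz) / wsum
    return out


def celltype_scores_loop(expr_values, gene_ids, sets) -> dict:
    """Per-region loop version of the class-mean scores."""
    idx = {g: k for k, g in enumerate(gene_ids)}
    out = {}
    for cname, genes in sets.items():
        cols = [idx[g] for g in genes if g in idx]
        vals = []
        for i in range(expr_values.shape[0]):
            vals.append(sum(expr_values[i, c] for c in cols) / len(cols))
        out[cname] = np.array(vals)
    return out


def spearman_loop(x, y) -> float:
    """Spearman rho from first principles: Pearson of average ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return np.array(r)

    rx, ry = ranks(list(x)), ranks(list(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def partial_corr_loop(x, y, covs) -> float:
    """Partial correlation via explicit two-stage regressions."""
    n = len(x)
    design = np.column_stack([np.ones(n), covs])
    bx = np.linalg.solve(design.T @ design, design.T @ x)
    by = np.linalg.solve(design.T @ design, design.T @ y)
    ex = x - design @ bx
    ey = y - design @ by
    return float((ex @ ey) / math.sqrt((ex @ ex) * (ey @ ey)))


def partial_spearman_loop(x, y, covs) -> float:
    """Rank everything with spearman_loop's ranking, then partial corr."""
    def ranks(v):
        # reuse spearman_loop's averaging by correlating against itself
        order = np.argsort(np.argsort(v, kind="mergesort"), kind="mergesort") + 1.0
        vals, counts = np.unique(v, return_counts=True)
        if np.any(counts > 1):
            out = np.empty(len(v))
            for val in vals:
                mask = v == val
                out[mask] = order[mask].mean()
            return out
        return order

    rx = ranks(np.asarray(x, dtype=float))
    ry = ranks(np.asarray(y, dtype=float))
    covs = np.atleast_2d(np.asarray(covs, dtype=float))
    if covs.shape[0] != len(x):
        covs = covs.T
    rc = np.column_stack([ranks(covs[:, j]) for j in range(covs.shape[1])])
    return partial_corr_loop(rx, ry, rc)


def oneway_anova_f_loop(values, groups) -> float:
    """One-way ANOVA F from the explicit sum-of-squares decomposition."""
    labels = list(dict.fromkeys(groups))
    gm = sum(values) / len(values)
    ssb = ssw = 0.0
    for lab in labels:
        g = [v for v, l in zip(values, groups) if l == lab]
        m = sum(g) / len(g)
        ssb += len(g) * (m - gm) ** 2
        ssw += sum((v - m) ** 2 for v in g)
    dfb = len(labels) - 1
    dfw = len(values) - len(labels)
    return (ssb / dfb) / (ssw / dfw)


def holm_loop(p) -> np.ndarray:
    """Step-down Holm adjustment, written out index by index."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        val = (m - rank) * p[i]
        running = max(running, val)
        adj[i] = min(1.0, running)
    return np.array(adj)


def bonferroni_loop(p) -> np.ndarray:
    return np.array([min(1.0, v * len(list(p))) for v in p])


def bh_loop(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        val = m * p[i] / (rank + 1)
        running = min(running, val)
        adj[i] = min(1.0, running)
    return np.array(adj)


def hypergeom_upper_tail_enum(m, k_term, n_target, observed) -> float:
    """Upper-tail hypergeometric p by exact enumeration of overlap counts."""
    total = math.comb(m, n_target)
    acc = 0
    for k in range(observed, min(k_term, n_target) + 1):
        if n_target - k <= m - k_term:
            acc += math.comb(k_term, k) * math.comb(m - k_term, n_target - k)
    return acc / total


def rm_anova_f_loop(data) -> float:
    """One-way repeated-measures F via the textbook decomposition."""
    data = np.asarray(data, dtype=float)
    n, t = data.shape
    gm = data.mean()
    ss_subj = t * sum((data[i].mean() - gm) ** 2 for i in range(n))
    ss_time = n * sum((data[:, j].mean() - gm) ** 2 for j in range(t))
    ss_tot = sum((data[i, j] - gm) ** 2 for i in range(n) for j in range(t))
    ss_err = ss_tot - ss_subj - ss_time
    return (ss_time / (t - 1)) / (ss_err / ((n - 1) * (t - 1)))
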