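"""Spatial-autocorrelation-preserving permutation nulls (spin tests).

Parcel centroids live on the unit sphere.  A null sample is produced by
drawing a uniform random 3-D rotation, applying it to the left-hemisphere
centroids and its sagittal mirror image to the right hemisphere, and
reassigning each region the value of the nearest rotated centroid of the
same hemisphere (``nearest``, duplicates allowed) or of its optimal
one-to-one match (``bijective``).  Because rotations are isometries, the
spatial autocorrelation of a spun map matches that of the original map,
which is what makes the resulting permutation p-values calibrated for
spatially smooth brain maps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datatypes import ParcelAtlas, SpinNulls, as_rng

logger = logging.getLogger(__name__)

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # sagittal (x -> -x) reflection


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` rotations uniformly from SO(3) (QR with sign correction)."""
    a = rng.standard_normal((n, 3, 3))
    out = np.empty_like(a)
    for i in range(n):
        q, r = np.linalg.qr(a[i])
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1.0
        out[i] = q
    return out


def generate_spins(
    atlas: ParcelAtlas,
    n_spins: int,
    method: str = "nearest",
    seed=None,
    rotations: np.ndarray | None = None,
) -> SpinNulls:
    """Build a table of spun region assignments.

    The rotation is sampled for the left hemisphere and mirrored to the
    right (``M R M`` with ``M`` the sagittal reflection), so homotopic
    regions rotate to homotopic places and values never cross hemispheres.
    ``rotations`` may be supplied explicitly (e.g. identity matrices) to
    make the assignment deterministic in tests.
    """
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    if method not in ("nearest", "bijective"):
        raise ValueError("method must be 'nearest' or 'bijective'")
    rng = as_rng(seed)
    idx = {h: atlas.hemi_indices(h) for h in ("L", "R")}
    for h, ix in idx.items():
        if len(ix) < 2:
            raise ValueError(f"hemisphere {h} has fewer than 2 regions")
    if rotations is None:
        rotations = random_rotations(n_spins, rng)
    else:
        rotations = np.asarray(rotations, dtype=float)
        if rotations.shape != (n_spins, 3, 3):
            raise ValueError("rotations must have shape (n_spins, 3, 3)")

    coords = {h: atlas.coords[idx[h]] for h in ("L", "R")}
    assignment = np.empty((n_spins, atlas.n_regions), dtype=int)
    rot_by_hemi = {
        "L": rotations,
        "R": np.einsum("ij,sjk,kl->sil", _MIRROR, rotations, _MIRROR),
    }
    for h in ("L", "R"):
        orig = coords[h]
        # rotated[s, j] = R_s @ orig[j]; sim[s, i, j] = cos angle(orig_i, rotated_j)
        rotated = np.einsum("sij,nj->sni", rot_by_hemi[h], orig)
        sim = np.einsum("ni,smi->snm", orig, rotated)
        if method == "nearest":
            local = np.argmax(sim, axis=2)  # ties -> lowest index
        else:
            local = np.empty((n_spins, len(orig)), dtype=int)
            for s in range(n_spins):
                rows, cols = linear_sum_assignment(-sim[s])
                local[s, rows] = cols
        assignment[:, idx[h]] = idx[h][local]
    spin_seed = None
    if not isinstance(seed, np.random.Generator) and seed is not None:
        spin_seed = int(seed)
    return SpinNulls(assignment=assignment, method=method, seed=spin_seed)


def apply_spins(values: np.ndarray, spins: SpinNulls) -> np.ndarray:
    """Spun copies of a regional map, shape ``(n_spins, n_regions)``."""
    values = np.asarray(values, dtype=float)
    if values.shape != (spins.n_regions,):
        raise ValueError("values length must match spin table")
    return values[spins.assignment]


def spin_pvalue(
    observed: float,
    nulls: np.ndarray,
    tails: str = "two",
    include_observed: bool = True,
) -> float:
    """Permutation p-value of an observed statistic against its null draws.

    The default convention counts the observed statistic as one of the
    draws, ``p = (1 + k) / (1 + n)``, which keeps p strictly positive
    (minimum ``1 / (1 + n)``).  ``include_observed=False`` gives the plain
    ``k / n`` count.  ``tails='two'`` compares magnitudes; ``'one'`` tests
    in the direction of the observed sign; ``'greater'``/``'less'`` fix the
    direction explicitly.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 1:
        raise ValueError("need at least one null value")
    if not np.isfinite(nulls).all() or not np.isfinite(observed):
        raise ValueError("non-finite value among observed/null statistics")
    if tails == "two":
        k = int(np.sum(np.abs(nulls) >= np.abs(observed)))
    elif tails == "greater" or (tails == "one" and observed >= 0):
        k = int(np.sum(nulls >= observed))
    elif tails == "less" or tails == "one":
        k = int(np.sum(nulls <= observed))
    else:
        raise ValueError("tails must be 'two', 'one', 'greater' or 'less'")
    if include_observed:
        return (1 + k) / (1 + nulls.size)
    return k / nulls.size


def spin_label_means(
    values: np.ndarray,
    labels: np.ndarray,
    spins: SpinNulls,
    tails: str = "two",
    include_observed: bool = True,
) -> pd.DataFrame:
    """Observed mean per label with a spin p-value for each.

    The null distribution of a label's mean is obtained by re-labelling the
    regions with each spun label vector and recomputing the mean, i.e. the
    labels are permuted while the map (and its spatial autocorrelation)
    stays fixed.  With ``method='nearest'`` a label can vanish from a spun
    labelling; such spins are skipped for that label and the p-value
    denominator shrinks accordingly (logged).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape or values.shape != (spins.n_regions,):
        raise ValueError("values/labels length must match spin table")
    spun_labels = labels[spins.assignment]  # (S, n)
    rows = []
    for label in pd.unique(labels):
        obs_mask = labels == label
        observed = float(values[obs_mask].mean())
        null_mask = spun_labels == label
        counts = null_mask.sum(axis=1)
        valid = counts > 0
        if not valid.all():
            logger.warning(
                "label %r absent from %d/%d spins; those spins skipped",
                label, int((~valid).sum()), spins.n_spins,
            )
        nulls = (values[None, :] * null_mask[valid]).sum(axis=1) / counts[valid]
        rows.append(
            {
                "label": label,
                "n_regions": int(obs_mask.sum()),
                "mean": observed,
                "p_spin": spin_pvalue(observed, nulls, tails, include_observed),
                "n_spins_used": int(valid.sum()),
            }
        )
    return pd.DataFrame(rows)
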