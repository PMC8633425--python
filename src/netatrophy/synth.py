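"""Synthetic atlases, connectomes, cohorts and expression data.

The generator emulates the statistical structure that the analysis pipeline
assumes: spatially embedded parcels on a sphere, a distance-dependent
structural connectome with a correlated functional matrix, age/sex-dependent
regional deformation with longitudinal atrophy produced by spreading on the
structural network, and spatially autocorrelated gene expression with
planted cell-class gradients and planted enriched annotation terms.  Every
planted effect is recorded so that downstream recovery tests can check the
pipeline against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.csgraph

from .datatypes import (
    CORTICAL_TYPES,
    SESSION_YEARS,
    SESSIONS,
    CohortParams,
    CohortTable,
    Connectome,
    ParcelAtlas,
    SpreadParams,
    as_rng,
    child_seeds,
)

logger = logging.getLogger(__name__)

YEO7_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

#: Cell classes of the virtual-histology analysis.
CELL_CLASSES = ("astro", "endo", "micro", "neuro-ex", "neuro-in", "oligo", "opc")


def _hemisphere_lattice(n: int) -> np.ndarray:
    """Fibonacci lattice of ``n`` points on the x < 0 unit hemisphere."""
    i = np.arange(n)
    # area-uniform polar angle around the -x axis; azimuth by golden angle
    cos_theta = 1.0 - (i + 0.5) / n  # in (0, 1): strictly inside hemisphere
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    x = -cos_theta
    y = sin_theta * np.cos(phi)
    z = sin_theta * np.sin(phi)
    return np.column_stack([x, y, z])


def make_atlas(n_per_hemisphere: int, n_networks: int = 7, seed=None) -> ParcelAtlas:
    """Mirror-symmetric synthetic atlas on the unit sphere.

    Left-hemisphere parcels sit on a Fibonacci lattice covering the x < 0
    hemisphere; right-hemisphere parcels are their sagittal reflections.
    Network labels form spatially contiguous patches (nearest of
    ``n_networks`` seed parcels, mirrored across hemispheres) and cortical
    types are a latitude gradient quantised into the four hierarchy classes.
    """
    if n_per_hemisphere < 4:
        raise ValueError("n_per_hemisphere must be >= 4")
    if n_networks > n_per_hemisphere:
        raise ValueError("n_networks cannot exceed n_per_hemisphere")
    rng = as_rng(seed)
    left = _hemisphere_lattice(n_per_hemisphere)
    right = left * np.array([-1.0, 1.0, 1.0])

    seeds = rng.choice(n_per_hemisphere, size=n_networks, replace=False)
    sim = left @ left[seeds].T  # cosine similarity to each network seed
    net_idx = np.argmax(sim, axis=1)
    if n_networks == 7:
        net_names = np.array(YEO7_NAMES, dtype=object)
    else:
        net_names = np.array([f"net{k + 1:02d}" for k in range(n_networks)], dtype=object)
    network_one = net_names[net_idx]

    # latitude gradient: equal-count bands from inferior to superior
    order = np.argsort(np.argsort(left[:, 2]))  # rank of z within hemisphere
    bands = (order * 4) // n_per_hemisphere
    ctype_one = np.array(CORTICAL_TYPES, dtype=object)[bands]

    coords = np.vstack([left, right])
    region_ids = np.array(
        [f"L_{i + 1:03d}" for i in range(n_per_hemisphere)]
        + [f"R_{i + 1:03d}" for i in range(n_per_hemisphere)],
        dtype=object,
    )
    hemisphere = np.array(["L"] * n_per_hemisphere + ["R"] * n_per_hemisphere, dtype=object)
    return ParcelAtlas(
        region_ids=region_ids,
        hemisphere=hemisphere,
        coords=coords,
        network=np.concatenate([network_one, network_one]),
        cortical_type=np.concatenate([ctype_one, ctype_one]),
    )


def _normalized_communicability(adj: np.ndarray) -> np.ndarray:
    """Degree-normalised communicability: expm(A) scaled by sqrt(G_ii G_jj)."""
    g = scipy.linalg.expm(adj)
    d = np.sqrt(np.diag(g))
    out = g / np.outer(d, d)
    np.fill_diagonal(out, 0.0)
    return out


def make_connectome(
    atlas: ParcelAtlas,
    target_density: float = 0.15,
    decay_length: float = 1.0,
    fc_noise_sd: float = 0.1,
    seed=None,
    max_tries: int = 10,
) -> Connectome:
    """Distance-dependent structural graph plus a correlated functional matrix.

    Structural edges are sampled with probability proportional to
    ``exp(-d / decay_length)`` (``d`` = great-circle distance in radians),
    rescaled so the expected density matches ``target_density``.  Sampling is
    repeated (up to ``max_tries``) until the realised density is within +/-10%
    of the target and the graph is connected.  The functional matrix is the
    degree-normalised communicability of the structural graph plus symmetric
    Gaussian noise, rescaled into [-1, 1] with zero diagonal.
    """
    if not 0 < target_density < 1:
        raise ValueError("target_density must be in (0, 1)")
    rng = as_rng(seed)
    n = atlas.n_regions
    d = atlas.great_circle_distances()
    iu = np.triu_indices(n, k=1)
    kernel = np.exp(-d[iu] / decay_length)
    # fixed-point scaling of edge probabilities so E[density] == target
    scale = target_density / kernel.mean()
    for _ in range(50):
        p = np.minimum(1.0, scale * kernel)
        mean_p = p.mean()
        if abs(mean_p - target_density) < 1e-12:
            break
        scale *= target_density / mean_p
    for _ in range(max_tries):
        upper = rng.random(len(kernel)) < p
        adj = np.zeros((n, n))
        adj[iu] = upper.astype(float)
        adj = adj + adj.T
        density = adj.sum() / (n * (n - 1))
        if abs(density - target_density) > 0.1 * target_density:
            continue
        n_comp, _ = scipy.sparse.csgraph.connected_components(adj, directed=False)
        if n_comp == 1:
            break
    else:
        raise RuntimeError(
            "could not sample a connected graph at the requested density; "
            "increase target_density or decay_length"
        )
    fc = _normalized_communicability(adj)
    if fc_noise_sd > 0:
        noise = rng.normal(0.0, fc_noise_sd, size=(n, n))
        noise = 0.5 * (noise + noise.T)
        np.fill_diagonal(noise, 0.0)
        fc = fc + noise
    peak = np.max(np.abs(fc))
    if peak > 0:
        fc = fc / peak
    np.fill_diagonal(fc, 0.0)
    return Connectome(sc=adj, fc=fc)


def simulate_spread(
    sc: np.ndarray, params: SpreadParams, atlas: ParcelAtlas | None = None
) -> np.ndarray:
    """Accumulate pathological load by spreading on the structural network.

    Starting from unit load on the seed regions, each step adds
    ``eta * vulnerability_i * sum_j A_hat_ij * load_j`` to region *i*, where
    ``A_hat`` is the adjacency row-normalised by the receiving region's
    degree.  The output is element-wise non-decreasing in both ``n_steps``
    and ``eta``; isolated regions keep zero load.
    """
    sc = np.asarray(sc, dtype=float)
    if not np.isfinite(sc).all():
        raise ValueError("structural matrix contains NaN/inf")
    n = sc.shape[0]
    seeds = params.seed_regions
    if len(seeds) and isinstance(seeds[0], str):
        if atlas is None:
            raise ValueError("atlas required to resolve seed region ids")
        seed_idx = atlas.index_of(seeds)
    else:
        seed_idx = np.asarray(seeds, dtype=int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= n):
        raise ValueError("seed region index out of range")
    vuln = params.vulnerability
    if vuln is None:
        vuln = np.ones(n)
    elif vuln.shape != (n,):
        raise ValueError("vulnerability length must match matrix size")
    deg = sc.sum(axis=1)
    a_hat = np.divide(sc, deg[:, None], out=np.zeros_like(sc), where=deg[:, None] > 0)
    load = np.zeros(n)
    load[seed_idx] = 1.0
    for _ in range(params.n_steps):
        load = load + params.eta * vuln * (a_hat @ load)
    return load


def disease_trajectory(
    sc: np.ndarray, spread: SpreadParams, atlas: ParcelAtlas | None = None
) -> dict[str, np.ndarray]:
    """Normalised atrophy-deficit map per follow-up session.

    The spread process is evaluated at ``n_steps * years`` steps for each
    follow-up; each map is normalised to unit peak (the accumulation model
    grows multiplicatively, so raw magnitudes are not comparable across
    horizons) and scaled by ``years / 4`` so the deficit amplitude grows
    linearly over the study while the spatial pattern evolves with the
    spread.
    """
    followups = [s for s in SESSIONS if s != "baseline"]
    out = {}
    for s in followups:
        sp = SpreadParams(
            seed_regions=spread.seed_regions,
            eta=spread.eta,
            n_steps=spread.n_steps * SESSION_YEARS[s],
            vulnerability=spread.vulnerability,
        )
        load = simulate_spread(sc, sp, atlas)
        peak = load.max()
        if peak > 0:
            load = load / peak
        out[s] = load * (SESSION_YEARS[s] / 4.0)
    return out


def make_cohort(
    atlas: ParcelAtlas,
    sc: np.ndarray,
    params: CohortParams,
    spread: SpreadParams,
    seed=None,
) -> CohortTable:
    """Simulate the longitudinal imaging cohort.

    Healthy controls are scanned at baseline only (they serve purely as the
    normative reference); patients are scanned at baseline, 1, 2 and 4
    years.  Every scan draws deformation = intercept + beta_age*age +
    beta_sex*sex + subject effect + site effect + noise; patient follow-ups
    additionally subtract ``disease_effect_scale * noise_sd`` times the
    normalised network-spread deficit of :func:`disease_trajectory` (peak
    deficit at 4 years = ``disease_effect_scale * noise_sd``).  Ages
    advance with the sessions.
    """
    rng = as_rng(seed)
    n_regions = atlas.n_regions
    if params.n_hc < 4:
        raise ValueError("need at least 4 healthy controls")

    spread_by_session = disease_trajectory(sc, spread, atlas)

    site_effects = rng.normal(0.0, params.site_sd, size=(params.n_sites, n_regions))

    def draw_subjects(n_subj: int):
        ages = rng.uniform(*params.age_range, size=n_subj)
        sexes = (rng.random(n_subj) < params.sex_ratio).astype(int)
        sites = rng.integers(params.n_sites, size=n_subj)
        subj_fx = rng.normal(0.0, params.subject_sd, size=(n_subj, n_regions))
        return ages, sexes, sites, subj_fx

    rows, value_rows = [], []

    def add_scan(sid, group, session, age, sex, site, base_fx, deficit):
        expected = params.beta_intercept + params.beta_age * age + params.beta_sex * sex
        noise = rng.normal(0.0, params.noise_sd, size=n_regions)
        vals = expected + base_fx + site_effects[site] + noise - deficit
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "session": session,
                "age": age,
                "sex": sex,
                "site": f"site{site + 1}",
            }
        )
        value_rows.append(vals)

    ages, sexes, sites, subj_fx = draw_subjects(params.n_hc)
    for i in range(params.n_hc):
        add_scan(f"HC{i + 1:04d}", "HC", "baseline", ages[i], sexes[i], sites[i], subj_fx[i], 0.0)

    ages, sexes, sites, subj_fx = draw_subjects(params.n_pd)
    zero = np.zeros(n_regions)
    for i in range(params.n_pd):
        for session in SESSIONS:
            years = SESSION_YEARS[session]
            deficit = (
                zero
                if session == "baseline"
                else params.disease_effect_scale * params.noise_sd * spread_by_session[session]
            )
            add_scan(
                f"PD{i + 1:04d}",
                "PD",
                session,
                ages[i] + years,
                sexes[i],
                sites[i],
                subj_fx[i],
                deficit,
            )

    demo = pd.DataFrame(rows)
    return CohortTable(demo, np.array(value_rows), atlas.region_ids)


@dataclass
class ExpressionBundle:
    """Synthetic regional expression plus the gene sets planted into it."""

    expr: pd.DataFrame  # regions x genes, z-scored per gene
    cell_sets: dict[str, list[str]]
    annotation: dict[str, list[str]]
    class_latents: pd.DataFrame  # regions x cell classes (ground-truth gradients)
    planted_genes: list[str]
    planted_term: str
    control_term: str


def _smooth_fields(chol: np.ndarray, rng: np.random.Generator, n_fields: int) -> np.ndarray:
    """Draw ``n_fields`` unit-variance Gaussian fields with kernel chol @ chol.T."""
    return chol @ rng.standard_normal((chol.shape[0], n_fields))


def make_expression(
    atlas: ParcelAtlas,
    n_genes: int = 1000,
    lengthscale: float = 0.5,
    seed=None,
    class_names: tuple[str, ...] = CELL_CLASSES,
    class_size: int = 20,
    class_mixing: float = 0.6,
    planted_map: np.ndarray | None = None,
    n_planted: int = 50,
    planted_mixing: float = 0.7,
    white_noise_sd: float = 0.4,
    n_random_terms: int = 18,
    term_size: int = 15,
    class_latents: pd.DataFrame | None = None,
) -> ExpressionBundle:
    """Spatially autocorrelated expression with planted structure.

    Each gene is a Gaussian field on the sphere with squared-exponential
    kernel ``exp(-d^2 / (2 * lengthscale^2))`` plus white noise, z-scored
    per gene across regions.  Genes belonging to a cell class share a class
    latent field (mixing weight ``class_mixing``); if ``planted_map`` is
    given, ``n_planted`` extra genes track it (weight ``planted_mixing``)
    and one annotation term is drawn from them (positive control) alongside
    one random term (negative control) and ``n_random_terms`` filler terms.
    """
    if n_genes < 20:
        raise ValueError("n_genes must be >= 20")
    n_regions = atlas.n_regions
    rng = as_rng(seed)
    n_class_genes = class_size * len(class_names)
    if planted_map is not None and n_planted > n_genes:
        raise ValueError("planted gene set larger than n_genes")
    n_plant = n_planted if planted_map is not None else 0
    if n_class_genes + n_plant > n_genes:
        raise ValueError("planted sets larger than n_genes")

    if lengthscale > 1e-6:
        dmat = atlas.great_circle_distances()
        kernel = np.exp(-(dmat**2) / (2.0 * lengthscale**2))
        kernel[np.diag_indices(n_regions)] += 1e-8
        chol = np.linalg.cholesky(kernel)
    else:
        chol = np.eye(n_regions)

    if class_latents is None:
        latents = _smooth_fields(chol, rng, len(class_names))
        class_latents = pd.DataFrame(latents, columns=list(class_names))
    else:
        if list(class_latents.columns) != list(class_names):
            raise ValueError("class_latents columns must match class_names")
        latents = class_latents.to_numpy(dtype=float)

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    own = _smooth_fields(chol, rng, n_genes)
    smooth = own.copy()

    cell_sets: dict[str, list[str]] = {}
    cursor = 0
    for k, cname in enumerate(class_names):
        cols = slice(cursor, cursor + class_size)
        smooth[:, cols] = (
            np.sqrt(class_mixing) * latents[:, [k]]
            + np.sqrt(1.0 - class_mixing) * own[:, cols]
        )
        cell_sets[cname] = gene_ids[cursor : cursor + class_size]
        cursor += class_size

    planted_genes: list[str] = []
    if planted_map is not None:
        m = np.asarray(planted_map, dtype=float)
        if m.shape != (n_regions,):
            raise ValueError("planted_map length must match atlas size")
        m = (m - m.mean()) / m.std()
        cols = slice(cursor, cursor + n_plant)
        smooth[:, cols] = (
            np.sqrt(planted_mixing) * m[:, None]
            + np.sqrt(1.0 - planted_mixing) * own[:, cols]
        )
        planted_genes = gene_ids[cursor : cursor + n_plant]
        cursor += n_plant

    values = smooth + white_noise_sd * rng.standard_normal((n_regions, n_genes))
    values = (values - values.mean(axis=0)) / values.std(axis=0)
    expr = pd.DataFrame(values, index=list(atlas.region_ids), columns=gene_ids)

    # annotation GMT: one positive control drawn from the planted genes,
    # one size-matched random negative control, plus filler terms
    annotation: dict[str, list[str]] = {}
    planted_term = "term_planted"
    control_term = "term_random"
    non_planted = [g for g in gene_ids if g not in set(planted_genes)]
    if planted_genes:
        k = min(term_size, len(planted_genes))
        annotation[planted_term] = list(rng.choice(planted_genes, size=k, replace=False))
    annotation[control_term] = list(rng.choice(non_planted, size=term_size, replace=False))
    for t in range(n_random_terms):
        size = int(rng.integers(10, 31))
        annotation[f"term_bg{t + 1:02d}"] = list(rng.choice(gene_ids, size=size, replace=False))

    return ExpressionBundle(
        expr=expr,
        cell_sets=cell_sets,
        annotation=annotation,
        class_latents=class_latents,
        planted_genes=planted_genes,
        planted_term=planted_term if planted_genes else "",
        control_term=control_term,
    )


@dataclass
class SyntheticStudy:
    """A complete synthetic study with ground truth for recovery tests."""

    atlas: ParcelAtlas
    connectome: Connectome
    cohort: CohortTable
    expression: ExpressionBundle
    spread_by_session: dict[str, np.ndarray]
    vulnerability: np.ndarray
    seed_regions: list[str]
    protected_class: str


def default_seed_regions(atlas: ParcelAtlas) -> list[str]:
    """One paralimbic epicentre per hemisphere (lowest region index)."""
    out = []
    for hemi in ("L", "R"):
        idx = np.flatnonzero((atlas.hemisphere == hemi) & (atlas.cortical_type == "paralimbic"))
        if len(idx) == 0:  # tiny atlases: fall back to first region of the hemisphere
            idx = atlas.hemi_indices(hemi)
        out.append(str(atlas.region_ids[idx[0]]))
    return out


def make_dataset(
    seed: int = 0,
    n_per_hemisphere: int = 110,
    n_networks: int = 7,
    target_density: float = 0.15,
    decay_length: float = 1.0,
    fc_noise_sd: float = 0.1,
    n_genes: int = 1000,
    expression_lengthscale: float = 0.5,
    protect_gamma: float = 1.5,
    protected_class: str = "endo",
    eta: float = 0.3,
    steps_per_year: int = 2,
    planted_session: str = "y4",
    cohort_params: CohortParams | None = None,
) -> SyntheticStudy:
    """Generate a full synthetic study with linked planted effects.

    The protective cell-class effect enters through regional vulnerability
    ``exp(-protect_gamma * latent)`` of the protected class, so regions rich
    in that class accrue less atrophy; the planted annotation term is drawn
    from genes that track the 2-year spread pattern.
    """
    seeds = child_seeds(seed, 5)
    cohort_params = cohort_params or CohortParams()
    atlas = make_atlas(n_per_hemisphere, n_networks, seed=seeds[0])
    conn = make_connectome(
        atlas, target_density=target_density, decay_length=decay_length,
        fc_noise_sd=fc_noise_sd, seed=seeds[1],
    )

    # class gradients first: vulnerability is tied to the protected class
    if expression_lengthscale > 1e-6:
        dmat = atlas.great_circle_distances()
        kernel = np.exp(-(dmat**2) / (2.0 * expression_lengthscale**2))
        kernel[np.diag_indices(atlas.n_regions)] += 1e-8
        chol = np.linalg.cholesky(kernel)
    else:
        chol = np.eye(atlas.n_regions)
    latent_rng = as_rng(seeds[2])
    latents = _smooth_fields(chol, latent_rng, len(CELL_CLASSES))
    class_latents = pd.DataFrame(latents, columns=list(CELL_CLASSES))
    protect = class_latents[protected_class].to_numpy()
    vulnerability = np.exp(-protect_gamma * (protect - protect.mean()) / protect.std())

    seed_regions = default_seed_regions(atlas)
    spread = SpreadParams(
        seed_regions=seed_regions, eta=eta, n_steps=steps_per_year,
        vulnerability=vulnerability,
    )
    cohort = make_cohort(atlas, conn.sc, cohort_params, spread, seed=seeds[3])

    spread_by_session = disease_trajectory(conn.sc, spread, atlas)

    expression = make_expression(
        atlas,
        n_genes=n_genes,
        lengthscale=expression_lengthscale,
        seed=seeds[4],
        class_latents=class_latents,
        planted_map=spread_by_session[planted_session],
    )
    return SyntheticStudy(
        atlas=atlas,
        connectome=conn,
        cohort=cohort,
        expression=expression,
        spread_by_session=spread_by_session,
        vulnerability=vulnerability,
        seed_regions=seed_regions,
        protected_class=protected_class,
    )
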