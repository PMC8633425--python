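"""Core data containers for parcel-level atrophy-network analysis.

Everything downstream of image processing operates on parcellated maps: a
brain is a fixed, ordered list of regions, each with a position on the unit
sphere (used by the rotation-based null model), a hemisphere, a resting-state
network label and a cortical-type label.  All matrices and value vectors in
the package are keyed to the region order of a :class:`ParcelAtlas`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")
CORTICAL_TYPES = ("paralimbic", "heteromodal", "unimodal", "idiotypic")
SESSIONS = ("baseline", "y1", "y2", "y4")
#: Follow-up interval of each session in years (used to scale disease spread).
SESSION_YEARS = {"baseline": 0, "y1": 1, "y2": 2, "y4": 4}
GROUPS = ("PD", "HC")

UNIT_NORM_TOL = 1e-9


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` reproducible child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class ParcelAtlas:
    """Ordered cortical parcellation with spherical coordinates and labels.

    Parameters
    ----------
    region_ids:
        Unique region names, one per parcel.
    hemisphere:
        ``"L"`` or ``"R"`` per region.
    coords:
        ``(n, 3)`` region centroids on the unit sphere (spherical projection
        of the cortical surface); every row must have unit Euclidean norm.
    network:
        Resting-state network label per region (e.g. the seven canonical
        cortical networks).
    cortical_type:
        Cortical hierarchy class per region, one of
        ``paralimbic / heteromodal / unimodal / idiotypic``.
    """

    region_ids: np.ndarray
    hemisphere: np.ndarray
    coords: np.ndarray
    network: np.ndarray
    cortical_type: np.ndarray

    def __post_init__(self):
        self.region_ids = np.asarray(self.region_ids, dtype=object)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.network = np.asarray(self.network, dtype=object)
        self.cortical_type = np.asarray(self.cortical_type, dtype=object)
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region_id in atlas")
        for arr, name in [
            (self.hemisphere, "hemisphere"),
            (self.network, "network"),
            (self.cortical_type, "cortical_type"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length does not match region_ids")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_regions, 3)")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere code(s): {sorted(bad)}")
        bad = set(self.cortical_type) - set(CORTICAL_TYPES)
        if bad:
            raise ValueError(f"unknown cortical type(s): {sorted(bad)}")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
            raise ValueError("centroids must lie on the unit sphere")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def index_of(self, region_ids: Sequence[str]) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.region_ids)}
        try:
            return np.array([lookup[r] for r in region_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"region id not in atlas: {exc.args[0]}") from None

    def great_circle_distances(self) -> np.ndarray:
        """Pairwise great-circle distances (radians) between centroids."""
        cosines = np.clip(self.coords @ self.coords.T, -1.0, 1.0)
        return np.arccos(cosines)


@dataclass
class CohortTable:
    """Per-scan demographics plus a regional deformation vector.

    ``demographics`` has one row per (subject, session) with columns
    ``subject_id, group, session, age, sex, site``; ``values`` holds the
    matching ``(n_rows, n_regions)`` deformation (or W-score) matrix in
    atlas region order.  Sex is coded 0 = female, 1 = male.
    """

    demographics: pd.DataFrame
    values: np.ndarray
    region_ids: np.ndarray

    DEMO_COLUMNS = ("subject_id", "group", "session", "age", "sex", "site")

    def __post_init__(self):
        self.demographics = self.demographics.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=object)
        missing = set(self.DEMO_COLUMNS) - set(self.demographics.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.values.shape != (len(self.demographics), len(self.region_ids)):
            raise ValueError("values shape does not match demographics/regions")
        keys = list(
            zip(self.demographics["subject_id"], self.demographics["session"])
        )
        if len(set(keys)) != len(keys):
            raise ValueError("(subject_id, session) pairs must be unique")
        bad = set(self.demographics["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        bad = set(self.demographics["session"]) - set(SESSIONS)
        if bad:
            raise ValueError(f"unknown session label(s): {sorted(bad)}")
        if (self.demographics["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad = set(self.demographics["sex"]) - {0, 1}
        if bad:
            raise ValueError("sex must be coded 0/1")

    @property
    def n_rows(self) -> int:
        return len(self.demographics)

    def subset(self, group: str | None = None, session: str | None = None) -> "CohortTable":
        mask = np.ones(self.n_rows, dtype=bool)
        if group is not None:
            mask &= (self.demographics["group"] == group).to_numpy()
        if session is not None:
            mask &= (self.demographics["session"] == session).to_numpy()
        return CohortTable(
            self.demographics.loc[mask].reset_index(drop=True),
            self.values[mask],
            self.region_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: demographic columns then one column per region."""
        vals = pd.DataFrame(self.values, columns=list(self.region_ids))
        return pd.concat([self.demographics.reset_index(drop=True), vals], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, region_ids: Sequence[str]) -> "CohortTable":
        region_ids = list(region_ids)
        missing = [r for r in region_ids if r not in frame.columns]
        if missing:
            raise ValueError(f"cohort table missing region column(s): {missing[:5]}")
        demo = frame[list(cls.DEMO_COLUMNS)].copy()
        return cls(demo, frame[region_ids].to_numpy(dtype=float), np.array(region_ids, dtype=object))


@dataclass
class Connectome:
    """Structural and functional connectivity over a fixed region order.

    ``sc`` is a symmetric non-negative (binary or weighted) structural
    adjacency; ``fc`` is a symmetric functional weight matrix in [-1, 1].
    Diagonals are zero; both matrices share the atlas region order.
    """

    sc: np.ndarray
    fc: np.ndarray

    SYM_TOL = 1e-8

    def __post_init__(self):
        self.sc = self._check(np.asarray(self.sc, dtype=float), "structural")
        self.fc = self._check(np.asarray(self.fc, dtype=float), "functional")
        if self.sc.shape != self.fc.shape:
            raise ValueError("sc and fc must have the same shape")
        if np.any(self.sc < 0):
            raise ValueError("structural adjacency must be non-negative")
        if np.any(np.abs(self.fc) > 1 + self.SYM_TOL):
            raise ValueError("functional weights must lie in [-1, 1]")
        self.fc = np.clip(self.fc, -1.0, 1.0)

    @classmethod
    def _check(cls, m: np.ndarray, kind: str) -> np.ndarray:
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"{kind} matrix must be square")
        if not np.isfinite(m).all():
            raise ValueError(f"{kind} matrix contains non-finite values")
        if np.max(np.abs(m - m.T)) > cls.SYM_TOL:
            raise ValueError(f"{kind} matrix is asymmetric beyond tolerance")
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        return m

    @property
    def n_regions(self) -> int:
        return self.sc.shape[0]


@dataclass
class WScoreModel:
    """Per-region normative regression of deformation on age and sex.

    For region *i* the expected deformation of a participant is
    ``beta_age[i] * age + beta_sex[i] * sex + beta_intercept[i]`` and the
    W-score divides the residual by ``resid_sd[i]``, the standard deviation
    of the control residuals (denominator n - 3).
    """

    region_ids: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    beta_intercept: np.ndarray
    resid_sd: np.ndarray
    n_controls: int

    def __post_init__(self):
        self.region_ids = np.asarray(self.region_ids, dtype=object)
        for name in ("beta_age", "beta_sex", "beta_intercept", "resid_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.region_ids.shape:
                raise ValueError(f"{name} length must match region_ids")
        if self.n_controls < 4:
            raise ValueError("normative model needs at least 4 controls")
        if np.any(self.resid_sd <= 0):
            raise ValueError("resid_sd must be positive in every region")


@dataclass
class SpinNulls:
    """Precomputed rotation-based null assignments.

    ``assignment`` has shape ``(n_spins, n_regions)``; row *s* maps each
    region index to the source region whose rotated centroid lands nearest
    (method ``nearest``) or to its optimal one-to-one match (``bijective``).
    Spun maps are ``values[assignment]``.
    """

    assignment: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 2:
            raise ValueError("assignment must be 2-D (n_spins, n_regions)")
        n = self.assignment.shape[1]
        if self.assignment.min() < 0 or self.assignment.max() >= n:
            raise ValueError("assignment entries must be valid region indices")
        if self.method not in ("nearest", "bijective"):
            raise ValueError("method must be 'nearest' or 'bijective'")
        if self.method == "bijective":
            expected = np.arange(n)
            if not np.all(np.sort(self.assignment, axis=1) == expected):
                raise ValueError("bijective assignment rows must be permutations")

    @property
    def n_spins(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_regions(self) -> int:
        return self.assignment.shape[1]


@dataclass
class SpreadParams:
    """Parameters of the network spreading process used by the generator.

    The process accumulates a pathological load along structural
    connections: at each step region *i* gains
    ``eta * vulnerability_i * sum_j A_hat_ij * load_j`` where ``A_hat`` is
    the adjacency row-normalised by the receiving region's degree.
    """

    seed_regions: Sequence
    eta: float = 0.3
    n_steps: int = 2
    vulnerability: np.ndarray | None = None

    def __post_init__(self):
        if len(self.seed_regions) == 0:
            raise ValueError("seed_regions must be non-empty")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.vulnerability is not None:
            self.vulnerability = np.asarray(self.vulnerability, dtype=float)
            if np.any(self.vulnerability <= 0):
                raise ValueError("vulnerability multipliers must be > 0")


@dataclass
class CohortParams:
    """Generative settings for the synthetic imaging cohort.

    Defaults mirror a longitudinal de-novo Parkinson's design: 157 healthy
    controls scanned at baseline only and 74 patients scanned at baseline
    and 1, 2 and 4 years, with a male-dominated sex ratio.  Deformation is a
    linear function of age and sex plus subject, site and scan noise;
    patient follow-ups additionally lose ``disease_effect_scale * noise_sd``
    times the (normalised) network-spread load.
    """

    n_hc: int = 157
    n_pd: int = 74
    age_range: tuple[float, float] = (45.0, 80.0)
    sex_ratio: float = 0.7
    beta_age: float = -0.005
    beta_sex: float = 0.03
    beta_intercept: float = 1.0
    noise_sd: float = 0.08
    subject_sd: float = 0.05
    site_sd: float = 0.02
    n_sites: int = 3
    disease_effect_scale: float = 1.5

    def __post_init__(self):
        if self.n_hc < 4:
            raise ValueError("need at least 4 healthy controls")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("invalid age_range")
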