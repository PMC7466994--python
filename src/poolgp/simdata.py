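"""Synthetic genebank collections with isolation-by-distance structure.

Generates the three data layers the downstream analyses consume:

* a panel of populations with geographic coordinates,
* a population x marker allele-frequency matrix whose spatial genetic
  structure (isolation by distance), rare-allele-skewed frequency spectrum
  and within-scaffold correlation decay are all tunable,
* balanced multi-environment complete-block phenotypes driven by planted
  QTL, with genotype-by-environment interaction.

Frequencies are built on the logit scale as a zero-mean Gaussian field with
a separable covariance: an exponential distance-decay kernel across
populations (range ``ibd_range_km``, mixed with a white-noise nugget) and,
within each scaffold, an exponential bp-distance kernel between markers
(length ``within_scaffold_corr``).  Adding the field to a rare-allele-skewed
ancestral logit and applying the inverse logit guarantees frequencies in
(0, 1) while producing the three target summary statistics.

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from poolgp.dataio import AlleleFrequencyMatrix, PhenotypeRecords
from poolgp.spatialstats import haversine_m

#: Default IBD field parameters, calibrated once by bisection so that the
#: Mantel correlation between genetic and geographic distances on the
#: reference configuration (200 populations in a Europe-like bounding box,
#: 2000 markers) lands near 0.44 — the degree of spatial genetic structure
#: this collection type exhibits.
DEFAULT_IBD_RANGE_KM = 550.0
DEFAULT_SPATIAL_WEIGHT = 0.3
DEFAULT_LOGIT_SD = 1.2

EUROPE_BBOX = (-10.0, 35.0, 30.0, 62.0)  # lon_min, lat_min, lon_max, lat_max


@dataclass
class PopulationPanel:
    """Labelled populations with geographic origin coordinates."""

    pop_ids: list[str]
    lon: np.ndarray
    lat: np.ndarray
    is_cultivar: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.pop_ids = [str(p) for p in self.pop_ids]
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = len(self.pop_ids)
        if n < 2:
            raise ValueError("panel needs at least 2 populations")
        if len(set(self.pop_ids)) != n:
            raise ValueError("duplicated pop_ids")
        if self.lon.shape != (n,) or self.lat.shape != (n,):
            raise ValueError("lon/lat length mismatch")
        if not (np.isfinite(self.lon).all() and np.isfinite(self.lat).all()):
            raise ValueError("non-finite coordinates")
        if np.any(np.abs(self.lon) > 180) or np.any(np.abs(self.lat) > 90):
            raise ValueError("coordinates outside valid lon/lat ranges")
        if self.is_cultivar is None:
            self.is_cultivar = np.zeros(n, dtype=bool)
        else:
            self.is_cultivar = np.asarray(self.is_cultivar, dtype=bool)
            if self.is_cultivar.shape != (n,):
                raise ValueError("is_cultivar length mismatch")

    @property
    def n(self) -> int:
        return len(self.pop_ids)


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype, for parameter-recovery tests."""

    qtl_marker_ids: list[str]
    qtl_effects: np.ndarray
    h2_pop: float
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    ibd_range_km: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_pop <= 1.0:
            raise ValueError("h2_pop must be in [0, 1]")
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)
        if not np.isfinite(self.qtl_effects).all():
            raise ValueError("non-finite QTL effects")


def generate_panel(
    n_pops: int,
    bbox: tuple[float, float, float, float] = EUROPE_BBOX,
    seed: int = 0,
    n_cultivars: int = 0,
) -> PopulationPanel:
    """Scatter *n_pops* populations uniformly at random inside *bbox*.

    *bbox* is (lon_min, lat_min, lon_max, lat_max) in decimal degrees.  The
    last *n_cultivars* populations are flagged as cultivars (external
    prediction targets); by default none are.
    """
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    lon_min, lat_min, lon_max, lat_max = map(float, bbox)
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("degenerate bounding box")
    if not (0 <= n_cultivars < n_pops):
        raise ValueError("n_cultivars must be in [0, n_pops)")
    rng = np.random.default_rng(seed)
    lon = rng.uniform(lon_min, lon_max, size=n_pops)
    lat = rng.uniform(lat_min, lat_max, size=n_pops)
    width = max(2, len(str(n_pops)))
    ids = [f"pop{str(i + 1).zfill(width)}" for i in range(n_pops)]
    is_cult = np.zeros(n_pops, dtype=bool)
    if n_cultivars:
        is_cult[-n_cultivars:] = True
    return PopulationPanel(pop_ids=ids, lon=lon, lat=lat, is_cultivar=is_cult)


def _population_kernel(panel: PopulationPanel, ibd_range_km: float, spatial_weight: float) -> np.ndarray:
    """Unit-diagonal population covariance: spatial exponential + nugget."""
    n = panel.n
    if ibd_range_km == 0.0 or spatial_weight == 0.0:
        return np.eye(n)
    d_km = (
        haversine_m(
            panel.lon[:, None], panel.lat[:, None], panel.lon[None, :], panel.lat[None, :]
        )
        / 1000.0
    )
    K = spatial_weight * np.exp(-d_km / ibd_range_km) + (1.0 - spatial_weight) * np.eye(n)
    # exp kernel has unit diagonal; mixing keeps it so
    return K


def _chol(K: np.ndarray) -> np.ndarray:
    jitter = 1e-10 * np.trace(K) / K.shape[0]
    for _ in range(8):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError("covariance kernel not positive definite")


def simulate_frequencies(
    panel: PopulationPanel,
    n_scaffolds: int = 100,
    markers_per_scaffold: int = 20,
    ibd_range_km: float = DEFAULT_IBD_RANGE_KM,
    within_scaffold_corr: float = 10_000.0,
    maf_shape: float = 0.4,
    seed: int = 0,
    spatial_weight: float = DEFAULT_SPATIAL_WEIGHT,
    logit_sd: float = DEFAULT_LOGIT_SD,
    scaffold_length_bp: int = 50_000,
) -> AlleleFrequencyMatrix:
    """Simulate spatially autocorrelated allele frequencies.

    Parameters
    ----------
    ibd_range_km : float
        Range of the exponential spatial covariance of the logit-scale
        field.  0 disables isolation by distance entirely.
    within_scaffold_corr : float
        bp length scale of the exponential marker-marker kernel within a
        scaffold; 0 makes markers independent given the spatial field.
    maf_shape : float
        Shape of the Beta(maf_shape, 1) ancestral frequency, folded to the
        minor allele — small values give a rare-allele-skewed spectrum.
    spatial_weight : float
        Mixing weight of the spatial kernel against the white-noise nugget;
        together with ``logit_sd`` it sets how much of the between-population
        differentiation follows geography.
    """
    if n_scaffolds < 1 or markers_per_scaffold < 1:
        raise ValueError("counts must be positive")
    if ibd_range_km < 0 or within_scaffold_corr < 0:
        raise ValueError("length scales must be >= 0")
    if not 0.0 <= spatial_weight <= 1.0:
        raise ValueError("spatial_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = panel.n
    p = n_scaffolds * markers_per_scaffold

    L_pop = _chol(_population_kernel(panel, ibd_range_km, spatial_weight))

    # ancestral frequencies: Beta(shape, 1) folded to the minor allele,
    # clipped away from 0 so the logit stays finite
    u = rng.beta(maf_shape, 1.0, size=p)
    p_anc = np.clip(np.minimum(u, 1.0 - u), 1e-3, 0.5)
    base_logit = logit(p_anc)

    values = np.empty((n, p))
    marker_ids: list[str] = []
    scaffolds: list[str] = []
    positions = np.empty(p, dtype=int)
    col = 0
    for s in range(n_scaffolds):
        m = markers_per_scaffold
        pos = np.sort(rng.integers(1, scaffold_length_bp + 1, size=m))
        if within_scaffold_corr > 0:
            d_bp = np.abs(pos[:, None] - pos[None, :]).astype(float)
            K_m = np.exp(-d_bp / within_scaffold_corr)
            L_m = _chol(K_m)
        else:
            L_m = np.eye(m)
        E = rng.standard_normal((n, m))
        Z = L_pop @ E @ L_m.T
        values[:, col : col + m] = Z
        positions[col : col + m] = pos
        scaf = f"scaffold_{s + 1:04d}"
        scaffolds.extend([scaf] * m)
        marker_ids.extend(f"{scaf}_snp{k + 1:03d}" for k in range(m))
        col += m

    freqs = expit(base_logit[None, :] + logit_sd * values)
    marker_map = pd.DataFrame(
        {"scaffold": scaffolds, "pos_bp": positions},
        index=pd.Index(marker_ids, name="marker_id"),
    )
    return AlleleFrequencyMatrix(
        pop_ids=list(panel.pop_ids), marker_ids=marker_ids, values=freqs, marker_map=marker_map
    )


def simulate_phenotypes(
    freqs: AlleleFrequencyMatrix,
    n_qtl: int = 50,
    effect_dist: str = "gaussian",
    h2_pop: float = 0.7,
    n_envs: int = 3,
    n_blocks: int = 3,
    gxe_share: float = 0.3,
    seed: int = 0,
    trait: str = "sim_trait",
) -> tuple[PhenotypeRecords, SimTruth]:
    """Simulate balanced complete-block plot phenotypes from planted QTL.

    The population genetic value is ``g_i = sum_q a_q x_iq`` over *n_qtl*
    markers sampled without replacement, standardized to unit variance.
    Plot values follow mu + g_i + env_j + (g x env)_ij + block_jr + e_ijr
    with the interaction and residual variances chosen so that the
    across-environment broad-sense heritability indicator
    sigma_g^2 / (sigma_g^2 + sigma_ge^2/J + sigma_e^2/(J R)) equals
    *h2_pop* in expectation.  *gxe_share* splits the non-genetic variance
    budget between interaction (share) and residual (1 - share).
    """
    if not 0 <= n_qtl <= freqs.n_markers:
        raise ValueError("n_qtl must be between 0 and the number of markers")
    if not (0.0 <= h2_pop <= 1.0 and 0.0 <= gxe_share <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    if n_envs < 1 or n_blocks < 2:
        raise ValueError("need >= 1 environment and >= 2 blocks")
    if np.isnan(freqs.values).any():
        raise ValueError("impute missing frequencies before simulating phenotypes")
    rng = np.random.default_rng(seed)
    n, J, R = freqs.n_pops, int(n_envs), int(n_blocks)

    if n_qtl > 0 and h2_pop > 0.0:
        qtl_idx = np.sort(rng.choice(freqs.n_markers, size=n_qtl, replace=False))
        if effect_dist == "gaussian":
            a = rng.standard_normal(n_qtl)
        elif effect_dist == "exponential":
            a = rng.exponential(1.0, size=n_qtl) * rng.choice([-1.0, 1.0], size=n_qtl)
        else:
            raise ValueError(f"unknown effect_dist {effect_dist!r}")
        g = freqs.values[:, qtl_idx] @ a
        sd = g.std()
        if sd == 0.0:
            g = np.zeros(n)
            scale = 0.0
        else:
            scale = 1.0 / sd
            g = (g - g.mean()) * scale
        qtl_ids = [freqs.marker_ids[q] for q in qtl_idx]
        qtl_effects = a * scale
        sigma_g2 = float(np.var(g))
    else:
        g = np.zeros(n)
        qtl_ids, qtl_effects = [], np.empty(0)
        sigma_g2 = 0.0

    # variance budget from the target heritability indicator
    if sigma_g2 > 0.0 and h2_pop < 1.0:
        T = sigma_g2 * (1.0 - h2_pop) / h2_pop
    elif sigma_g2 > 0.0:
        T = 0.0
    else:
        T = 1.0  # pure-noise trait: unit non-genetic budget
    if J == 1:
        sigma_ge2 = 0.0
        sigma_e2 = T * R
    else:
        denom = gxe_share / J + (1.0 - gxe_share) / (J * R)
        S = T / denom if denom > 0 else 0.0
        sigma_ge2 = gxe_share * S
        sigma_e2 = (1.0 - gxe_share) * S

    mu = 10.0
    env_eff = rng.normal(0.0, 1.0, size=J)
    block_eff = rng.normal(0.0, 0.5, size=(J, R))
    gxe = rng.normal(0.0, np.sqrt(sigma_ge2), size=(n, J)) if sigma_ge2 > 0 else np.zeros((n, J))
    resid = rng.normal(0.0, np.sqrt(sigma_e2), size=(n, J, R)) if sigma_e2 > 0 else np.zeros((n, J, R))

    rows = []
    for j in range(J):
        env = f"env{j + 1}"
        for r in range(R):
            block = f"block{r + 1}"
            y = mu + g + env_eff[j] + gxe[:, j] + block_eff[j, r] + resid[:, j, r]
            for i, pop in enumerate(freqs.pop_ids):
                rows.append((pop, env, block, trait, y[i]))
    records = PhenotypeRecords(
        pd.DataFrame(rows, columns=["pop_id", "env", "block", "trait", "value"])
    )
    truth = SimTruth(
        qtl_marker_ids=qtl_ids,
        qtl_effects=qtl_effects,
        h2_pop=float(h2_pop),
        sigma_g2=sigma_g2,
        sigma_ge2=float(sigma_ge2),
        sigma_e2=float(sigma_e2),
    )
    return records, truth


def inject_missing(
    freqs: AlleleFrequencyMatrix, rate: float, seed: int = 0, max_marker_rate: float = 0.33
) -> AlleleFrequencyMatrix:
    """Mask approximately *rate* of the entries missing, independently.

    Per-marker missingness is capped at *max_marker_rate* (matching the
    0-33% range typical of pooled genotyping), so every marker keeps
    enough observations for mean imputation.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return AlleleFrequencyMatrix(
            pop_ids=list(freqs.pop_ids),
            marker_ids=list(freqs.marker_ids),
            values=freqs.values.copy(),
            marker_map=freqs.marker_map.copy(),
        )
    rng = np.random.default_rng(seed)
    values = freqs.values.copy()
    n = freqs.n_pops
    cap = int(np.floor(max_marker_rate * n))
    mask = rng.random(values.shape) < rate
    for j in range(freqs.n_markers):
        extra = int(mask[:, j].sum()) - cap
        if extra > 0:
            on = np.flatnonzero(mask[:, j])
            off = rng.choice(on, size=extra, replace=False)
            mask[off, j] = False
    values[mask] = np.nan
    return AlleleFrequencyMatrix(
        pop_ids=list(freqs.pop_ids),
        marker_ids=list(freqs.marker_ids),
        values=values,
        marker_map=freqs.marker_map.copy(),
    )


def make_synthetic_cultivars(
    freqs: AlleleFrequencyMatrix, n_cultivars: int, parents_per_cultivar: int = 3, seed: int = 0
) -> tuple[AlleleFrequencyMatrix, list[list[str]]]:
    """Assemble synthetic 'cultivar' frequency rows by averaging parent rows.

    Mimics bred material derived from a few source populations; returns the
    cultivar matrix and the parent ids of each cultivar.
    """
    if n_cultivars < 2:
        raise ValueError("need at least 2 cultivars (matrix invariant)")
    rng = np.random.default_rng(seed)
    rows = []
    parents: list[list[str]] = []
    for c in range(n_cultivars):
        idx = rng.choice(freqs.n_pops, size=parents_per_cultivar, replace=False)
        rows.append(freqs.values[idx].mean(axis=0))
        parents.append([freqs.pop_ids[i] for i in idx])
    ids = [f"cultivar{c + 1:02d}" for c in range(n_cultivars)]
    out = AlleleFrequencyMatrix(
        pop_ids=ids,
        marker_ids=list(freqs.marker_ids),
        values=np.vstack(rows),
        marker_map=freqs.marker_map.copy(),
    )
    return out, parents
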