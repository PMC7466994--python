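"""Calibration-set optimization for genomic prediction.

Phenotyping is the bottleneck when exploiting a genotyped genebank
collection, so the populations to phenotype (the calibration set) should
be chosen well.  Four selection procedures are implemented:

1. stratified sampling after Ward clustering of genetic distances,
2. the same on geographic (great-circle) distances,
3. Ward-like clustering of a blended genetic/geographic dissimilarity
   (mixing parameter alpha, both matrices max-normalized first),
4. CDmean exchange optimization on the relationship matrix.

A selected set is scored against the envelope of random same-size sets:
score = (OptPA - MinPA) / (MaxPA - MinPA), where Min/MaxPA are the extreme
predictive abilities over 100 random sets; 0.5 means halfway between the
worst and best random set, and values outside [0, 1] are possible.

The module also builds GWAS-informed marker sets on calibration data only
(forward fixed-effect inclusion gated by a 5% F-test) and traces
predictive ability against the number of markers in the model, with the
minimum marker count reaching 95% of the curve maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from poolgp.dataio import AlleleFrequencyMatrix
from poolgp.gpredict import _pearson, fit_rrblup, predict
from poolgp.grm import KinshipMatrix
from poolgp.gwas import run_gwas
from poolgp.spatialstats import DistanceMatrix


@dataclass
class CalibrationSet:
    """A selected subset of populations plus selection metadata."""

    pop_ids: list[str]
    method: str  # genetic | spatial | clustgeo | cdmean | random
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.pop_ids)) != len(self.pop_ids):
            raise ValueError("duplicated populations in calibration set")

    @property
    def k(self) -> int:
        return len(self.pop_ids)


@dataclass
class PerformanceScore:
    """Predictive ability of a calibration set against its random envelope."""

    opt_pa: float
    min_pa: float
    max_pa: float
    score: float
    random_pas: np.ndarray = field(repr=False, default=None)


@dataclass
class MarkerCurve:
    """Predictive ability vs number of markers, GWAS-first and random-first."""

    counts: np.ndarray
    pa_gwas_first: np.ndarray
    pa_random_first: np.ndarray
    gwas_set: list[str]
    min_markers_95_gwas: int
    min_markers_95_random: int


def _ward_groups(D: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(squareform(D, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def _representatives(D: np.ndarray, ids: list[str], labels: np.ndarray) -> list[str]:
    """Per group, the member minimizing mean distance to the other members;
    ties break on the lexicographically smallest pop_id."""
    chosen = []
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        if members.size == 1:
            chosen.append(ids[members[0]])
            continue
        sub = D[np.ix_(members, members)]
        mean_d = sub.sum(axis=1) / (members.size - 1)
        best = mean_d.min()
        tied = [ids[members[i]] for i in range(members.size) if mean_d[i] <= best + 1e-12]
        chosen.append(min(tied))
    return sorted(chosen)


def select_by_clustering(D: DistanceMatrix, k: int) -> CalibrationSet:
    """Stratified selection: Ward clustering of D into k groups, then the
    most central member of each group."""
    if not 1 <= k <= D.n:
        raise ValueError(f"k must be in [1, {D.n}]")
    if k == D.n:
        return CalibrationSet(pop_ids=sorted(D.ids), method="genetic" if "genetic" in D.units else "spatial", params={"k": k})
    labels = _ward_groups(D.D, k)
    method = "spatial" if D.units == "meters" else "genetic"
    return CalibrationSet(pop_ids=_representatives(D.D, D.ids, labels), method=method, params={"k": k})


def select_clustgeo(
    D_gen: DistanceMatrix, D_geo: DistanceMatrix, k: int, alpha: float = 0.5
) -> CalibrationSet:
    """Spatially constrained stratified selection.

    Both dissimilarities are max-normalized, their squares blended as
    (1 - alpha) D_gen^2 + alpha D_geo^2 (so Ward pseudo-inertia blends
    linearly), and the Ward tree of the blended dissimilarity is cut at k.
    alpha = 0 reduces to genetic clustering, alpha = 1 to spatial.
    """
    if D_gen.ids != D_geo.ids:
        if set(D_gen.ids) == set(D_geo.ids):
            order = [D_geo.ids.index(i) for i in D_gen.ids]
            D_geo = DistanceMatrix(ids=list(D_gen.ids), D=D_geo.D[np.ix_(order, order)], units=D_geo.units)
        else:
            raise ValueError("mismatched ids between distance matrices")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 1 <= k <= D_gen.n:
        raise ValueError(f"k must be in [1, {D_gen.n}]")
    A = D_gen.D / max(D_gen.D.max(), 1e-300)
    B = D_geo.D / max(D_geo.D.max(), 1e-300)
    Dmix = np.sqrt((1.0 - alpha) * A**2 + alpha * B**2)
    if k == D_gen.n:
        return CalibrationSet(pop_ids=sorted(D_gen.ids), method="clustgeo", params={"k": k, "alpha": alpha})
    labels = _ward_groups(Dmix, k)
    return CalibrationSet(
        pop_ids=_representatives(Dmix, D_gen.ids, labels),
        method="clustgeo",
        params={"k": k, "alpha": alpha},
    )


def _cdmean(G: np.ndarray, Ginv_r: np.ndarray, lam: float, cal: np.ndarray, val: np.ndarray) -> float:
    """Mean CD of unphenotyped populations for calibration index set *cal*.

    CD_i = [G - lam (Z'PZ + lam G_r^-)^{-1}]_ii / G_ii, with Z the
    calibration incidence and P the projection off the intercept.
    """
    k = cal.size
    ZtPZ = np.zeros_like(G)
    # Z'PZ = diag(1_cal) - (1/k) 1_cal 1_cal'
    ZtPZ[cal, cal] = 1.0
    ZtPZ[np.ix_(cal, cal)] -= 1.0 / k
    A = ZtPZ + lam * Ginv_r
    B = np.linalg.inv(A)
    cd = (np.diag(G) - lam * np.diag(B)) / np.diag(G)
    return float(cd[val].mean())


def select_cdmean(
    G: KinshipMatrix,
    k: int,
    lam: float = 1.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> CalibrationSet:
    """CDmean exchange optimization of the calibration set.

    Starts from a random k-subset and, for *n_iter* iterations, proposes
    swapping one random selected population with one random non-selected
    population, accepting only proposals that increase the mean coefficient
    of determination (CD) of the predicted, unphenotyped populations.
    *lam* is the residual-to-genetic variance ratio (1 corresponds to an
    assumed h^2 of 0.5).  The inverse of G is ridge-stabilized
    (1e-6 x mean diagonal) because a pooled-frequency G is often
    rank-deficient.
    """
    n = G.n
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < n")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if np.any(np.diag(G.G) <= 0):
        raise ValueError("G has non-positive diagonal entries")
    rng = np.random.default_rng(seed)
    ridge = 1e-6 * float(np.diag(G.G).mean())
    try:
        Ginv_r = np.linalg.inv(G.G + ridge * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("G singular even after ridge stabilization") from exc
    cal = rng.choice(n, size=k, replace=False)
    in_cal = np.zeros(n, dtype=bool)
    in_cal[cal] = True
    val = np.flatnonzero(~in_cal)
    current = _cdmean(G.G, Ginv_r, lam, np.flatnonzero(in_cal), val)
    trajectory = [current]
    for _ in range(int(n_iter)):
        out_i = rng.choice(np.flatnonzero(in_cal))
        in_j = rng.choice(np.flatnonzero(~in_cal))
        in_cal[out_i], in_cal[in_j] = False, True
        cal_idx = np.flatnonzero(in_cal)
        val_idx = np.flatnonzero(~in_cal)
        cand = _cdmean(G.G, Ginv_r, lam, cal_idx, val_idx)
        if cand > current:
            current = cand
            trajectory.append(cand)
        else:
            in_cal[out_i], in_cal[in_j] = True, False
    ids = sorted(G.pop_ids[i] for i in np.flatnonzero(in_cal))
    return CalibrationSet(
        pop_ids=ids,
        method="cdmean",
        params={
            "k": k,
            "lambda": lam,
            "n_iter": int(n_iter),
            "seed": int(seed),
            "cdmean": current,
            "trajectory": trajectory,
        },
    )


def performance(opt_pa: float, min_pa: float, max_pa: float) -> float:
    """(OptPA - MinPA) / (MaxPA - MinPA); may leave [0, 1]."""
    if not max_pa > min_pa:
        raise ValueError("performance undefined: MaxPA must exceed MinPA")
    return (opt_pa - min_pa) / (max_pa - min_pa)


def _set_pa(freqs: AlleleFrequencyMatrix, yv: np.ndarray, cal_ids: list[str]) -> float:
    cal_set = set(cal_ids)
    val_ids = [p for p in freqs.pop_ids if p not in cal_set]
    idx = {p: i for i, p in enumerate(freqs.pop_ids)}
    model = fit_rrblup(freqs.subset_pops(cal_ids), yv[[idx[p] for p in cal_ids]])
    pred = predict(model, freqs.subset_pops(val_ids)).to_numpy()
    return _pearson(yv[[idx[p] for p in val_ids]], pred)


def evaluate_calibration(
    freqs: AlleleFrequencyMatrix,
    y: np.ndarray | pd.Series,
    calibration: CalibrationSet,
    n_random: int = 100,
    seed: int = 0,
) -> PerformanceScore:
    """Score a calibration set against the random-set envelope.

    OptPA trains on the set and predicts all remaining populations;
    MinPA/MaxPA are the extremes over *n_random* random same-size sets
    evaluated identically.  Degenerate (constant) predictions yield NaN
    predictive abilities and are excluded from the envelope.
    """
    yv = np.asarray(y, dtype=float).ravel()
    n = freqs.n_pops
    if calibration.k >= n:
        raise ValueError("calibration set must leave at least one validation population")
    unknown = set(calibration.pop_ids) - set(freqs.pop_ids)
    if unknown:
        raise ValueError(f"calibration populations absent from matrix: {sorted(unknown)[:5]}")
    opt_pa = _set_pa(freqs, yv, list(calibration.pop_ids))
    rng = np.random.default_rng(seed)
    pas = np.empty(n_random)
    for r in range(int(n_random)):
        ids = [freqs.pop_ids[i] for i in rng.choice(n, size=calibration.k, replace=False)]
        pas[r] = _set_pa(freqs, yv, ids)
    finite = pas[np.isfinite(pas)]
    if finite.size == 0 or not np.isfinite(opt_pa):
        return PerformanceScore(opt_pa=opt_pa, min_pa=np.nan, max_pa=np.nan, score=np.nan, random_pas=pas)
    min_pa, max_pa = float(finite.min()), float(finite.max())
    score = performance(opt_pa, min_pa, max_pa) if max_pa > min_pa else np.nan
    return PerformanceScore(opt_pa=float(opt_pa), min_pa=min_pa, max_pa=max_pa, score=float(score), random_pas=pas)


def build_gwas_set(
    freqs_cal: AlleleFrequencyMatrix,
    y_cal: np.ndarray | pd.Series,
    G_cal: KinshipMatrix,
    alpha: float = 0.05,
) -> list[str]:
    """GWAS-informed marker set, built on calibration data only.

    Runs a kinship-only GWAS on the calibration populations, then visits
    markers by ascending p-value and adds each as a fixed effect to a
    multiple regression iff the nested-model F-test p-value is below
    *alpha*; the set size is capped at the number of calibration
    populations.  Returns the ordered selected markers (may be empty).
    """
    yv = np.asarray(y_cal, dtype=float).ravel()
    n = freqs_cal.n_pops
    result = run_gwas(yv, freqs_cal, model="kinship", G=G_cal)
    order = result.table.sort_values(["p", "marker"], kind="mergesort")
    col_of = {m: i for i, m in enumerate(freqs_cal.marker_ids)}
    # incremental Gram-Schmidt on the growing design [1, selected markers]
    Qbasis = [np.ones(n) / np.sqrt(n)]
    ry = yv - Qbasis[0] * (Qbasis[0] @ yv)
    rss = float(ry @ ry)
    selected: list[str] = []
    for m in order["marker"]:
        if len(selected) >= n:
            break
        x = freqs_cal.values[:, col_of[m]].copy()
        for qv in Qbasis:
            x -= qv * (qv @ x)
        nx = float(np.sqrt(x @ x))
        if nx < 1e-10:
            continue  # collinear with current design
        qx = x / nx
        proj = float(qx @ ry)
        rss_new = rss - proj**2
        df = n - (len(selected) + 2)
        if df < 1 or rss_new <= 0:
            break
        f = (rss - rss_new) / (rss_new / df)
        if stats.f.sf(f, 1, df) < alpha:
            selected.append(str(m))
            Qbasis.append(qx)
            ry = ry - qx * proj
            rss = rss_new
    return selected


def marker_curve(
    freqs: AlleleFrequencyMatrix,
    y: np.ndarray | pd.Series,
    calibration: CalibrationSet,
    gwas_set: list[str],
    max_random: int = 2000,
    seed: int = 0,
    validation_ids: list[str] | None = None,
) -> MarkerCurve:
    """Predictive ability as a function of the number of markers.

    GWAS-first regime: models with the first 1, 2, ..., |gwas_set| markers
    of the GWAS set (ascending GWAS p), then random other markers one by
    one up to *max_random* additional.  Random-first regime: the same total
    number of markers drawn randomly from the start.  All markers enter as
    random effects.  For each regime, min_markers_95 is the smallest count
    whose predictive ability reaches 95% of the regime's curve maximum.
    """
    yv = np.asarray(y, dtype=float).ravel()
    cal_ids = list(calibration.pop_ids)
    if validation_ids is None:
        cal = set(cal_ids)
        validation_ids = [p for p in freqs.pop_ids if p not in cal]
    if set(cal_ids) & set(validation_ids):
        raise ValueError("calibration and validation sets overlap")
    idx = {p: i for i, p in enumerate(freqs.pop_ids)}
    f_cal = freqs.subset_pops(cal_ids)
    f_val = freqs.subset_pops(validation_ids)
    y_cal = yv[[idx[p] for p in cal_ids]]
    y_val = yv[[idx[p] for p in validation_ids]]

    rng = np.random.default_rng(seed)
    in_gwas = set(gwas_set)
    others = [m for m in freqs.marker_ids if m not in in_gwas]
    n_random = min(int(max_random), len(others))
    random_tail = [others[i] for i in rng.permutation(len(others))[:n_random]]
    gwas_sequence = list(gwas_set) + random_tail
    total = len(gwas_sequence)
    all_pool = list(freqs.marker_ids)
    random_sequence = [all_pool[i] for i in rng.permutation(len(all_pool))[:total]]

    def curve(sequence: list[str]) -> np.ndarray:
        pas = np.empty(len(sequence))
        for m_count in range(1, len(sequence) + 1):
            subset = sequence[:m_count]
            model = fit_rrblup(f_cal, y_cal, marker_subset=subset)
            pred = predict(model, f_val.subset_markers(subset)).to_numpy()
            pas[m_count - 1] = _pearson(y_val, pred)
        return pas

    pa_gwas = curve(gwas_sequence)
    pa_rand = curve(random_sequence)

    def min95(pa: np.ndarray) -> int:
        finite = np.where(np.isfinite(pa), pa, -np.inf)
        threshold = 0.95 * finite.max()
        return int(np.argmax(finite >= threshold) + 1)

    return MarkerCurve(
        counts=np.arange(1, total + 1),
        pa_gwas_first=pa_gwas,
        pa_random_first=pa_rand,
        gwas_set=list(gwas_set),
        min_markers_95_gwas=min95(pa_gwas),
        min_markers_95_random=min95(pa_rand),
    )
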