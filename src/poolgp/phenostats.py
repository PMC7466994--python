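"""Balanced ANOVA for plot phenotypes: adjusted means and heritability.

Two classical designs are supported, exactly matching balanced complete
blocks:

* model 1 (single environment): Y_ij = mu + g_i + b_j + E_ij
* model 2 (multi-environment):  Y_ijr = mu + g_i + env_j + (g x env)_ij
  + b/env_jr + E_ijr

Variance components come from expected mean squares of the random-g
version — exact for balanced data — with negative estimates truncated at
zero.  Broad-sense heritability indicators on a population-mean basis are

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / R)                (model 1)
    H^2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2/J + sigma_e^2/(JR)) (model 2)

with R blocks per environment and J environments.  Adjusted (least-squares)
means equal raw population means under balance; they are computed from the
fitted fixed effects so the identity is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from poolgp.dataio import PhenotypeRecords


class UnbalancedDesignError(ValueError):
    """Raised when the design is not a balanced complete block layout."""


@dataclass
class AnovaFit:
    """Fitted balanced ANOVA (model 1 or 2) for one trait."""

    model_id: int
    trait: str
    envs: list[str]
    mu: float
    g_effects: pd.Series
    block_effects: pd.DataFrame  # env x block (single row for model 1)
    env_effects: pd.Series
    gxe_effects: pd.DataFrame  # pop x env; zeros for model 1
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    f_statistic: float
    p_value: float
    R: int
    J: int
    anova_table: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_e2) < 0:
            raise ValueError("variance components must be >= 0")
        if self.R < 2 or self.J < 1:
            raise ValueError("need R >= 2 blocks and J >= 1 environments")


@dataclass
class AdjustedMeans:
    """Per-population least-squares means for one trait (one env or _avg)."""

    trait: str
    values: pd.Series  # indexed by pop_id
    scope: str  # environment label or "avg"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite adjusted means")


def _balanced_cube(records: PhenotypeRecords, trait: str, env: str | None):
    """Return the Y[pop, env, block] cube, erroring on any unbalance."""
    sub = records.for_trait(trait, env)
    pops = sorted(sub["pop_id"].unique())
    envs = sorted(sub["env"].unique())
    blocks = sorted(sub["block"].unique())
    if len(pops) < 2:
        raise ValueError("population effect not estimable with a single population")
    if len(blocks) < 2:
        raise UnbalancedDesignError("need >= 2 blocks per environment")
    expected = len(pops) * len(envs) * len(blocks)
    if len(sub) != expected:
        raise UnbalancedDesignError(
            f"design not balanced for trait {trait!r}: {len(sub)} records, expected {expected}"
        )
    cube = (
        sub.set_index(["pop_id", "env", "block"])["value"]
        .unstack(["env", "block"])
        .loc[pops]
        .to_numpy()
        .reshape(len(pops), len(envs), len(blocks))
    )
    if np.isnan(cube).any():
        raise UnbalancedDesignError(f"incomplete blocks for trait {trait!r}")
    return cube, pops, envs, blocks


def fit_model1(records: PhenotypeRecords, trait: str, env: str) -> AnovaFit:
    """Single-environment complete-block ANOVA, Y = mu + g + b + E.

    The population F test uses the residual mean square; variance components
    use sigma_g^2 = max(0, (MS_g - MS_e)/R) with the g effect random.
    """
    cube, pops, envs, blocks = _balanced_cube(records, trait, env)
    Y = cube[:, 0, :]  # pops x blocks
    I, R = Y.shape
    grand = Y.mean()
    pop_means = Y.mean(axis=1)
    block_means = Y.mean(axis=0)
    ss_g = R * float(((pop_means - grand) ** 2).sum())
    ss_b = I * float(((block_means - grand) ** 2).sum())
    ss_tot = float(((Y - grand) ** 2).sum())
    ss_e = max(ss_tot - ss_g - ss_b, 0.0)
    df_g, df_b, df_e = I - 1, R - 1, (I - 1) * (R - 1)
    ms_g, ms_b, ms_e = ss_g / df_g, ss_b / df_b, ss_e / df_e
    f_g = ms_g / ms_e if ms_e > 0 else np.inf
    p_g = float(stats.f.sf(f_g, df_g, df_e)) if np.isfinite(f_g) else 0.0
    sigma_g2 = max(0.0, (ms_g - ms_e) / R)
    table = pd.DataFrame(
        {
            "df": [df_g, df_b, df_e],
            "sum_sq": [ss_g, ss_b, ss_e],
            "mean_sq": [ms_g, ms_b, ms_e],
        },
        index=["population", "block", "residual"],
    )
    return AnovaFit(
        model_id=1,
        trait=trait,
        envs=[env],
        mu=float(grand),
        g_effects=pd.Series(pop_means - grand, index=pops),
        block_effects=pd.DataFrame([block_means - grand], index=[env], columns=blocks),
        env_effects=pd.Series([0.0], index=[env]),
        gxe_effects=pd.DataFrame(0.0, index=pops, columns=[env]),
        sigma_g2=float(sigma_g2),
        sigma_ge2=0.0,
        sigma_e2=float(ms_e),
        f_statistic=float(f_g),
        p_value=p_g,
        R=R,
        J=1,
        anova_table=table,
    )


def fit_model2(records: PhenotypeRecords, trait: str) -> AnovaFit:
    """Multi-environment ANOVA with g x env interaction and nested blocks.

    Environments and the interaction are treated as random for inference on
    the population effect: F_g = MS_g / MS_gxe.  Components follow the
    expected mean squares sigma_g^2 = (MS_g - MS_gxe)/(J R) and
    sigma_ge^2 = (MS_gxe - MS_e)/R, truncated at zero.
    """
    cube, pops, envs, blocks = _balanced_cube(records, trait, None)
    I, J, R = cube.shape
    if J < 2:
        raise UnbalancedDesignError("model 2 needs >= 2 environments")
    grand = cube.mean()
    m_i = cube.mean(axis=(1, 2))
    m_j = cube.mean(axis=(0, 2))
    m_ij = cube.mean(axis=2)
    m_jr = cube.mean(axis=0)
    ss_g = J * R * float(((m_i - grand) ** 2).sum())
    ss_env = I * R * float(((m_j - grand) ** 2).sum())
    ss_gxe = R * float(((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum())
    ss_blk = I * float(((m_jr - m_j[:, None]) ** 2).sum())
    ss_tot = float(((cube - grand) ** 2).sum())
    ss_e = max(ss_tot - ss_g - ss_env - ss_gxe - ss_blk, 0.0)
    df_g, df_env = I - 1, J - 1
    df_gxe, df_blk = (I - 1) * (J - 1), J * (R - 1)
    df_e = J * (I - 1) * (R - 1)
    ms = np.array([ss_g / df_g, ss_env / df_env, ss_gxe / df_gxe, ss_blk / df_blk, ss_e / df_e])
    ms_g, ms_env, ms_gxe, ms_blk, ms_e = ms
    f_g = ms_g / ms_gxe if ms_gxe > 0 else np.inf
    p_g = float(stats.f.sf(f_g, df_g, df_gxe)) if np.isfinite(f_g) else 0.0
    sigma_g2 = max(0.0, (ms_g - ms_gxe) / (J * R))
    sigma_ge2 = max(0.0, (ms_gxe - ms_e) / R)
    table = pd.DataFrame(
        {
            "df": [df_g, df_env, df_gxe, df_blk, df_e],
            "sum_sq": [ss_g, ss_env, ss_gxe, ss_blk, ss_e],
            "mean_sq": list(ms),
        },
        index=["population", "environment", "g_x_env", "block_in_env", "residual"],
    )
    return AnovaFit(
        model_id=2,
        trait=trait,
        envs=envs,
        mu=float(grand),
        g_effects=pd.Series(m_i - grand, index=pops),
        block_effects=pd.DataFrame(m_jr - m_j[:, None], index=envs, columns=blocks),
        env_effects=pd.Series(m_j - grand, index=envs),
        gxe_effects=pd.DataFrame(
            m_ij - m_i[:, None] - m_j[None, :] + grand, index=pops, columns=envs
        ),
        sigma_g2=float(sigma_g2),
        sigma_ge2=float(sigma_ge2),
        sigma_e2=float(ms_e),
        f_statistic=float(f_g),
        p_value=p_g,
        R=R,
        J=J,
        anova_table=table,
    )


def adjusted_means(fit: AnovaFit) -> AdjustedMeans:
    """Least-squares mean per population: mu + g_i, averaged over blocks
    (and environments for model 2).  Equals the raw population mean under
    balance.  Model-2 means carry the ``_avg`` trait-name suffix."""
    values = fit.mu + fit.g_effects
    if fit.model_id == 2:
        return AdjustedMeans(trait=f"{fit.trait}_avg", values=values, scope="avg")
    return AdjustedMeans(trait=fit.trait, values=values, scope=fit.envs[0])


def heritability(fit: AnovaFit) -> float:
    """Broad-sense heritability indicator on a population-mean basis."""
    if fit.sigma_g2 == 0.0:
        return 0.0
    if fit.model_id == 1:
        denom = fit.sigma_g2 + fit.sigma_e2 / fit.R
    else:
        denom = fit.sigma_g2 + fit.sigma_ge2 / fit.J + fit.sigma_e2 / (fit.J * fit.R)
    return float(fit.sigma_g2 / denom)


def trait_correlations(means: list[AdjustedMeans], min_common: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of adjusted means across traits.

    Each pair is computed on the populations present for both traits;
    pairs sharing fewer than *min_common* populations are left NaN.
    """
    if len(means) < 2:
        raise ValueError("need at least 2 traits")
    frame = pd.DataFrame({m.trait: m.values for m in means})
    if frame.columns.duplicated().any():
        raise ValueError("duplicated trait labels")
    corr = frame.corr(method="pearson", min_periods=min_common)
    np.fill_diagonal(corr.values, 1.0)
    return corr
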