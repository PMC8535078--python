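"""Modified joint regression for variety-stability analysis.

The Finlay-Wilkinson family of "joint regression" models describes a
variety x environment table of trait means by the bilinear model

    y_ij = V_i + b_i * E_j + error_ij

where ``V_i`` is the mean of variety *i*, ``E_j`` is a latent quality
index of environment *j*, and the sensitivity slope ``b_i`` measures
how strongly variety *i* responds to the environment: ``b_i > 1`` is
above-average sensitivity, ``b_i < 1`` is stability.  In the
*modified* form implemented here the environmental indices are
estimated **jointly** with the slopes by alternating least squares
(ALS), rather than fixed at the observed environment means; for
complete tables the solution coincides with the rank-1 truncated SVD
of the row-centred matrix, which the test-suite uses as an independent
oracle.

Identification: the bilinear part is invariant under
``(b, E) -> (b/c, cE)`` and under shifting E, so the constraints
``mean_i(b_i) = 1`` and ``sum_j(E_j) = 0`` are enforced after every
iteration.  Standard errors are computed conditionally on the final E
from the pooled residual mean square — the classical joint-regression
reporting convention, which understates uncertainty slightly because E
is itself estimated (recorded in the fit metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, IntegrityError
from .met_core import CellMeanMatrix

__all__ = [
    "JointRegressionFit",
    "StabilityTest",
    "fit_joint_regression",
    "slope_heterogeneity_test",
    "variety_effect_test",
    "classify_stability",
]

logger = logging.getLogger(__name__)

#: Relative RSS below which a fit is declared exact (interpolating).
_EXACT_FIT_RTOL = 1e-12

#: Relative parameter-stabilisation threshold for the ALS stop rule.
_PARAM_RTOL = 1e-12


@dataclass
class JointRegressionFit:
    """Constrained least-squares solution of the bilinear model."""

    varieties: list
    environments: list
    variety_means: np.ndarray        # V_i, trait units
    sensitivities: np.ndarray        # b_i, dimensionless, mean 1
    env_index: np.ndarray            # E_j, trait units, sum 0
    se_variety_means: np.ndarray
    se_sensitivities: np.ndarray
    rss: float
    error_df: int
    n_observed: int
    n_iter: int
    converged: bool
    exact_fit: bool
    rss_trace: np.ndarray
    mask: np.ndarray                 # g x e observed mask
    residuals: np.ndarray            # g x e, NaN where unobserved
    trait: str = ""
    notes: dict = field(default_factory=dict)

    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def residual_mean_square(self) -> float:
        if self.error_df <= 0:
            return float("nan")
        return self.rss / self.error_df

    def fitted(self) -> np.ndarray:
        """Fitted cell means V_i + b_i E_j (dense g x e)."""
        return (
            self.variety_means[:, None]
            + self.sensitivities[:, None] * self.env_index[None, :]
        )

    def summary(self) -> pd.DataFrame:
        """Per-variety table: mean, sensitivity and their s.e."""
        return pd.DataFrame(
            {
                "mean": self.variety_means,
                "sensitivity": self.sensitivities,
                "se_mean": self.se_variety_means,
                "se_sensitivity": self.se_sensitivities,
            },
            index=pd.Index(self.varieties, name="variety"),
        )


@dataclass
class StabilityTest:
    """An F test from the joint-regression ANOVA."""

    name: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    sum_of_squares: float
    exact_fit: bool = False

    def __post_init__(self) -> None:
        if not self.exact_fit and not (0.0 <= self.p_value <= 1.0):
            raise IntegrityError(f"p-value {self.p_value} outside [0, 1]")


def _as_arrays(cells) -> tuple[np.ndarray, np.ndarray, list, list, str]:
    if isinstance(cells, CellMeanMatrix):
        y = cells.values.to_numpy(dtype=float)
        w = cells.mask.to_numpy(dtype=bool)
        return y, w, cells.varieties, cells.environments, cells.trait
    y = np.asarray(cells, dtype=float)
    if y.ndim != 2:
        raise IntegrityError("cell-mean input must be 2-D")
    w = np.isfinite(y)
    g, e = y.shape
    return (
        y,
        w,
        [f"V{i+1}" for i in range(g)],
        [f"E{j+1}" for j in range(e)],
        "",
    )


def fit_joint_regression(
    cells,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> JointRegressionFit:
    """Fit ``y_ij = V_i + b_i E_j + error_ij`` by alternating least squares.

    Parameters
    ----------
    cells
        A :class:`~oatmet.met_core.CellMeanMatrix` or a plain g x e
        array of cell means with NaN marking missing cells.  Needs
        g >= 2 varieties, e >= 2 environments, every variety observed
        in >= 3 environments when any cell is missing (>= 2 when
        complete so that tiny exact examples remain fittable).
    tol
        Convergence threshold on the relative change in residual sum
        of squares between sweeps.  Because the RSS flattens out while
        the bilinear direction can still rotate, the sweep loop also
        requires the parameters themselves to have stabilised (relative
        change below an internal 1e-12) before declaring convergence.
    max_iter
        Sweep budget; exceeding it flags ``converged=False`` instead
        of raising.

    Notes
    -----
    One sweep: (a) per-variety OLS of the observed cell means on the
    current E gives (V_i, b_i); (b) given (V, b), the least-squares
    index is ``E_j = sum_i b_i (y_ij - V_i) / sum_i b_i^2`` over
    observed cells; (c) re-identify by absorbing mean(E) into V and
    rescaling so mean(b) = 1.  The RSS is non-increasing across
    sweeps.  Initialisation is deterministic (no RNG): E starts at the
    first right singular vector of the row-centred matrix (missing
    cells zero-filled), b = 1.  For complete tables this warm start is
    already the least-squares direction, so convergence does not slow
    down when the top two singular values are close — a plain
    column-means start degrades to power iteration there.
    """
    y, w, varieties, environments, trait = _as_arrays(cells)
    g, e = y.shape
    if g < 2:
        raise IntegrityError(f"need >= 2 varieties, got {g}")
    if e < 2:
        raise IntegrityError(f"need >= 2 environments, got {e}")
    wf = w.astype(float)
    n_obs_per_variety = w.sum(axis=1)
    min_obs = 2 if w.all() else 3
    if (n_obs_per_variety < min_obs).any():
        bad = [varieties[i] for i in np.flatnonzero(n_obs_per_variety < min_obs)]
        raise IntegrityError(
            f"variety observed in fewer than {min_obs} environments: {bad}"
        )
    if (w.sum(axis=0) < 2).any():
        bad = [environments[j] for j in np.flatnonzero(w.sum(axis=0) < 2)]
        raise IntegrityError(f"environment with < 2 observed varieties: {bad}")

    n_obs = int(w.sum())
    y0 = np.where(w, y, 0.0)
    scale = float(np.sum(w * (y0 - y0[w].mean()) ** 2)) or 1.0

    # deterministic initialisation: leading right singular direction of
    # the row-centred matrix (observed cells only, missing zero-filled)
    V = (y0.sum(axis=1) / np.maximum(n_obs_per_variety, 1)).astype(float)
    R = np.where(w, y0 - V[:, None], 0.0)
    _, s_init, vt_init = np.linalg.svd(R, full_matrices=False)
    E = s_init[0] * vt_init[0]
    E = E - E.mean()
    b = np.ones(g)

    if np.abs(E).max() <= 1e-12 * max(1.0, np.sqrt(scale)):
        raise DegenerateInputError(
            "no environment spread (environments indistinguishable after "
            "removing variety means): slopes are undefined; fit an "
            "additive model instead"
        )

    def rss_of(V, b, E) -> float:
        r = y0 - (V[:, None] + b[:, None] * E[None, :])
        return float(np.sum(wf * r * r))

    rss_trace = []
    rss_prev = np.inf
    E_prev = E.copy()
    b_prev = b.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # (a) per-variety OLS of y on E over observed cells, vectorised
        n_i = wf.sum(axis=1)
        Sx = wf @ E
        Sxx = wf @ (E * E)
        Sy = (wf * y0).sum(axis=1)
        Sxy = (wf * y0) @ E
        denom = n_i * Sxx - Sx * Sx
        if np.any(np.abs(denom) < 1e-300):
            raise DegenerateInputError(
                "environment index degenerate for at least one variety "
                "(no within-variety spread in E)"
            )
        b = (n_i * Sxy - Sx * Sy) / denom
        V = (Sy - b * Sx) / n_i
        # (b) least-squares update of E given (V, b)
        num = (wf * (y0 - V[:, None]) * b[:, None]).sum(axis=0)
        den = (wf * (b * b)[:, None]).sum(axis=0)
        E = num / den
        # (c) re-identification: sum(E) = 0, mean(b) = 1
        e_bar = E.mean()
        V = V + b * e_bar
        E = E - e_bar
        c = b.mean()
        if abs(c) < 1e-300:
            raise DegenerateInputError("mean sensitivity collapsed to zero")
        b = b / c
        E = E * c

        rss = rss_of(V, b, E)
        rss_trace.append(rss)
        logger.debug("ALS sweep %d: RSS = %.6e", n_iter, rss)
        if rss <= _EXACT_FIT_RTOL * scale:
            converged = True
            break
        e_scale = max(float(np.abs(E).max()), 1e-300)
        params_stable = (
            np.abs(E - E_prev).max() <= _PARAM_RTOL * e_scale
            and np.abs(b - b_prev).max() <= _PARAM_RTOL * max(np.abs(b).max(), 1.0)
        )
        if (
            np.isfinite(rss_prev)
            and abs(rss_prev - rss) <= tol * max(rss_prev, 1e-300)
            and params_stable
        ):
            converged = True
            break
        rss_prev = rss
        E_prev = E.copy()
        b_prev = b.copy()

    rss = rss_trace[-1]
    exact_fit = rss <= _EXACT_FIT_RTOL * scale
    error_df = n_obs - (2 * g + e - 2)

    # standard errors conditional on the final E (pooled residual MS)
    if error_df > 0 and not exact_fit:
        mse = rss / error_df
    else:
        mse = 0.0
    n_i = wf.sum(axis=1)
    Ebar_i = (wf @ E) / n_i
    Sxx_i = wf @ (E * E) - n_i * Ebar_i**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b = np.sqrt(mse / Sxx_i)
        se_V = np.sqrt(mse * (1.0 / n_i + Ebar_i**2 / Sxx_i))

    resid = np.where(w, y0 - (V[:, None] + b[:, None] * E[None, :]), np.nan)
    return JointRegressionFit(
        varieties=varieties,
        environments=environments,
        variety_means=V,
        sensitivities=b,
        env_index=E,
        se_variety_means=se_V,
        se_sensitivities=se_b,
        rss=rss,
        error_df=error_df,
        n_observed=n_obs,
        n_iter=n_iter,
        converged=converged,
        exact_fit=exact_fit,
        rss_trace=np.asarray(rss_trace),
        mask=w,
        residuals=resid,
        trait=trait,
        notes={"se_convention": "conditional on final E, pooled residual MS"},
    )


def _require_usable(fit: JointRegressionFit) -> None:
    if not fit.converged:
        raise IntegrityError("fit did not converge; tests are not meaningful")


def slope_heterogeneity_test(fit: JointRegressionFit) -> StabilityTest:
    """F test of equal sensitivities (all b_i = 1) against pooled error.

    The heterogeneity sum of squares is
    ``sum_i (b_i - 1)^2 * sum_{j in obs(i)} E_j^2`` on g - 1 degrees of
    freedom; under no genotype-by-environment interaction it is pure
    noise relative to the pooled residual mean square.
    """
    _require_usable(fit)
    g = fit.n_varieties
    wf = fit.mask.astype(float)
    Sxx = wf @ (fit.env_index**2)
    ss_het = float(np.sum((fit.sensitivities - 1.0) ** 2 * Sxx))
    if fit.exact_fit or fit.error_df < 1:
        # an interpolating fit: any slope spread is infinitely significant
        p = 1.0 if ss_het == 0.0 else 0.0
        return StabilityTest(
            "slope heterogeneity", float("inf") if ss_het else 0.0,
            g - 1, max(fit.error_df, 0), p, ss_het, exact_fit=True,
        )
    f = (ss_het / (g - 1)) / fit.residual_mean_square
    p = float(stats.f.sf(f, g - 1, fit.error_df))
    return StabilityTest("slope heterogeneity", f, g - 1, fit.error_df, p, ss_het)


def variety_effect_test(fit: JointRegressionFit) -> StabilityTest:
    """F test of equality of the variety means against pooled error."""
    _require_usable(fit)
    g = fit.n_varieties
    n_i = fit.mask.sum(axis=1).astype(float)
    grand = float(np.sum(n_i * fit.variety_means) / n_i.sum())
    ss_var = float(np.sum(n_i * (fit.variety_means - grand) ** 2))
    if fit.exact_fit or fit.error_df < 1:
        p = 1.0 if ss_var == 0.0 else 0.0
        return StabilityTest(
            "variety means", float("inf") if ss_var else 0.0,
            g - 1, max(fit.error_df, 0), p, ss_var, exact_fit=True,
        )
    f = (ss_var / (g - 1)) / fit.residual_mean_square
    p = float(stats.f.sf(f, g - 1, fit.error_df))
    return StabilityTest("variety means", f, g - 1, fit.error_df, p, ss_var)


def classify_stability(
    fit: JointRegressionFit,
    threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.Series:
    """Label each variety ``sensitive``, ``stable`` or ``average``.

    A variety whose slope is significantly above ``threshold`` (average
    sensitivity, 1.0) is ``sensitive``; significantly below is
    ``stable``; otherwise ``average``.  Significance is a two-sided t
    test at level ``alpha`` on the pooled error df, using the
    conditional slope standard errors.  With an exact (interpolating)
    fit the s.e. are zero and the comparison degenerates to the sign
    of ``b_i - threshold``.
    """
    _require_usable(fit)
    b = fit.sensitivities
    se = fit.se_sensitivities
    labels = []
    if fit.exact_fit or fit.error_df < 1:
        # interpolating fit: s.e. are zero, compare slopes directly
        # (with an epsilon so numerically-unit slopes stay "average")
        eps = 1e-9 * max(1.0, abs(threshold))
        for bi in b:
            if bi > threshold + eps:
                labels.append("sensitive")
            elif bi < threshold - eps:
                labels.append("stable")
            else:
                labels.append("average")
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, fit.error_df)
        for bi, si in zip(b, se):
            if si > 0 and (bi - threshold) / si > tcrit:
                labels.append("sensitive")
            elif si > 0 and (bi - threshold) / si < -tcrit:
                labels.append("stable")
            else:
                labels.append("average")
    return pd.Series(labels, index=pd.Index(fit.varieties, name="variety"), name="stability")
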