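"""Principal-component biplot of variety x environment trait means.

Rows are variety-environment mean combinations (4 varieties x 22
environments = 88 rows in the reference trial), columns are traits.
Because traits are measured in heterogeneous units, columns are
centred and scaled to unit variance (correlation-matrix PCA) before
the singular value decomposition.  With SVD ``Z = U S Vt``, the biplot
uses

    scores   = U * S**alpha        (rows)
    loadings = V * S**(1 - alpha)  (traits)

``alpha = 0.5`` (symmetric) by default; ``alpha = 1`` is the
row-metric and ``alpha = 0`` the column-metric convention.  Variance
fractions come from the squared singular values.  The angle between
two trait loading vectors tracks the sign of their correlation: acute
means positive, obtuse negative.

Per-variety convex hulls of the 2-D scores visualise how widely each
variety's environments scatter; a larger hull means greater
between-environment variation for that variety.  The hull is built
with the Andrew monotone-chain construction, which degrades gracefully
to a segment or point for collinear or tiny groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "BiplotResult",
    "compute_biplot",
    "convex_hulls",
    "convex_hull",
    "polygon_area",
    "plot_biplot",
]

logger = logging.getLogger(__name__)

_SCALING_ALPHA = {"symmetric": 0.5, "row": 1.0, "column": 0.0}


@dataclass
class BiplotResult:
    """Scores, loadings and variance fractions of a 2-D biplot."""

    scores: pd.DataFrame              # rows x (PC1, PC2)
    loadings: pd.DataFrame            # traits x (PC1, PC2)
    variance_fractions: np.ndarray    # per retained PC, from all s^2
    singular_values: np.ndarray
    alpha: float
    n_imputed: int = 0
    dropped_traits: list = field(default_factory=list)
    hulls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vf = self.variance_fractions
        if np.any(vf < -1e-12) or vf.sum() > 1 + 1e-9:
            raise DegenerateInputError("variance fractions outside [0, 1]")


def compute_biplot(
    table: pd.DataFrame,
    alpha: float | str = 0.5,
    drop_incomplete: bool = False,
) -> BiplotResult:
    """Correlation-matrix PCA biplot of a rows x traits table.

    Parameters
    ----------
    table
        Numeric frame, >= 3 rows and >= 2 traits.  Missing entries are
        mean-imputed per trait (count logged) unless ``drop_incomplete``
        removes those rows instead.
    alpha
        Scaling exponent in [0, 1], or one of ``symmetric``, ``row``,
        ``column``.

    Constant trait columns carry no correlation information and are
    dropped with a warning; fewer than 2 non-constant traits is an
    error.  Loadings signs are fixed by making the largest-magnitude
    loading on each axis positive, so output is deterministic across
    linear-algebra back-ends.
    """
    if isinstance(alpha, str):
        try:
            alpha = _SCALING_ALPHA[alpha]
        except KeyError:
            raise DegenerateInputError(
                f"unknown scaling {alpha!r}; use one of {sorted(_SCALING_ALPHA)}"
            ) from None
    if not 0.0 <= alpha <= 1.0:
        raise DegenerateInputError(f"scaling exponent must be in [0, 1], got {alpha}")

    df = table.astype(float)
    if drop_incomplete:
        n_before = len(df)
        df = df.dropna()
        if n_before - len(df):
            logger.info("dropped %d incomplete rows", n_before - len(df))
        n_imputed = 0
    else:
        n_imputed = int(df.isna().to_numpy().sum())
        if n_imputed:
            logger.info("mean-imputed %d missing entries", n_imputed)
            df = df.fillna(df.mean())
    if len(df) < 3:
        raise DegenerateInputError(f"need >= 3 rows, have {len(df)}")

    sd = df.std(ddof=1)
    dropped = list(df.columns[(sd == 0) | sd.isna()])
    if dropped:
        logger.warning("dropping constant trait column(s): %s", dropped)
        df = df.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    if df.shape[1] < 2:
        raise DegenerateInputError("fewer than 2 non-constant traits")

    z = (df - df.mean()) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    var_frac = s**2 / np.sum(s**2)
    scores = u[:, :2] * s[:2] ** alpha
    loadings = vt[:2].T * s[:2] ** (1.0 - alpha)
    pcs = ["PC1", "PC2"]
    return BiplotResult(
        scores=pd.DataFrame(scores, index=df.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=pcs),
        variance_fractions=var_frac[:2],
        singular_values=s,
        alpha=float(alpha),
        n_imputed=n_imputed,
        dropped_traits=dropped,
    )


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Minimal convex polygon via the Andrew monotone chain.

    Returns hull vertices in counter-clockwise order.  Collinear input
    degrades to a 2-point segment, a single point to itself; interior
    and repeated points are excluded.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateInputError("points must be an n x 2 array")
    uniq = np.unique(pts, axis=0)           # lexicographic sort as a side effect
    if len(uniq) <= 2:
        return uniq

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in uniq:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in uniq[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:                        # fully collinear set
        return np.array([uniq[0], uniq[-1]])
    return hull


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon (0 for points/segments)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def convex_hulls(scores: pd.DataFrame, groups) -> dict:
    """Per-group convex hulls of 2-D scores.

    Returns ``{group: {"vertices": array, "area": float, "n": int}}``
    with vertices in counter-clockwise order.
    """
    pts = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    groups = np.asarray(list(groups))
    if len(groups) != len(pts):
        raise DegenerateInputError("one group label per score row required")
    out = {}
    for grp in pd.unique(groups):
        sub = pts[groups == grp]
        verts = convex_hull(sub)
        out[grp] = {"vertices": verts, "area": polygon_area(verts), "n": len(sub)}
    return out


def plot_biplot(result: BiplotResult, groups=None, path=None, ax=None):
    """Render the biplot (scores, loading arrows, optional group hulls).

    Matplotlib is imported lazily; pass ``path`` to save a vector or
    raster file, or ``ax`` to draw into an existing axes.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    sc = result.scores
    if groups is not None:
        groups = np.asarray(list(groups))
        for grp in pd.unique(groups):
            m = groups == grp
            ax.scatter(sc.iloc[m, 0], sc.iloc[m, 1], s=18, label=str(grp))
            verts = convex_hull(sc.to_numpy()[m])
            if len(verts) >= 3:
                closed = np.vstack([verts, verts[:1]])
                ax.plot(closed[:, 0], closed[:, 1], lw=0.8, alpha=0.6)
        ax.legend(fontsize=8)
    else:
        ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], s=18, color="0.4")
    span = np.abs(sc.to_numpy()).max() or 1.0
    lmax = np.abs(result.loadings.to_numpy()).max() or 1.0
    for trait, (x, y) in result.loadings.iterrows():
        ax.annotate(
            "", xy=(x / lmax * span, y / lmax * span), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:red", lw=1.2),
        )
        ax.annotate(str(trait), (x / lmax * span * 1.06, y / lmax * span * 1.06),
                    color="tab:red", fontsize=8, ha="center")
    vf = result.variance_fractions
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}%)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
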