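"""Grand-mean phase difference maps, functional connectivity, and the
diffusion-embedding principal gradient.

The grand-mean phase difference (gmPD) at a channel is the argument of the
participant-mean of the complex per-participant mean phase differences
DeltaTheta_k — an amplitude-weighted circular mean, so strongly
synchronized participants contribute more.

Functional connectivity is the Pearson correlation of band-passed signals
with negative entries clipped to zero; its principal gradient is the first
non-trivial eigenvector of the diffusion-map embedding (alpha = 0.5,
diffusion time 0) of that non-negative affinity.  Channels with similar
gradient values are more strongly connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GmPDMap",
    "GradientResult",
    "RegressionResult",
    "gmpd_map",
    "functional_connectivity",
    "average_connectivity",
    "principal_gradient",
    "regress_gmpd_on_gradient",
    "plot_topography",
]


@dataclass
class GmPDMap:
    complex_mean: np.ndarray  # (n_channels,) participant-mean of DeltaTheta_k
    gmpd: np.ndarray  # radians; NaN where undefined
    resultant_amp: np.ndarray  # |complex mean|
    K: int  # participants averaged
    defined: np.ndarray  # resultant_amp above cancellation tolerance


@dataclass
class GradientResult:
    gradient: np.ndarray  # per-channel values, sign-arbitrary
    eigenvalues: np.ndarray  # non-trivial spectrum, descending
    alpha: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def gmpd_map(delta_thetas: np.ndarray, tol: float = 1e-12) -> GmPDMap:
    """Grand-mean phase difference per channel.

    ``delta_thetas`` is a (K participants, n_channels) complex array of
    per-participant mean phase differences.  Channels whose complex means
    cancel (resultant below ``tol``) are flagged undefined.
    """
    dt = np.atleast_2d(np.asarray(delta_thetas, dtype=complex))
    if dt.shape[0] < 1 or dt.size == 0:
        raise ValueError("need at least one participant")
    mean = dt.mean(axis=0)
    amp = np.abs(mean)
    defined = amp > tol
    gmpd = np.where(defined, np.angle(mean), np.nan)
    return GmPDMap(
        complex_mean=mean,
        gmpd=gmpd,
        resultant_amp=amp,
        K=dt.shape[0],
        defined=defined,
    )


def functional_connectivity(signals: np.ndarray, valid: np.ndarray | None = None):
    """Zero-clipped Pearson correlation of band-passed channel signals."""
    x = np.asarray(signals, dtype=float)
    if valid is not None:
        x = x[:, np.asarray(valid, dtype=bool)]
    if x.shape[0] < 2:
        raise ValueError("connectivity needs at least 2 channels")
    if x.shape[1] < 3:
        raise ValueError("connectivity needs at least 3 valid samples")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argwhere(sd == 0)[0][0])
        raise ValueError(f"channel {bad} has zero variance; correlation undefined")
    c = np.corrcoef(x)
    c = np.clip(c, 0.0, None)
    np.fill_diagonal(c, 1.0)
    return c


def average_connectivity(matrices) -> np.ndarray:
    """Group-level connectivity: mean of per-participant matrices."""
    mats = list(matrices)
    if not mats:
        raise ValueError("no connectivity matrices to average")
    c = np.mean(mats, axis=0)
    np.fill_diagonal(c, 1.0)
    return c


def principal_gradient(
    connectivity: np.ndarray, alpha: float = 0.5, degenerate_tol: float = 1e-9
) -> GradientResult:
    """First non-trivial diffusion-map eigenvector of a non-negative affinity.

    The affinity W is alpha-normalized (W' = D^-a W D^-a), row-normalized to
    a Markov operator, and eigendecomposed through the conjugate symmetric
    matrix; the gradient is the first non-trivial right eigenvector scaled
    by lambda/(1-lambda) (diffusion time 0).  The returned sign is fixed
    deterministically but carries no meaning.
    """
    w = np.asarray(connectivity, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("connectivity must be symmetric")
    if np.any(w < 0):
        raise ValueError("connectivity must be non-negative")
    n_comp, _ = connected_components(w > 0, directed=False)
    if n_comp > 1:
        raise ValueError(f"connectivity graph has {n_comp} disconnected components")

    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    d1 = w1.sum(axis=1)
    s = w1 / np.outer(np.sqrt(d1), np.sqrt(d1))
    evals, evecs = np.linalg.eigh(s)  # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    lam = evals[1]
    lam_next = evals[2] if evals.size > 2 else None
    if lam_next is not None and (lam - lam_next) < degenerate_tol:
        raise ValueError(
            "degenerate spectrum: leading non-trivial eigenvalues are not separated"
        )
    phi = evecs[:, 1] / np.sqrt(d1)
    phi = phi / np.linalg.norm(phi)
    if phi[np.argmax(np.abs(phi))] < 0:  # deterministic sign
        phi = -phi
    grad = (lam / (1.0 - lam)) * phi
    return GradientResult(gradient=grad, eigenvalues=evals[1:], alpha=alpha)


def regress_gmpd_on_gradient(abs_gmpd, gradient) -> RegressionResult:
    """OLS of |gmPD| on the principal gradient across channels.

    |gmPD| is used because it is non-circular, like the gradient.  NaN
    channels (undefined gmPD) are dropped.
    """
    y = np.asarray(abs_gmpd, dtype=float)
    x = np.asarray(gradient, dtype=float)
    if y.shape != x.shape:
        raise ValueError("gmPD and gradient must cover the same channel set")
    keep = ~np.isnan(y) & ~np.isnan(x)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("regression needs at least 3 defined channels")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for a constant gradient")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def plot_topography(positions, values, path, title: str | None = None):
    """Top-down scalp scatter: electrode positions colored by a value.

    ``positions`` are unit-sphere (x, y, z) electrode coordinates; the
    plot projects onto the x-y plane viewed from above (anterior up).
    Writes PNG/SVG according to the file suffix.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = np.asarray(positions, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=np.asarray(values, dtype=float),
                    s=120, cmap="viridis", edgecolors="k")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="gray", lw=1)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
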