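"""Characterizing the shape of coordination-ability score distributions.

Three ingredients:

* **Hartigan's dip statistic** — the maximum distance between the empirical
  CDF and the nearest unimodal CDF, with a bootstrap p-value drawn from the
  uniform null at the same sample size.  Implemented here from the published
  algorithm (greatest convex minorant / least concave majorant refinement of
  the modal interval).
* **Amplitude-Gaussian mixture curve fit** — least-squares fit of
  ``sum_i a_i * exp(-((x - b_i) / c_i)**2)`` to the histogram density.  This
  is a curve-fit parameterization (free amplitudes), not a weight-normalized
  probability mixture, so fitted amplitudes are comparable across datasets
  with the same binning.
* **k selection** — residual-sum-of-squares elbow over a k range, with the
  silhouette index of one-dimensional k-means clusterings as corroboration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "DipResult",
    "MixtureFit",
    "KSelection",
    "dip_statistic",
    "dip_null_table",
    "dip_test",
    "fit_mixture",
    "select_k",
]


# ---------------------------------------------------------------------------
# Hartigan's dip


def _lower_hull(xs: np.ndarray, ys: np.ndarray, idx: np.ndarray) -> list[int]:
    """Indices (into the full array) of the lower convex hull of (xs, ys)."""
    hull: list[int] = []
    for j in idx:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (xs[b] - xs[a]) * (ys[j] - ys[a]) - (ys[b] - ys[a]) * (
                xs[j] - xs[a]
            )
            if cross > 0:
                break
            hull.pop()
        hull.append(j)
    return hull


def _upper_hull(xs: np.ndarray, ys: np.ndarray, idx: np.ndarray) -> list[int]:
    hull: list[int] = []
    for j in idx:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (xs[b] - xs[a]) * (ys[j] - ys[a]) - (ys[b] - ys[a]) * (
                xs[j] - xs[a]
            )
            if cross < 0:
                break
            hull.pop()
        hull.append(j)
    return hull


def dip_statistic(samples: Sequence[float]) -> float:
    """Hartigan's dip: sup distance from the ECDF to the closest unimodal CDF.

    The empirical step function jumps at each order statistic; the greatest
    convex minorant (GCM) touches its lower corners and the least concave
    majorant (LCM) its upper corners.  The modal interval is iteratively
    narrowed to the stretch where the GCM-LCM gap is largest; outside it the
    one-sided ECDF deviations bound the dip.  For a sample with all values
    distinct the dip is at least ``1 / (2n)``.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("dip statistic requires at least 4 observations")
    if x[0] == x[-1]:
        return 0.0

    lo, hi = 0, n - 1
    best = 1.0  # in count units; final dip = best / (2n)
    counts = np.arange(n, dtype=float)

    while True:
        idx = np.arange(lo, hi + 1)
        gcm = _lower_hull(x, counts, idx)  # knots, ascending, corners (x_j, j)
        lcm = _upper_hull(x, counts + 1.0, idx)  # corners (x_j, j + 1)
        gx = x[gcm]
        gy = counts[gcm]
        lx = x[lcm]
        ly = counts[lcm] + 1.0

        # Largest gap between the two curves, evaluated at every knot of the
        # other curve; remember the bracketing knots to narrow the interval.
        d = 0.0
        new_lo, new_hi = lo, hi
        # LCM knots against the GCM curve
        gap_at_lcm = ly - np.interp(lx, gx, gy)
        k = int(np.argmax(gap_at_lcm))
        if gap_at_lcm[k] > d:
            d = float(gap_at_lcm[k])
            seg = int(np.searchsorted(gx, lx[k], side="left"))
            new_lo = gcm[max(seg - 1, 0)]
            new_hi = lcm[k]
        # GCM knots against the LCM curve
        gap_at_gcm = np.interp(gx, lx, ly) - gy
        k = int(np.argmax(gap_at_gcm))
        if gap_at_gcm[k] > d:
            d = float(gap_at_gcm[k])
            seg = int(np.searchsorted(lx, gx[k], side="right"))
            new_lo = gcm[k]
            new_hi = lcm[min(seg, len(lcm) - 1)]

        if d <= best:
            break

        # One-sided ECDF deviations outside the candidate modal interval:
        # upper corners above the GCM on [lo, new_lo] ...
        jj = np.arange(lo, new_lo + 1)
        if jj.size:
            dip_l = float(np.max(jj + 1.0 - np.interp(x[jj], gx, gy)))
        else:  # pragma: no cover - new_lo >= lo always
            dip_l = 1.0
        # ... and lower corners below the LCM on [new_hi, hi].
        jj = np.arange(new_hi, hi + 1)
        dip_u = float(np.max(np.interp(x[jj], lx, ly) - jj))

        best = max(best, dip_l, dip_u)
        if new_lo == lo and new_hi == hi:
            break
        if new_hi - new_lo < 2:
            break
        lo, hi = new_lo, new_hi

    return best / (2.0 * n)


@dataclass(frozen=True)
class DipResult:
    dip: float
    p_value: float
    n: int
    n_boot: int


def dip_null_table(
    n: int, n_boot: int = 2000, seed: int | np.random.Generator | None = 0
) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform samples of size ``n`` (the null)."""
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_test(
    samples: Sequence[float],
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = 0,
    null_table: Optional[np.ndarray] = None,
) -> DipResult:
    """Dip statistic plus a bootstrap p-value from the uniform null.

    ``null_table`` may carry precomputed null dips (same sample size) so that
    many tests can share one reference distribution; the dip is invariant
    under strictly increasing transforms, so the uniform null is generic.
    """
    samples = np.asarray(samples, dtype=float)
    dip = dip_statistic(samples)
    if null_table is None:
        null_table = dip_null_table(samples.size, n_boot=n_boot, seed=seed)
    p = float(np.mean(null_table >= dip))
    return DipResult(dip=dip, p_value=p, n=samples.size, n_boot=len(null_table))


# ---------------------------------------------------------------------------
# Amplitude-Gaussian mixture on the histogram


@dataclass(frozen=True)
class MixtureFit:
    """Least-squares amplitude-Gaussian fit to a histogram density."""

    k: int
    components: tuple[tuple[float, float, float], ...]  # (amplitude, center, width)
    rss: float
    bins: int
    bin_edges: np.ndarray = field(repr=False, default=None)

    def density(self, x: Sequence[float]) -> np.ndarray:
        """Evaluate the fitted curve sum_i a_i exp(-((x-b_i)/c_i)^2)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for a, b, c in self.components:
            out += a * np.exp(-(((x - b) / c) ** 2))
        return out


def _model(params: np.ndarray, centers: np.ndarray) -> np.ndarray:
    k = params.size // 3
    a = params[0::3][:k]
    b = params[1::3][:k]
    c = params[2::3][:k]
    return np.sum(
        a[:, None] * np.exp(-(((centers[None, :] - b[:, None]) / c[:, None]) ** 2)),
        axis=0,
    )


def _model_jac(params: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the residuals w.r.t. (a_i, b_i, c_i) triples."""
    k = params.size // 3
    a = params[0::3][:k, None]
    b = params[1::3][:k, None]
    c = params[2::3][:k, None]
    z = (centers[None, :] - b) / c
    e = np.exp(-(z**2))
    jac = np.empty((centers.size, 3 * k))
    jac[:, 0::3] = e.T
    jac[:, 1::3] = (a * e * 2 * z / c).T
    jac[:, 2::3] = (a * e * 2 * z**2 / c).T
    return jac


def histogram_density(
    samples: Sequence[float], bins: int = 20, range_: tuple[float, float] = (0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram density and bin centers over a fixed range (default [0, 1])."""
    samples = np.asarray(samples, dtype=float)
    density, edges = np.histogram(samples, bins=bins, range=range_, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return density, centers, edges


def fit_mixture(
    samples: Sequence[float],
    k: int,
    bins: int = 20,
    seed: int | np.random.Generator | None = 0,
    n_restarts: int = 20,
    range_: tuple[float, float] = (0.0, 1.0),
    warm_start: Optional[MixtureFit] = None,
) -> MixtureFit:
    """Fit ``k`` amplitude-Gaussians to the sample histogram by least squares.

    Multi-start optimization: initial centers on sample quantiles plus
    seeded jitter; widths start at the sample scale over ``k``.  When
    ``warm_start`` carries a fit with fewer components, the previous solution
    extended by one negligible component joins the starts, which makes the
    best RSS non-increasing in ``k``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ValueError("mixture fit requires at least 10 samples")
    if not 1 <= k <= 10:
        raise ValueError("k must be in [1, 10]")
    rng = np.random.default_rng(seed)
    density, centers, edges = histogram_density(samples, bins=bins, range_=range_)
    span = range_[1] - range_[0]
    width0 = max(np.std(samples), span / (4 * bins)) / max(k, 1)
    amp0 = max(density.max(), 1e-3)

    lower = np.tile([0.0, range_[0] - 0.5 * span, span / (10 * bins)], k)
    upper = np.tile([10 * amp0 + 10.0, range_[1] + 0.5 * span, 2.0 * span], k)

    starts = []
    qs = np.linspace(0.1, 0.9, k)
    base_centers = np.quantile(samples, qs)
    for r in range(n_restarts):
        jitter = rng.normal(0.0, span * 0.05, size=k) if r else np.zeros(k)
        b = np.clip(base_centers + jitter, *[range_[0], range_[1]])
        c = np.full(k, width0) * rng.uniform(0.5, 1.5, size=k) if r else np.full(
            k, width0
        )
        a = np.full(k, amp0 / max(k, 1)) * (
            rng.uniform(0.5, 1.5, size=k) if r else 1.0
        )
        starts.append(np.column_stack([a, b, c]).ravel())
    if warm_start is not None and warm_start.k < k:
        prev = list(warm_start.components)
        resid = density - warm_start.density(centers)
        extra_b = centers[int(np.argmax(resid))]
        while len(prev) < k:
            prev.append((1e-6, extra_b, width0))
        starts.append(np.array(prev).ravel())

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)
        try:
            res = least_squares(
                lambda p: _model(p, centers) - density,
                p0,
                jac=lambda p: _model_jac(p, centers),
                bounds=(lower, upper),
                max_nfev=300,
            )
        except Exception:  # pragma: no cover - optimizer edge failures
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:  # pragma: no cover
        raise RuntimeError("mixture fit failed to converge from any start")
    rss, params = best
    comps = tuple(
        (float(params[3 * i]), float(params[3 * i + 1]), abs(float(params[3 * i + 2])))
        for i in range(k)
    )
    comps = tuple(sorted(comps, key=lambda t: -t[0]))  # largest amplitude first
    return MixtureFit(k=k, components=comps, rss=rss, bins=bins, bin_edges=edges)


@dataclass(frozen=True)
class KSelection:
    """Diagnostics of mixture-order selection."""

    k_rss: int
    k_silhouette: Optional[int]
    rss_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    fits: dict[int, MixtureFit] = field(repr=False, default_factory=dict)

    @property
    def k(self) -> int:
        """The operative choice: the RSS-elbow k."""
        return self.k_rss


def select_k(
    samples: Sequence[float],
    k_range: tuple[int, int] = (1, 10),
    bins: int = 20,
    seed: int | np.random.Generator | None = 0,
    elbow_threshold: float = 0.10,
    n_restarts: int = 5,
    range_: tuple[float, float] = (0.0, 1.0),
) -> KSelection:
    """Choose the number of mixture components.

    The RSS elbow is the first k whose RSS improvement when moving to k+1,
    measured relative to the histogram's total variation around its mean
    (i.e. the gain in R-squared), falls below ``elbow_threshold``.
    Normalizing by total variation rather than by the current RSS keeps the
    criterion meaningful when the residual is already near zero.  Separately,
    1-D k-means hard clusterings are scored with the silhouette index over
    k >= 2 (silhouette is undefined at k = 1) and the argmax reported as
    corroboration.
    """
    samples = np.asarray(samples, dtype=float)
    rng = np.random.default_rng(seed)
    k_min, k_max = k_range
    rss_by_k: dict[int, float] = {}
    fits: dict[int, MixtureFit] = {}
    prev = None
    for k in range(k_min, k_max + 1):
        fit = fit_mixture(
            samples,
            k,
            bins=bins,
            seed=rng,
            n_restarts=n_restarts,
            range_=range_,
            warm_start=prev,
        )
        if prev is not None and prev.rss < fit.rss:
            # keep the nested-model guarantee even if the optimizer stalls
            fit = MixtureFit(
                k=k, components=prev.components, rss=prev.rss, bins=bins,
                bin_edges=fit.bin_edges,
            )
        rss_by_k[k] = fit.rss
        fits[k] = fit
        prev = fit

    density, _, _ = histogram_density(samples, bins=bins, range_=range_)
    total_var = float(np.sum((density - density.mean()) ** 2))
    k_rss = k_max
    for k in range(k_min, k_max):
        improvement = (rss_by_k[k] - rss_by_k[k + 1]) / total_var if total_var else 0.0
        if improvement < elbow_threshold:
            k_rss = k
            break

    silhouette_by_k: dict[int, float] = {}
    col = samples.reshape(-1, 1)
    for k in range(max(2, k_min), k_max + 1):
        if k >= samples.size:
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=rng.integers(2**31))
        labels = km.fit_predict(col)
        if len(np.unique(labels)) < 2:
            continue
        silhouette_by_k[k] = float(silhouette_score(col, labels))
    k_sil = (
        max(silhouette_by_k, key=silhouette_by_k.get) if silhouette_by_k else None
    )
    return KSelection(
        k_rss=k_rss,
        k_silhouette=k_sil,
        rss_by_k=rss_by_k,
        silhouette_by_k=silhouette_by_k,
        fits=fits,
    )
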