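"""Pairwise Granger causality, adjacency binarization and baseline graphs.

A signal X "Granger-causes" Y when past values of X improve the linear
prediction of Y beyond Y's own past.  For each ordered channel pair the
module fits, by ordinary least squares on an identical sample range, the
restricted autoregression of the target on its own L lags and the full
regression that adds the source's L lags; the causality strength is the
log ratio of the two residual variances,

    F_{x -> y} = ln( var(eps_y | y past) / var(eta_y | y, x past) ) >= 0.

Per-band N x N matrices of these values are thresholded by rank: the
largest floor(N^2 * k) entries (diagonal included, fixed at 1) are kept
as an asymmetric binary adjacency.  Baseline adjacency builders (random,
electrode-distance kernel, phase-locking value) are provided for
comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class GCError(ValueError):
    """Raised for degenerate inputs to the causality estimators."""


@dataclass
class VARConfig:
    """Autoregression settings for the pairwise fits.

    ``lag`` is the model order L (default 5, i.e. ~40 ms of history at
    128 Hz); ``order_selection="bic"`` instead picks L per pair by the
    Bayesian information criterion of the full bivariate model over
    1..max_lag.
    """

    lag: int = 5
    order_selection: str = "fixed"  # "fixed" | "bic"
    max_lag: int = 10

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise GCError("lag order must be >= 1")
        if self.order_selection not in {"fixed", "bic"}:
            raise GCError("order_selection must be 'fixed' or 'bic'")


@dataclass
class GCMatrix:
    """Per-band causal weight matrix; ``values[i, j] = F_{j -> i}``
    (column = source, row = target), diagonal fixed to 1."""

    values: np.ndarray
    band: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise GCError("GC matrix must be square")


@dataclass
class BinaryAdjacency:
    """Thresholded {0,1} adjacency with retention fraction ``k``."""

    mask: np.ndarray
    k: float
    band: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise GCError("mask entries must be 0 or 1")

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum())


def _lag_design(x: np.ndarray, L: int) -> np.ndarray:
    """Columns x(t-1), ..., x(t-L) for t = L..n-1; shape (n-L, L)."""
    # sliding windows of length L ending at t-1, reversed so lag 1 comes first
    return sliding_window_view(x[:-1], L)[:, ::-1]


def _ols_rss(design: np.ndarray, y: np.ndarray, check_rank: bool = True) -> float:
    if check_rank:
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise GCError(
                f"singular design (rank {rank} < {design.shape[1]}): "
                "the two series are collinear"
            )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def _pair_F(x: np.ndarray, y: np.ndarray, L: int) -> tuple[float, float]:
    """(F_{x->y}, F_{y->x}) at fixed order L, identical sample range."""
    ylag, xlag = _lag_design(y, L), _lag_design(x, L)
    rss_y_uni = _ols_rss(ylag, y[L:])
    rss_x_uni = _ols_rss(xlag, x[L:])
    biv_y = np.hstack([ylag, xlag])
    biv_x = np.hstack([xlag, ylag])
    rss_y_biv = _ols_rss(biv_y, y[L:])
    rss_x_biv = _ols_rss(biv_x, x[L:])
    return float(np.log(rss_y_uni / rss_y_biv)), float(np.log(rss_x_uni / rss_x_biv))


def _bic_order(x: np.ndarray, y: np.ndarray, cfg: VARConfig) -> int:
    """Order minimizing the BIC of the full bivariate system over 1..max_lag."""
    n = len(x)
    best, best_bic = 1, np.inf
    for L in range(1, cfg.max_lag + 1):
        n_eff = n - L
        design = np.hstack([_lag_design(y, L), _lag_design(x, L)])
        rss = _ols_rss(design, y[L:], check_rank=False) + _ols_rss(design, x[L:], check_rank=False)
        bic = n_eff * np.log(rss / (2 * n_eff)) + 4 * L * np.log(n_eff)
        if bic < best_bic:
            best, best_bic = L, bic
    return best


def gc_pair(x: np.ndarray, y: np.ndarray, cfg: VARConfig | None = None) -> tuple[float, float]:
    """Granger causality between two series, both directions.

    Returns ``(F_{x->y}, F_{y->x})``, each the log ratio of the
    restricted to the full residual variance (non-negative up to
    numerical tolerance since the models are nested).  Series are
    demeaned before fitting.

    Raises
    ------
    GCError
        For series that are too short, constant, or exactly collinear.
    """
    cfg = cfg or VARConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise GCError("series must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise GCError("series contain non-finite values")
    L = cfg.lag if cfg.order_selection == "fixed" else None
    min_len = 4 * (L or cfg.max_lag) + 10
    if len(x) < min_len:
        raise GCError(f"series too short: need at least {min_len} samples")
    if x.std() == 0 or y.std() == 0:
        raise GCError("constant series")
    x = x - x.mean()
    y = y - y.mean()
    if L is None:
        L = _bic_order(x, y, cfg)
    return _pair_F(x, y, L)


def gc_matrix(
    data: np.ndarray,
    cfg: VARConfig | None = None,
    band: str | None = None,
) -> GCMatrix:
    """All-pairs causality matrix for one band of one window.

    ``data`` is channels x samples.  Entry (i, j), i != j, holds
    F_{j -> i}; the diagonal is fixed to 1.  All fits share one
    precomputed lag gram matrix, so the result is identical to calling
    :func:`gc_pair` on every pair (fixed order only).
    """
    cfg = cfg or VARConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise GCError("need a channels x samples array with >= 2 channels")
    N, n = data.shape
    L = cfg.lag
    if n < 4 * L + 10:
        raise GCError(f"series too short: need at least {4 * L + 10} samples")
    sd = data.std(axis=1)
    for i in np.flatnonzero(sd == 0):
        raise GCError(f"channel {i} is constant")
    X = data - data.mean(axis=1, keepdims=True)

    if cfg.order_selection == "bic":
        # per-pair order selection falls back to the pairwise path
        vals = np.eye(N)
        for i in range(N):
            for j in range(i + 1, N):
                f_ij, f_ji = gc_pair(X[i], X[j], cfg)
                vals[j, i] = f_ij  # i -> j stored at row j, col i
                vals[i, j] = f_ji
        return GCMatrix(vals, band=band)

    # lag design for every channel at once: Z[:, c*L + (l-1)] = X[c, t-l]
    Z = np.concatenate([_lag_design(X[c], L) for c in range(N)], axis=1)
    Y = X[:, L:].T  # (n-L, N)
    G = Z.T @ Z
    g = Z.T @ Y
    yy = np.einsum("tc,tc->c", Y, Y)

    def _rss(cols: np.ndarray, target: int) -> float:
        Gs = G[np.ix_(cols, cols)]
        gs = g[cols, target]
        try:
            beta = np.linalg.solve(Gs, gs)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(Gs, gs, rcond=None)[0]
        return float(yy[target] - gs @ beta)

    cols_of = [np.arange(c * L, (c + 1) * L) for c in range(N)]
    rss_uni = np.array([_rss(cols_of[i], i) for i in range(N)])
    vals = np.eye(N)
    for i in range(N):  # target
        for j in range(N):  # source
            if i == j:
                continue
            rss_biv = _rss(np.concatenate([cols_of[i], cols_of[j]]), i)
            vals[i, j] = np.log(rss_uni[i] / max(rss_biv, 1e-300))
    return GCMatrix(vals, band=band)


def binarize(gc: GCMatrix, k: float) -> BinaryAdjacency:
    """Keep the largest ``floor(N^2 * k)`` entries as an asymmetric mask.

    The diagonal (value 1) always survives and counts toward the total,
    which is clamped to at least N; off-diagonal ties are broken in
    row-major order.  Because selection is by rank, any strictly
    increasing transform of the off-diagonal values leaves the mask
    unchanged.
    """
    if not (0.0 < k < 1.0):
        raise GCError(f"retention fraction k={k} outside (0, 1)")
    vals = gc.values
    N = vals.shape[0]
    m = max(int(np.floor(N * N * k)), N)
    mask = np.eye(N, dtype=int)
    n_off = m - N
    if n_off > 0:
        off = ~np.eye(N, dtype=bool)
        flat_idx = np.flatnonzero(off.ravel())
        order = np.argsort(-vals.ravel()[flat_idx], kind="stable")
        keep = flat_idx[order[:n_off]]
        mask.ravel()[keep] = 1
    return BinaryAdjacency(mask, k=k, band=gc.band)


def threshold_sweep(
    gc_stream: GCMatrix | list[GCMatrix],
    k_grid: list[float],
) -> dict[float, list[BinaryAdjacency]]:
    """Binarize one or many matrices over a grid of retention fractions.

    The 1-sets are nested across k: every edge kept at a smaller k is
    kept at any larger k.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise GCError("empty k grid")
    if isinstance(gc_stream, GCMatrix):
        gc_stream = [gc_stream]
    return {k: [binarize(gc, k) for gc in gc_stream] for k in sorted(k_grid)}


def plv_matrix(band_data: np.ndarray) -> np.ndarray:
    """Phase-locking value between all channel pairs of band-limited data.

    PLV_ij = |mean_t exp(i (phi_i(t) - phi_j(t)))| with instantaneous
    phases from the analytic (Hilbert) signal; symmetric, in [0, 1],
    diagonal 1.
    """
    from scipy.signal import hilbert

    phases = np.angle(hilbert(np.asarray(band_data, dtype=float), axis=-1))
    phasors = np.exp(1j * phases)
    M = phasors @ phasors.conj().T / phases.shape[-1]
    return np.abs(M)


def baseline_adjacency(
    kind: str,
    *,
    n_channels: int | None = None,
    k: float = 0.5,
    seed: int | None = None,
    coords: np.ndarray | None = None,
    sigma: float | None = None,
    band_data: np.ndarray | None = None,
) -> np.ndarray:
    """Comparison adjacency matrices: random, electrode distance, or PLV.

    - ``random``: symmetric Bernoulli(k) mask (seeded), diagonal 1;
    - ``distance``: Gaussian kernel exp(-d_ij^2 / (2 sigma^2)) of the
      inter-electrode distances (sigma defaults to the mean pairwise
      distance);
    - ``plv``: phase-locking value of ``band_data``.
    """
    if kind == "random":
        if n_channels is None:
            raise GCError("random baseline needs n_channels")
        rng = np.random.default_rng(seed)
        upper = rng.random((n_channels, n_channels)) < k
        mask = np.triu(upper, 1)
        out = (mask | mask.T).astype(float)
        np.fill_diagonal(out, 1.0)
        return out
    if kind == "distance":
        if coords is None:
            raise GCError("distance baseline needs electrode coordinates")
        coords = np.asarray(coords, dtype=float)
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        if sigma is None:
            off = d2[~np.eye(len(coords), dtype=bool)]
            sigma = float(np.sqrt(off.mean())) or 1.0
        return np.exp(-d2 / (2.0 * sigma**2))
    if kind == "plv":
        if band_data is None:
            raise GCError("plv baseline needs band-limited data")
        return plv_matrix(band_data)
    raise GCError(f"unknown baseline kind '{kind}'")


def permutation_null(
    x: np.ndarray,
    y: np.ndarray,
    cfg: VARConfig | None = None,
    n_perm: int = 200,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Observed F_{x->y} and its permutation null distribution.

    The null shuffles the source series (destroying its temporal
    alignment) and refits only the full model; the restricted fit does
    not involve x and is reused.  Intended as a significance utility for
    testing, not as the adjacency itself.
    """
    cfg = cfg or VARConfig()
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float) - np.mean(x)
    y = np.asarray(y, dtype=float) - np.mean(y)
    L = cfg.lag
    ylag = _lag_design(y, L)
    yt = y[L:]
    rss_uni = _ols_rss(ylag, yt, check_rank=False)
    observed = float(np.log(rss_uni / _ols_rss(np.hstack([ylag, _lag_design(x, L)]), yt, check_rank=False)))
    null = np.empty(n_perm)
    for p in range(n_perm):
        xp = rng.permutation(x)
        rss_biv = _ols_rss(np.hstack([ylag, _lag_design(xp, L)]), yt, check_rank=False)
        null[p] = np.log(rss_uni / rss_biv)
    return observed, null
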