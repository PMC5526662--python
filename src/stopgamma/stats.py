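"""Group-level inference: paired t/z maps, cluster-based permutation
correction, Spearman correlations with bootstrap CIs, Fisher-z group tests,
BH-FDR and normality-gated paired tests.

The multiple-comparison correction over time-frequency (or time) grids is
the max-statistic cluster permutation scheme: per-pixel paired t over
subjects, converted to z via the probit of the two-sided p; contiguous
suprathreshold pixels (|z| above the two-sided p < 0.05 threshold,
4-connectivity) form clusters whose mass is the sum of z inside.  The null
is built from 2000 random subject-level sign flips (each subject's paired
difference keeps its pairing, only the order of subtraction may change),
recording the single largest absolute cluster mass per permutation; a
cluster is significant when its |mass| exceeds the 95th percentile of that
null.  Positive and negative clusters are tested against the same
absolute-mass null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as st
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ClusterResult",
    "group_z_map",
    "cluster_permutation",
    "cluster_permutation_1d",
    "spearman_bootstrap",
    "fisherz_group_test",
    "bh_fdr",
    "max_corr_search",
    "paired_test",
]

#: |z| guard for zero-variance pixels (probit of ~1e-16).
Z_GUARD = 8.21


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Signed probit of the two-sided t p-value; capped at +-Z_GUARD."""
    t = np.asarray(t, dtype=np.float64)
    p = 2.0 * st.t.sf(np.abs(t), df)
    with np.errstate(divide="ignore"):
        z = st.norm.isf(np.clip(p / 2.0, 1e-300, 1.0))
    return np.clip(z, 0, Z_GUARD) * np.sign(t)


def _paired_t(diffs: np.ndarray):
    """Pixel-wise one-sample t over the subject axis (axis 0)."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var):
        t = np.where(zero_var, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)
    return t, n - 1


def group_z_map(a: np.ndarray, b: np.ndarray):
    """Paired t and z maps of condition A - B over subjects.

    *a*, *b* are ``(n_subjects, ...)`` arrays on identical grids; needs at
    least two subjects.  Pixels with zero across-subject variance get the
    +-Z_GUARD value (flagged via a warning).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("condition arrays must share one grid")
    if a.shape[0] < 2:
        raise ValueError("need at least two subjects")
    t, df = _paired_t(a - b)
    inf_mask = np.isinf(t)
    if np.any(inf_mask):
        warnings.warn("zero across-subject variance at some pixels; z capped")
    z = _t_to_z(np.where(inf_mask, 0.0, t), df)
    z = np.where(inf_mask, np.sign(t) * Z_GUARD, z)
    return t, z


@dataclass
class Cluster:
    mask: np.ndarray
    mass: float
    sign: int
    p_perm: float

    def bbox(self) -> tuple:
        sl = ndimage.find_objects(self.mask.astype(int))[0]
        return tuple((s.start, s.stop) for s in sl)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    sig_mask: np.ndarray
    z_map: np.ndarray
    null_max_mass: np.ndarray
    threshold_p: float
    n_perm: int
    alpha: float
    seed: int

    def significant(self) -> list[Cluster]:
        thr = float(np.quantile(self.null_max_mass, 1.0 - self.alpha)) \
            if len(self.null_max_mass) else np.inf
        return [c for c in self.clusters if abs(c.mass) > thr]

    def summary(self) -> list[dict]:
        return [
            dict(sign=c.sign, mass=float(c.mass), p_perm=float(c.p_perm),
                 bbox=c.bbox(), n_pixels=int(c.mask.sum()))
            for c in self.clusters
        ]


def _structure(ndim: int) -> np.ndarray:
    # 4-connectivity: orthogonal neighbors only, no diagonals
    return ndimage.generate_binary_structure(ndim, 1)


def _extract_clusters(z: np.ndarray, thr: float, structure: np.ndarray):
    """(mask, mass, sign) triples for positive and negative clusters."""
    out = []
    for sign in (1, -1):
        lab, nlab = ndimage.label(sign * z > thr, structure=structure)
        if nlab == 0:
            continue
        masses = ndimage.sum_labels(z, lab, index=np.arange(1, nlab + 1))
        for k, mass in enumerate(masses, start=1):
            out.append((lab == k, float(mass), sign))
    return out


def _t_to_z_thresholded(t: np.ndarray, df: int, t_crit: float) -> np.ndarray:
    """z map that is exact above the cluster-forming threshold, 0 below.

    Sub-threshold pixels never contribute to cluster masses, so their z is
    irrelevant; the supra-threshold conversion uses a dense monotone
    interpolation table (|z| error < 1e-6), which keeps the permutation
    loop cheap.
    """
    grid = np.linspace(t_crit * 0.999, 50.0, 6000)
    zg = _t_to_z(grid, df)
    z = np.zeros_like(t)
    mask = np.abs(t) > t_crit
    sub = t[mask]
    z[mask] = np.interp(np.abs(sub), grid, zg) * np.sign(sub)
    return z


def _max_masses(z_perms: np.ndarray, thr: float, structure: np.ndarray) -> np.ndarray:
    """Largest absolute suprathreshold-cluster mass per permutation map.

    All permutation maps are labeled in one pass by stacking them along a
    leading axis whose connectivity is switched off, so clusters never
    bridge permutations.
    """
    n_perm = z_perms.shape[0]
    st3 = np.zeros((3,) * z_perms.ndim, dtype=bool)
    st3[1] = structure
    out = np.zeros(n_perm)
    perm_ix = np.broadcast_to(
        np.arange(n_perm).reshape((n_perm,) + (1,) * (z_perms.ndim - 1)),
        z_perms.shape,
    )
    for sign in (1, -1):
        lab, nlab = ndimage.label(sign * z_perms > thr, structure=st3)
        if nlab == 0:
            continue
        index = np.arange(1, nlab + 1)
        masses = np.abs(ndimage.sum_labels(z_perms, lab, index=index))
        owner = ndimage.minimum(perm_ix, lab, index=index).astype(int)
        np.maximum.at(out, owner, masses)
    return out


def cluster_permutation(
    diffs: np.ndarray,
    n_perm: int = 2000,
    threshold_p: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-mass permutation test of paired differences against zero.

    *diffs* is ``(n_subjects, n_freq, n_time)`` (or ``(n_subjects, n_time)``
    for 1-D data).  See the module docstring for the procedure.  The
    permutation p of each cluster is ``(1 + #{null >= |mass|}) / (n_perm + 1)``;
    ``sig_mask`` marks clusters whose |mass| exceeds the ``1 - alpha``
    quantile of the max-mass null.
    """
    diffs = np.asarray(diffs, dtype=np.float64)
    if diffs.ndim not in (2, 3):
        raise ValueError("diffs must be (subjects, time) or (subjects, freq, time)")
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")
    grid_shape = diffs.shape[1:]
    structure = _structure(len(grid_shape))
    t, df = _paired_t(diffs)
    t = np.where(np.isinf(t), np.sign(t) * 1e6, t)
    z = _t_to_z(t, df)
    z_thr = st.norm.isf(threshold_p / 2.0)

    clusters_raw = _extract_clusters(z, z_thr, structure)

    # vectorized sign-flip null: sum of squares is flip-invariant, so the
    # permuted t-map is a pure function of the flipped mean
    rng = np.random.default_rng(seed)
    flat = diffs.reshape(n, -1)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    m = signs @ flat / n
    sumsq = np.sum(flat**2, axis=0)
    var = np.maximum(sumsq / n - m**2, 0.0) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m / np.sqrt(var / n)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=1e6, neginf=-1e6)
    t_crit = st.t.isf(threshold_p / 2.0, df)
    z_perm = _t_to_z_thresholded(t_perm, df, t_crit).reshape(n_perm, *grid_shape)
    null = _max_masses(z_perm, z_thr, structure)

    clusters = []
    sig_mask = np.zeros(grid_shape, dtype=bool)
    crit = float(np.quantile(null, 1.0 - alpha)) if n_perm else np.inf
    for mask, mass, sign in clusters_raw:
        p = (1.0 + np.sum(null >= abs(mass))) / (n_perm + 1.0)
        clusters.append(Cluster(mask=mask, mass=mass, sign=sign, p_perm=float(p)))
        if abs(mass) > crit:
            sig_mask |= mask
    return ClusterResult(clusters=clusters, sig_mask=sig_mask, z_map=z,
                         null_max_mass=null, threshold_p=threshold_p,
                         n_perm=n_perm, alpha=alpha, seed=seed)


def cluster_permutation_1d(diffs: np.ndarray, **kwargs) -> ClusterResult:
    """1-D (time-course) variant of :func:`cluster_permutation`."""
    diffs = np.asarray(diffs, dtype=np.float64)
    if diffs.ndim != 2:
        raise ValueError("diffs must be (subjects, time)")
    return cluster_permutation(diffs, **kwargs)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return st.rankdata(a, axis=axis)


def spearman_bootstrap(x, y, n_boot: int = 2000, seed: int = 0):
    """Spearman rho with a percentile bootstrap CI over paired resamples.

    Returns ``(rho, (lo, hi))``; rho is NaN with a NaN CI when either input
    is constant (undefined ranks).  Ties get average ranks.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 5 or len(y) != n:
        raise ValueError("need at least 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), (float("nan"), float("nan"))
    rho = float(st.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    rx = _rank(x[idx])
    ry = _rank(y[idx])
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = (rx * ry).sum(axis=1) / denom
    boots = boots[np.isfinite(boots)]
    if boots.size == 0:
        return rho, (float("nan"), float("nan"))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return rho, (float(lo), float(hi))


def fisherz_group_test(rhos):
    """One-sample t-test of Fisher-z transformed per-subject correlations.

    ``z = atanh(rho)``; |rho| = 1 values are excluded with a warning.
    Returns ``(t, p, (ci_lo, ci_hi))`` with the CI on the mean z scale.
    """
    rhos = np.asarray(rhos, dtype=np.float64)
    keep = np.abs(rhos) < 1.0
    if not np.all(keep):
        warnings.warn("dropping |rho| = 1 values (infinite Fisher z)")
    z = np.arctanh(rhos[keep])
    if len(z) < 2:
        raise ValueError("need at least two finite Fisher-z values")
    if np.ptp(z) == 0:  # degenerate: identical z for every subject
        m = float(z[0])
        if m == 0.0:
            return 0.0, 1.0, (0.0, 0.0)
        return float(np.sign(m) * np.inf), 0.0, (m, m)
    res = st.ttest_1samp(z, 0.0)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(res.pvalue), (float(ci.low), float(ci.high))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def max_corr_search(
    epochs: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    extents: np.ndarray,
    band: tuple[float, float] = (60.0, 90.0),
    window: tuple[float, float] = (0.0, 0.156),
    n_boot: int = 2000,
    seed: int = 0,
):
    """Strongest trial-wise extent/power Spearman correlation in a TF window.

    *epochs* is ``(n_trials, n_freq, n_time)``; every pixel with frequency
    in *band* and time in ``[window)`` is correlated with the movement
    extents across trials; the extremum by |rho| is returned as
    ``(rho, freq_hz, time_s, (ci_lo, ci_hi))`` with a bootstrap CI at that
    pixel.  NaN rho (constant extent) propagates as missing.
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    extents = np.asarray(extents, dtype=np.float64)
    if epochs.shape[0] != len(extents):
        raise ValueError("one extent per trial required")
    if epochs.shape[0] < 5:
        raise ValueError("need at least 5 trials")
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    tmask = (times >= window[0]) & (times < window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("search window selects no pixels")
    if np.all(extents == extents[0]):
        return float("nan"), float("nan"), float("nan"), (float("nan"), float("nan"))
    sub = epochs[:, fmask][:, :, tmask]  # trials x F x T
    n_tr = sub.shape[0]
    re = _rank(extents) - (n_tr + 1) / 2.0
    rp = _rank(sub.reshape(n_tr, -1), axis=0) - (n_tr + 1) / 2.0
    denom = np.sqrt((re**2).sum() * (rp**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = re @ rp / denom
    k = int(np.nanargmax(np.abs(rhos)))
    fi, ti = np.unravel_index(k, (fmask.sum(), tmask.sum()))
    best_rho = float(rhos[k])
    _, ci = spearman_bootstrap(extents, sub[:, fi, ti], n_boot=n_boot, seed=seed)
    return best_rho, float(freqs[fmask][fi]), float(times[tmask][ti]), ci


def paired_test(a, b, alpha_normality: float = 0.05):
    """Paired test with a Lilliefors normality gate on the differences.

    t-test when normality of the differences is not rejected, otherwise a
    Wilcoxon signed-rank test (exact for n <= 15).  Returns
    ``(statistic, p, test_used)``; all-zero differences give ``p = 1`` with
    the ``"degenerate"`` label.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("need paired 1-D samples with n >= 5")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0, "degenerate"
    p_norm = lilliefors(d, dist="norm", pvalmethod="table")[1]
    if p_norm < alpha_normality:
        mode = "exact" if len(d) <= 15 else "auto"
        res = st.wilcoxon(a, b, mode=mode)
        return float(res.statistic), float(res.pvalue), "wilcoxon"
    res = st.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), "ttest"
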