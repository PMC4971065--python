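"""Polarity-invariant modified K-means over GFP-peak topographies.

Microstate template maps are defined only up to sign: a map and its
negation belong to the same class.  Clustering therefore assigns each
peak topography to the template with the highest *absolute* spatial
correlation, and the objective is the global explained variance

    GEV = sum_p (GFP_p * rho_p)^2 / sum_p GFP_p^2,

the GFP-weighted squared spatial correlation between each peak map and
its assigned template.  The module also provides the cross-validation
criterion for choosing the number of classes, canonical A-D labeling by
optimal assignment against reference maps, and the topographic
permutation test (TANOVA) on global map dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gfp import TopographySet
from .io_formats import Montage

_EPS = 1e-12


@dataclass
class TemplateSet:
    """K microstate template maps, each average-referenced and unit-norm."""

    templates: np.ndarray  # (K, n_channels)
    labels: tuple[str, ...]

    def __post_init__(self):
        t = np.asarray(self.templates, dtype=float)
        if t.ndim != 2:
            raise ValueError("templates must be K x channels")
        if len(self.labels) != t.shape[0]:
            raise ValueError("one label per template required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("template labels must be unique")
        t = t - t.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(t, axis=1)
        if np.any(norms < _EPS):
            raise ValueError("constant (zero-variance) template map")
        self.templates = t / norms[:, None]
        self.labels = tuple(self.labels)

    @property
    def K(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class ClusteringResult:
    templates: TemplateSet
    assignments: np.ndarray  # per-peak template index
    polarity: np.ndarray  # per-peak sign of the winning correlation
    gev_total: float
    gev_per_template: np.ndarray
    cv_criterion: float
    n_iterations: int
    converged: bool


def default_labels(K: int) -> tuple[str, ...]:
    return tuple(chr(ord("A") + i) for i in range(K))


def spatial_correlation(u: np.ndarray, w: np.ndarray) -> float:
    """Signed Pearson correlation across channels of two topographies.

    Callers use the absolute value for class assignment and the sign for
    polarity alignment.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.shape != w.shape:
        raise ValueError("topographies must have equal channel counts")
    uc = u - u.mean()
    wc = w - w.mean()
    nu, nw = np.linalg.norm(uc), np.linalg.norm(wc)
    if nu < _EPS or nw < _EPS:
        raise ValueError("constant (zero-GFP) topography")
    return float(uc @ wc / (nu * nw))


def _prepare_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each map; return unit-norm maps and their GFP values."""
    x = np.asarray(maps, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms < _EPS):
        raise ValueError("zero-GFP peak map in input; exclude upstream")
    gfp = norms / np.sqrt(x.shape[1])
    return x / norms[:, None], gfp


def _gev(u: np.ndarray, gfp: np.ndarray, templates: np.ndarray,
         labels: np.ndarray) -> tuple[float, np.ndarray]:
    rho = np.einsum("pc,pc->p", u, templates[labels])
    contrib = (gfp * rho) ** 2
    denom = float(np.sum(gfp**2))
    K = templates.shape[0]
    per = np.array([contrib[labels == k].sum() for k in range(K)]) / denom
    return float(per.sum()), per


def _update_templates(
    u: np.ndarray,
    x: np.ndarray,
    gfp: np.ndarray,
    corr: np.ndarray,
    labels: np.ndarray,
    K: int,
    how: str,
) -> np.ndarray:
    C = u.shape[1]
    new = np.empty((K, C))
    fit = np.abs(corr[np.arange(len(labels)), labels])
    for k in range(K):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            # re-seed an empty cluster from the worst-fit peak
            worst = int(np.argmin(fit))
            members = np.array([worst])
        if how == "mean":
            signs = np.sign(corr[members, k])
            signs[signs == 0] = 1.0
            t = (signs[:, None] * x[members]).mean(axis=0)
        elif how == "eigen":
            um = u[members]
            w = gfp[members] ** 2
            cov = (um * w[:, None]).T @ um
            vals, vecs = np.linalg.eigh(cov)
            t = vecs[:, -1]
        else:
            raise ValueError(f"unknown template update {how!r}")
        t = t - t.mean()
        n = np.linalg.norm(t)
        if n < _EPS:  # degenerate cancellation; fall back to first member
            t = u[members[0]]
            n = 1.0
        new[k] = t / n
    return new


def modified_kmeans(
    tset: TopographySet | np.ndarray,
    K: int,
    n_restarts: int = 50,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    template_update: str = "mean",
) -> ClusteringResult:
    """Polarity-invariant modified K-means on peak topographies.

    Each restart seeds templates from K randomly chosen peak maps, then
    alternates (i) assignment of every peak to the template with the
    highest absolute spatial correlation and (ii) template re-estimation
    from the assigned maps, each flipped to the template's polarity
    before averaging (``template_update="mean"``, the classical step) or
    replaced by the GFP^2-weighted principal eigenvector of the member
    maps (``"eigen"``, the exact GEV optimizer for a fixed assignment).
    Iteration stops when the relative GEV change falls below ``tol``;
    the restart with the highest total GEV wins.
    """
    maps = tset.maps if isinstance(tset, TopographySet) else np.asarray(tset)
    n = maps.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError(f"need at least K={K} peaks, got {n}")
    u, gfp = _prepare_maps(maps)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = u * (gfp * np.sqrt(u.shape[1]))[:, None]  # centered raw-scale maps

    best: tuple[float, np.ndarray, np.ndarray, int, bool] | None = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=K, replace=False)
        templates = u[idx].copy()
        prev_gev = -np.inf
        converged = False
        labels = np.zeros(n, dtype=int)
        for it in range(1, max_iter + 1):
            corr = u @ templates.T
            labels = np.argmax(np.abs(corr), axis=1)
            templates = _update_templates(u, x, gfp, corr, labels, K, template_update)
            corr = u @ templates.T
            labels = np.argmax(np.abs(corr), axis=1)
            gev, _ = _gev(u, gfp, templates, labels)
            if abs(gev - prev_gev) < tol * max(abs(prev_gev), _EPS):
                converged = True
                break
            prev_gev = gev
        gev, _ = _gev(u, gfp, templates, labels)
        if best is None or gev > best[0]:
            best = (gev, templates, labels, it, converged)

    gev_total, templates, labels, n_iter, converged = best
    corr = u @ templates.T
    winning = corr[np.arange(n), labels]
    polarity = np.where(winning >= 0, 1, -1)
    _, per = _gev(u, gfp, templates, labels)
    sigma2 = _residual_variance(u, gfp, templates, labels)
    C = u.shape[1]
    cv = sigma2 * ((C - 1) / (C - 1 - K)) ** 2 if K < C - 1 else np.inf
    return ClusteringResult(
        templates=TemplateSet(templates, default_labels(K)),
        assignments=labels,
        polarity=polarity,
        gev_total=gev_total,
        gev_per_template=per,
        cv_criterion=float(cv),
        n_iterations=n_iter,
        converged=converged,
    )


def _residual_variance(u, gfp, templates, labels) -> float:
    """Mean per-peak residual variance after projection on the assigned template."""
    C = u.shape[1]
    rho = np.einsum("pc,pc->p", u, templates[labels])
    norm2 = gfp**2 * C  # squared norm of each centered map
    resid = norm2 * np.maximum(0.0, 1.0 - rho**2)
    return float(np.mean(resid) / (C - 1))


def select_k(
    tset: TopographySet | np.ndarray,
    k_range=range(2, 7),
    n_restarts: int = 20,
    seed: int = 0,
    **kwargs,
) -> tuple[int, dict[int, float], dict[int, ClusteringResult]]:
    """Choose K by the predictive-residual cross-validation criterion.

    CV(K) = sigma_hat^2 * ((C-1)/(C-1-K))^2 with sigma_hat^2 the mean
    per-peak residual variance after projecting each map on its assigned
    template; the penalty factor charges each extra class.  Returns the
    argmin K, the per-K criterion, and the fitted results.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    maps = tset.maps if isinstance(tset, TopographySet) else np.asarray(tset)
    C = maps.shape[1]
    if max(k_range) >= C - 1:
        raise ValueError("max(k_range) must be < n_channels - 1")
    rng = np.random.default_rng(seed)
    cvs: dict[int, float] = {}
    results: dict[int, ClusteringResult] = {}
    for K in k_range:
        res = modified_kmeans(maps, K, n_restarts=n_restarts, seed=rng, **kwargs)
        cvs[K] = res.cv_criterion
        results[K] = res
    # near-ties (at the round-off scale of the data variance) resolve to
    # the smallest K: the criterion asks for the fewest maps that explain
    # the variance
    x = maps - maps.mean(axis=1, keepdims=True)
    scale = float(np.mean(np.sum(x**2, axis=1)) / (C - 1))
    cv_min = min(cvs.values())
    chosen = min(K for K in k_range if cvs[K] <= cv_min + 1e-12 * scale)
    return chosen, cvs, results


def canonical_reference_maps(montage: Montage) -> TemplateSet:
    """Reference topographies for canonical A-D labeling, built from geometry.

    Synthetic stand-ins for the normative maps of the resting-state
    literature: A and B are the two oblique posterior-anterior gradients
    (left-posterior/right-anterior and its mirror image), C the
    occipital-frontal gradient, and D a fronto-central focal pattern.
    They serve only to anchor label order; any topography set can be
    matched against them by absolute spatial correlation.
    """
    pos = montage.positions
    pos = (pos - pos.mean(axis=0)) / np.abs(pos - pos.mean(axis=0)).max()
    dir_a = np.array([1.0, 0.8])
    dir_b = np.array([-1.0, 0.8])
    dir_c = np.array([0.0, 1.0])
    maps = np.vstack([
        -(pos @ dir_a),            # A: left-posterior positive
        -(pos @ dir_b),            # B: right-posterior positive
        -(pos @ dir_c),            # C: occipital positive
        np.exp(-np.sum((pos - np.array([0.0, 0.15])) ** 2, axis=1) / (2 * 0.45**2)),
    ])
    return TemplateSet(maps, ("A", "B", "C", "D"))


def canonical_labeling(
    result: ClusteringResult, reference: TemplateSet
) -> ClusteringResult:
    """Relabel templates by optimal one-to-one matching against a reference.

    Maximizes the total absolute spatial correlation over all
    permutations (Hungarian algorithm; identical to exhaustive search).
    Templates are reordered to reference-label order and assignments
    remapped accordingly.
    """
    tpl = result.templates
    if tpl.K != reference.K:
        raise ValueError("template count does not match reference")
    score = np.abs(tpl.templates @ reference.templates.T)
    row, col = linear_sum_assignment(-score)
    # order templates so that new row i carries reference label i
    order = row[np.argsort(col)]
    remap = np.empty(tpl.K, dtype=int)
    remap[order] = np.arange(tpl.K)
    return ClusteringResult(
        templates=TemplateSet(tpl.templates[order], reference.labels),
        assignments=remap[result.assignments],
        polarity=result.polarity.copy(),
        gev_total=result.gev_total,
        gev_per_template=result.gev_per_template[order],
        cv_criterion=result.cv_criterion,
        n_iterations=result.n_iterations,
        converged=result.converged,
    )


def _diss(u: np.ndarray, w: np.ndarray) -> float:
    """Global map dissimilarity between two maps, polarity-aligned."""
    uc = u - u.mean()
    wc = w - w.mean()
    gu = np.sqrt(np.mean(uc**2))
    gw = np.sqrt(np.mean(wc**2))
    if gu < _EPS or gw < _EPS:
        raise ValueError("zero-GFP mean map in TANOVA")
    if uc @ wc < 0:
        wc = -wc
    return float(np.sqrt(np.mean((uc / gu - wc / gw) ** 2)))


def tanova(
    group_a: TopographySet | np.ndarray,
    group_b: TopographySet | np.ndarray,
    n_perm: int | str = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Topographic permutation test on global map dissimilarity.

    The statistic is the DISS between the two group-mean maps (each
    normalized to unit GFP, polarity-aligned).  Group labels are
    permuted; ``n_perm="exact"`` enumerates every split of the pooled
    maps with the observed group sizes.  The observed statistic counts
    in both numerator and denominator, so the smallest attainable p is
    1/(n_perm+1).
    """
    a = group_a.maps if isinstance(group_a, TopographySet) else np.asarray(group_a)
    b = group_b.maps if isinstance(group_b, TopographySet) else np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    observed = _diss(a.mean(axis=0), b.mean(axis=0))
    pooled = np.vstack([a, b])
    n_a, n_tot = a.shape[0], a.shape[0] + b.shape[0]

    def stat(idx_a: np.ndarray) -> float:
        mask = np.zeros(n_tot, dtype=bool)
        mask[idx_a] = True
        return _diss(pooled[mask].mean(axis=0), pooled[~mask].mean(axis=0))

    if n_perm == "exact":
        count = 0
        total = 0
        for idx in combinations(range(n_tot), n_a):
            total += 1
            if stat(np.asarray(idx)) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 1  # observed split
        for _ in range(int(n_perm)):
            idx = rng.choice(n_tot, size=n_a, replace=False)
            if stat(idx) >= observed - 1e-12:
                count += 1
        p = count / (int(n_perm) + 1)
    return observed, p
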