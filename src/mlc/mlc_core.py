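"""Learning non-negative, L1-sparsified per-sample weights for co-expression.

For a GO term l, gene pairs fall into three groups: both annotated
(p-p), exactly one annotated (p-n), neither (n-n). The weights w >= 0
of the weighted inner product S_w are chosen to separate the
distribution of p-p similarities from that of p-n similarities, as
measured by Welch's two-sample t-statistic

    t(w) = (mu_pp - mu_pn) / sqrt(var_pp / N_pp + var_pn / N_pn),

where mu/var are the mean and (unbiased) variance of S_w over the pairs
in each group and N_* the pair counts. n-n pairs never enter the
objective. The fitted weights minimize

    -alpha * t(w) + (1 - alpha) * sum_m w_m,   w_m >= 0,

so alpha in (0, 1) trades separability against L1 sparsity; t is
invariant to positive rescaling of w, hence the L1 term alone fixes the
scale and drives uninformative samples to exactly zero.

Because S_w is linear in w, all pair means and variances are quadratic
forms in w. They are accumulated into per-sample moment vectors and
sample x sample moment matrices once per partition, making each
objective/gradient evaluation O(f^2) regardless of the number of gene
pairs. When f^2 matrices would exceed a memory cap, the statistics are
instead estimated from a seeded uniform subsample of explicit pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .preprocess import ScaledExpression
from .similarity import SELECTION_EPS, WeightVector

__all__ = [
    "PairPartition",
    "GlobalPairs",
    "PairMoments",
    "SampledPairMoments",
    "MLCModel",
    "partition_pairs",
    "partition_pairs_global",
    "build_pair_moments",
    "welch_t",
    "objective",
    "objective_grad",
    "fit_mlc",
    "fit_mlc_global",
    "selected_samples",
]

#: variances below this are treated as exactly zero (degenerate t)
VARIANCE_FLOOR = 1e-12

#: exact moment matrices are built only when 4 * f^2 doubles fit the cap
DEFAULT_MOMENT_MEMORY_CAP_BYTES = 2_000_000_000

#: pairs per class kept in the subsampling fallback
DEFAULT_MAX_SAMPLED_PAIRS = 100_000

DEFAULT_ALPHA = 0.99


@dataclass(frozen=True)
class PairPartition:
    """Positive/negative gene index sets for one term's pair groups."""

    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.positives, dtype=int)
        Q = np.asarray(self.negatives, dtype=int)
        object.__setattr__(self, "positives", P)
        object.__setattr__(self, "negatives", Q)
        if np.intersect1d(P, Q).size:
            raise ValueError("positive and negative index sets overlap")
        if P.size < 2:
            raise ValueError("need at least 2 positive genes for p-p pairs")
        if Q.size < 1:
            raise ValueError("need at least 1 negative gene for p-n pairs")

    @property
    def n_pp(self) -> int:
        k = self.positives.size
        return k * (k - 1) // 2

    @property
    def n_pn(self) -> int:
        return self.positives.size * self.negatives.size


@dataclass(frozen=True)
class GlobalPairs:
    """Explicit pair index arrays for the term-agnostic (global) variant:
    p-p pairs share at least one informative GO term, p-n pairs share none."""

    pp_pairs: np.ndarray  # (n_pp, 2) int
    pn_pairs: np.ndarray  # (n_pn, 2) int

    @property
    def n_pp(self) -> int:
        return self.pp_pairs.shape[0]

    @property
    def n_pn(self) -> int:
        return self.pn_pairs.shape[0]


def partition_pairs(y: np.ndarray) -> PairPartition:
    """Split genes into positives (annotated with the term) and negatives."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return PairPartition(positives=np.flatnonzero(y == 1), negatives=np.flatnonzero(y == 0))


def partition_pairs_global(
    gene_terms: dict[str, set[str]],
    genes: tuple[str, ...] | list[str],
) -> GlobalPairs:
    """Classify every gene pair by whether it shares an informative GO term.

    Terms annotated to every annotated gene (the root and anything with
    zero information content) are ignored when deciding sharing —
    otherwise every annotated pair would trivially be p-p. Pairs where
    neither gene carries any informative annotation are the n-n
    analogue of the term-specific partition and are excluded entirely;
    with a single-term corpus this makes the global partition coincide
    with that term's partition.
    """
    genes = list(genes)
    n = len(genes)
    term_counts: dict[str, int] = {}
    for g in genes:
        for t in gene_terms.get(g, ()):  # noqa: B909
            term_counts[t] = term_counts.get(t, 0) + 1
    # a term annotated to every gene (the root after propagation, when all
    # genes are annotated) carries no information and cannot define sharing
    informative = {t for t, c in term_counts.items() if c < n}
    terms = sorted(informative)
    t_index = {t: i for i, t in enumerate(terms)}
    B = np.zeros((n, len(terms)), dtype=bool)
    for i, g in enumerate(genes):
        for t in gene_terms.get(g, ()):
            j = t_index.get(t)
            if j is not None:
                B[i, j] = True
    share = (B.astype(np.int32) @ B.astype(np.int32).T) > 0
    has_informative = B.any(axis=1)
    iu, ju = np.triu_indices(n, k=1)
    shared = share[iu, ju]
    either = has_informative[iu] | has_informative[ju]
    pp = np.column_stack([iu[shared], ju[shared]])
    pn = np.column_stack([iu[~shared & either], ju[~shared & either]])
    return GlobalPairs(pp_pairs=pp, pn_pairs=pn)


class PairMoments:
    """Exact sufficient statistics for the pair means/variances of S_w.

    With p_m = sum_{i in P} x_im, q_m = sum_{i in Q} x_im,
    G^P = X_P' X_P, G^Q = X_Q' X_Q and H = (X_P^2)' (X_P^2):

        sum over p-p pairs of S_w        = w' U,   U = (p^2 - diag G^P) / 2
        sum over p-n pairs of S_w        = w' V,   V = p * q
        sum over p-p pairs of S_w^2      = w' M_pp w,  M_pp = ((G^P)^2 - H) / 2
        sum over p-n pairs of S_w^2      = w' M_pn w,  M_pn = G^P * G^Q

    (elementwise squares/products). Means and unbiased variances follow
    directly, as do their analytic gradients in w.
    """

    def __init__(self, X: ScaledExpression | np.ndarray, part: PairPartition):
        V = X.values if isinstance(X, ScaledExpression) else np.asarray(X, dtype=float)
        P = part.positives
        Q = part.negatives
        XP = V[P]
        XQ = V[Q]
        p = XP.sum(axis=0)
        q = XQ.sum(axis=0)
        GP = XP.T @ XP
        GQ = XQ.T @ XQ
        H = (XP**2).T @ (XP**2)
        self.U = (p**2 - np.diag(GP)) / 2.0
        self.V = p * q
        self.M_pp = (GP**2 - H) / 2.0
        self.M_pn = GP * GQ
        self.n_pp = part.n_pp
        self.n_pn = part.n_pn
        self.n_samples = V.shape[1]

    def stats(self, w: np.ndarray, with_grad: bool = False):
        if self.n_pp < 2 or self.n_pn < 2:
            raise ValueError("pair variances need at least 2 pairs per group")
        w = np.asarray(w, dtype=float)
        mpp_w = self.M_pp @ w
        mpn_w = self.M_pn @ w
        mu_pp = (w @ self.U) / self.n_pp
        mu_pn = (w @ self.V) / self.n_pn
        var_pp = (w @ mpp_w - self.n_pp * mu_pp**2) / (self.n_pp - 1)
        var_pn = (w @ mpn_w - self.n_pn * mu_pn**2) / (self.n_pn - 1)
        if not with_grad:
            return mu_pp, mu_pn, var_pp, var_pn, None
        d_mu_pp = self.U / self.n_pp
        d_mu_pn = self.V / self.n_pn
        d_var_pp = 2.0 * (mpp_w - mu_pp * self.U) / (self.n_pp - 1)
        d_var_pn = 2.0 * (mpn_w - mu_pn * self.V) / (self.n_pn - 1)
        return mu_pp, mu_pn, var_pp, var_pn, (d_mu_pp, d_mu_pn, d_var_pp, d_var_pn)


class SampledPairMoments:
    """Pair statistics from explicit (possibly subsampled) pairs.

    Stores Z matrices whose rows are the elementwise products
    x~_i * x~_j of each kept pair, so S_w over the kept pairs is Z @ w.
    Serves both the memory-capped fallback of the term-specific fit and
    the global variant, whose p-p set has no product structure.
    """

    def __init__(
        self,
        X: ScaledExpression | np.ndarray,
        pp_pairs: np.ndarray,
        pn_pairs: np.ndarray,
        max_pairs: int = DEFAULT_MAX_SAMPLED_PAIRS,
        rng: np.random.Generator | None = None,
    ):
        V = X.values if isinstance(X, ScaledExpression) else np.asarray(X, dtype=float)
        rng = rng if rng is not None else np.random.default_rng(0)
        pp_pairs = np.asarray(pp_pairs, dtype=int)
        pn_pairs = np.asarray(pn_pairs, dtype=int)
        self.n_pp = pp_pairs.shape[0]
        self.n_pn = pn_pairs.shape[0]
        if self.n_pp < 2:
            raise ValueError("p-p variance needs at least 2 p-p pairs")
        if self.n_pn < 2:
            raise ValueError("p-n variance needs at least 2 p-n pairs")
        pp_kept = self._subsample(pp_pairs, max_pairs, rng)
        pn_kept = self._subsample(pn_pairs, max_pairs, rng)
        self.pp_kept = pp_kept
        self.pn_kept = pn_kept
        self.Z_pp = V[pp_kept[:, 0]] * V[pp_kept[:, 1]]
        self.Z_pn = V[pn_kept[:, 0]] * V[pn_kept[:, 1]]
        self.n_samples = V.shape[1]

    @staticmethod
    def _subsample(pairs: np.ndarray, max_pairs: int, rng: np.random.Generator) -> np.ndarray:
        if pairs.shape[0] <= max_pairs:
            return pairs
        keep = rng.choice(pairs.shape[0], size=max_pairs, replace=False)
        return pairs[np.sort(keep)]

    def stats(self, w: np.ndarray, with_grad: bool = False):
        w = np.asarray(w, dtype=float)
        s_pp = self.Z_pp @ w
        s_pn = self.Z_pn @ w
        k_pp = s_pp.size
        k_pn = s_pn.size
        mu_pp = s_pp.mean()
        mu_pn = s_pn.mean()
        var_pp = s_pp.var(ddof=1)
        var_pn = s_pn.var(ddof=1)
        if not with_grad:
            return mu_pp, mu_pn, var_pp, var_pn, None
        d_mu_pp = self.Z_pp.mean(axis=0)
        d_mu_pn = self.Z_pn.mean(axis=0)
        d_var_pp = 2.0 * (self.Z_pp.T @ s_pp - k_pp * mu_pp * d_mu_pp) / (k_pp - 1)
        d_var_pn = 2.0 * (self.Z_pn.T @ s_pn - k_pn * mu_pn * d_mu_pn) / (k_pn - 1)
        return mu_pp, mu_pn, var_pp, var_pn, (d_mu_pp, d_mu_pn, d_var_pp, d_var_pn)


def build_pair_moments(
    X: ScaledExpression | np.ndarray,
    part: PairPartition,
    memory_cap_bytes: int = DEFAULT_MOMENT_MEMORY_CAP_BYTES,
    max_sampled_pairs: int = DEFAULT_MAX_SAMPLED_PAIRS,
    rng: np.random.Generator | None = None,
) -> PairMoments | SampledPairMoments:
    """Exact f x f moment matrices when they fit the memory cap, else
    seeded uniform pair subsampling."""
    V = X.values if isinstance(X, ScaledExpression) else np.asarray(X, dtype=float)
    f = V.shape[1]
    if 4 * f * f * 8 <= memory_cap_bytes:
        return PairMoments(X, part)
    P = part.positives
    Q = part.negatives
    iu, ju = np.triu_indices(P.size, k=1)
    pp = np.column_stack([P[iu], P[ju]])
    gp, gq = np.meshgrid(P, Q, indexing="ij")
    pn = np.column_stack([gp.ravel(), gq.ravel()])
    return SampledPairMoments(X, pp, pn, max_pairs=max_sampled_pairs, rng=rng)


def _welch_from_stats(mu_pp, mu_pn, var_pp, var_pn, n_pp, n_pn, grads=None):
    var_pp = max(var_pp, 0.0)
    var_pn = max(var_pn, 0.0)
    diff = mu_pp - mu_pn
    s = var_pp / n_pp + var_pn / n_pn
    # t is invariant to rescaling w, so tiny variances paired with a tiny
    # mean difference are legitimate (the optimizer may shrink ||w||);
    # only an exactly degenerate denominator is special-cased
    if s <= VARIANCE_FLOOR * max(diff * diff, 1.0) and abs(diff) <= 1e-12:
        if grads is None:
            return 0.0, None
        return 0.0, np.zeros_like(grads[0])
    if s <= 0.0:
        raise ValueError("zero pair variances with unequal means: t undefined")
    t = diff / np.sqrt(s)
    if grads is None:
        return t, None
    d_mu_pp, d_mu_pn, d_var_pp, d_var_pn = grads
    ds = d_var_pp / n_pp + d_var_pn / n_pn
    dt = (d_mu_pp - d_mu_pn) / np.sqrt(s) - diff * ds / (2.0 * s**1.5)
    return t, dt


def welch_t(
    w: WeightVector | np.ndarray,
    moments: PairMoments | SampledPairMoments,
) -> float:
    """Welch separability t(w) between p-p and p-n weighted similarities.

    Scale-invariant: t(c w) = t(w) for any c > 0.
    """
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if np.any(wv < 0):
        raise ValueError("weights must be non-negative")
    mu_pp, mu_pn, var_pp, var_pn, _ = moments.stats(wv)
    t, _ = _welch_from_stats(mu_pp, mu_pn, var_pp, var_pn, moments.n_pp, moments.n_pn)
    return float(t)


def _objective_and_grad(w, moments, alpha):
    mu_pp, mu_pn, var_pp, var_pn, grads = moments.stats(w, with_grad=True)
    t, dt = _welch_from_stats(
        mu_pp, mu_pn, var_pp, var_pn, moments.n_pp, moments.n_pn, grads
    )
    obj = -alpha * t + (1.0 - alpha) * np.sum(w)
    grad = -alpha * dt + (1.0 - alpha)
    return obj, grad


def objective(
    w: WeightVector | np.ndarray,
    moments: PairMoments | SampledPairMoments,
    alpha: float,
) -> float:
    """-alpha t(w) + (1 - alpha) sum(w), the quantity minimized in fitting."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    obj, _ = _objective_and_grad(wv, moments, alpha)
    return float(obj)


def objective_grad(
    w: WeightVector | np.ndarray,
    moments: PairMoments | SampledPairMoments,
    alpha: float,
) -> np.ndarray:
    """Analytic gradient of the objective (matches central differences)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    _, grad = _objective_and_grad(wv, moments, alpha)
    return np.asarray(grad)


@dataclass
class MLCModel:
    """A fitted per-term (or global) weighted-inner-product metric."""

    term: str
    weights: WeightVector
    alpha: float
    objective_value: float
    converged: bool
    n_selected: int
    n_iter: int
    welch_t: float
    #: objective at the start and at every accepted iterate
    trace: tuple[float, ...] = ()

    def selected(self, eps: float = SELECTION_EPS) -> np.ndarray:
        return self.weights.selected(eps)


def _minimize_weights(moments, alpha, term, max_iter=500):
    f = moments.n_samples
    w0 = np.ones(f)

    def fun(w):
        return _objective_and_grad(w, moments, alpha)

    trace = [float(fun(w0)[0])]

    def record(wk):
        trace.append(float(_objective_and_grad(wk, moments, alpha)[0]))

    res = minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * f,
        options={"maxiter": max_iter},
        callback=record,
    )
    w = np.maximum(res.x, 0.0)
    weights = WeightVector(w=w, term=term)
    try:
        t_final = welch_t(weights, moments)
    except ValueError:
        t_final = 0.0
    return MLCModel(
        term=term,
        weights=weights,
        alpha=alpha,
        objective_value=float(res.fun),
        converged=bool(res.success),
        n_selected=weights.n_selected,
        n_iter=int(res.nit),
        welch_t=float(t_final),
        trace=tuple(trace),
    )


def fit_mlc(
    X: ScaledExpression | np.ndarray,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    term: str = "term",
    max_iter: int = 500,
    moments: PairMoments | SampledPairMoments | None = None,
    memory_cap_bytes: int = DEFAULT_MOMENT_MEMORY_CAP_BYTES,
) -> MLCModel:
    """Fit term-specific sample weights by bound-constrained L-BFGS.

    Deterministic: the optimizer starts from all-ones weights (the
    unweighted inner product, i.e. plain PCC behavior) and uses no
    randomness. Precomputed ``moments`` may be passed to share the
    expensive accumulation across several alpha values.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if moments is None:
        part = partition_pairs(y)
        moments = build_pair_moments(X, part, memory_cap_bytes=memory_cap_bytes)
    return _minimize_weights(moments, alpha, term, max_iter=max_iter)


def fit_mlc_global(
    X: ScaledExpression | np.ndarray,
    gene_terms: dict[str, set[str]],
    genes: tuple[str, ...] | list[str],
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = 500,
    max_sampled_pairs: int = DEFAULT_MAX_SAMPLED_PAIRS,
    rng: np.random.Generator | None = None,
) -> MLCModel:
    """Fit one weight vector for all terms at once: p-p pairs share at
    least one informative term, p-n pairs share none."""
    pairs = partition_pairs_global(gene_terms, genes)
    moments = SampledPairMoments(
        X, pairs.pp_pairs, pairs.pn_pairs, max_pairs=max_sampled_pairs, rng=rng
    )
    return _minimize_weights(moments, alpha, "global", max_iter=max_iter)


def selected_samples(model: MLCModel, eps: float = SELECTION_EPS) -> np.ndarray:
    """Indices of samples the model kept (weight above eps * max weight)."""
    return model.weights.selected(eps)
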