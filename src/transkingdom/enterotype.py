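"""Dirichlet-multinomial mixture (DMM) enterotyping.

The community-typing model: each sample's genus counts x_i are multinomial
with a composition drawn from one of K Dirichlet components,

    P(x_i) = sum_k pi_k * DM(x_i | alpha_k),

where DM is the Dirichlet-multinomial (multivariate Polya) density.  Fitting
is EM: responsibilities in the E-step, mixture weights by responsibility
means and each alpha_k by a responsibility-weighted Minka fixed-point update
in the M-step.  Model selection across K uses BIC, AIC and a Laplace
approximation to the negative log evidence (diagonal-curvature variant).

Usage follows the statsmodels convention::

    model = DirichletMultinomialMixture(counts, k=2)
    res = model.fit(seed=0)
    res.summary()
    labels = res.assign()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, polygamma, psi
from sklearn.cluster import KMeans

from .tables import CountTable, clr_transform


class EnterotypeError(ValueError):
    pass


def dm_loglik(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log Dirichlet-multinomial likelihood of one count row.

    log DM(x | alpha) = log G(A) - log G(N + A)
                        + sum_j [log G(x_j + a_j) - log G(a_j)],
    with A = sum(alpha), N = sum(x); the multinomial coefficient is omitted,
    matching the exchangeable-sequence (Polya urn) convention.
    """
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise EnterotypeError("alpha must be strictly positive")
    x = np.asarray(x, dtype=float)
    A = alpha.sum()
    N = x.sum()
    return float(gammaln(A) - gammaln(N + A)
                 + np.sum(gammaln(x + alpha) - gammaln(alpha)))


def _dm_loglik_matrix(X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """n x K matrix of per-component DM log-likelihoods."""
    n = X.shape[0]
    K = alphas.shape[0]
    N = X.sum(axis=1)
    out = np.empty((n, K))
    for k in range(K):
        a = alphas[k]
        A = a.sum()
        out[:, k] = (gammaln(A) - gammaln(N + A)
                     + np.sum(gammaln(X + a) - gammaln(a), axis=1))
    return out


def _minka_update(X: np.ndarray, weights: np.ndarray, alpha: np.ndarray,
                  inner_iter: int = 5) -> np.ndarray:
    """Responsibility-weighted fixed-point update of one alpha vector."""
    N = X.sum(axis=1)
    w = weights
    wsum = w.sum()
    for _ in range(inner_iter):
        A = alpha.sum()
        num = (w[:, None] * (psi(X + alpha) - psi(alpha))).sum(axis=0)
        den = (w * (psi(N + A) - psi(A))).sum()
        if den <= 0:
            break
        alpha = np.clip(alpha * num / den, 1e-8, 1e6)
    return alpha


@dataclass
class DMMResults:
    """Fitted Dirichlet-multinomial mixture."""

    k: int
    alphas: np.ndarray                 # K x G
    weights: np.ndarray                # K
    responsibilities: pd.DataFrame     # n x K
    loglik: float
    n_parameters: int
    scores: dict                       # {"BIC", "AIC", "Laplace"}
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    restart_index: int
    seed: int | None
    genus_ids: list = field(default_factory=list)
    tie_log: list = field(default_factory=list)

    def assign(self) -> pd.Series:
        """Hard labels by maximum responsibility; ties -> lowest component,
        recorded in ``tie_log``."""
        R = self.responsibilities.to_numpy()
        labels = R.argmax(axis=1)
        maxv = R.max(axis=1)
        for i in range(R.shape[0]):
            if (np.isclose(R[i], maxv[i])).sum() > 1:
                self.tie_log.append(self.responsibilities.index[i])
        return pd.Series(labels, index=self.responsibilities.index,
                         name="enterotype")

    def mean_profiles(self) -> np.ndarray:
        """Component mean compositions alpha_k / sum(alpha_k)."""
        return self.alphas / self.alphas.sum(axis=1, keepdims=True)

    def summary(self) -> str:
        lines = [
            f"Dirichlet-multinomial mixture, K={self.k}",
            f"  samples: {self.responsibilities.shape[0]}, "
            f"genera: {self.alphas.shape[1]}",
            f"  loglik: {self.loglik:.3f}  converged: {self.converged} "
            f"({self.n_iter} iterations, restart {self.restart_index})",
            f"  weights: {np.round(self.weights, 4).tolist()}",
            "  scores: " + ", ".join(f"{k}={v:.2f}"
                                     for k, v in sorted(self.scores.items())),
        ]
        return "\n".join(lines)


class DirichletMultinomialMixture:
    """DMM model over a genus-level count table.

    Parameters
    ----------
    counts : CountTable or DataFrame
        Samples x genera integer counts (typically rarefied).
    k : int
        Number of mixture components.
    """

    def __init__(self, counts: CountTable | pd.DataFrame, k: int):
        df = counts.data if isinstance(counts, CountTable) else counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise EnterotypeError("empty count table")
        if k < 1:
            raise EnterotypeError("k must be >= 1")
        self.counts = df
        self.k = int(k)
        self.X = df.to_numpy(dtype=float)

    # -- internals -------------------------------------------------------
    def _init_responsibilities(self, rng: np.random.Generator,
                               jitter: float) -> np.ndarray:
        n = self.X.shape[0]
        if self.k == 1:
            return np.ones((n, 1))
        if n < self.k:  # fewer samples than components: random soft start
            R = rng.dirichlet(np.ones(self.k), size=n)
            return R
        clr = clr_transform(pd.DataFrame(self.X)).to_numpy()
        km = KMeans(n_clusters=self.k, n_init=3,
                    random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(clr)
        R = np.full((n, self.k), 0.05 / max(self.k - 1, 1))
        R[np.arange(n), labels] = 0.95
        if jitter > 0:
            R = R + rng.uniform(0, jitter, size=R.shape)
        return R / R.sum(axis=1, keepdims=True)

    def _em(self, R: np.ndarray, max_iter: int, tol: float):
        X = self.X
        n, G = X.shape
        K = self.k
        alphas = np.empty((K, G))
        # moment-matched start from soft assignments
        for k in range(K):
            w = R[:, k]
            prof = (w[:, None] * (X + 0.5)).sum(axis=0)
            prof /= prof.sum()
            alphas[k] = np.clip(prof * 50.0, 1e-6, None)
        weights = R.mean(axis=0)
        trace = []
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step
            log_comp = _dm_loglik_matrix(X, alphas)
            log_r = np.log(np.maximum(weights, 1e-300)) + log_comp
            ll = float(logsumexp(log_r, axis=1).sum())
            trace.append(ll)
            R = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
            # M-step
            weights = np.maximum(R.mean(axis=0), 1e-12)
            weights /= weights.sum()
            for k in range(K):
                alphas[k] = _minka_update(X, R[:, k], alphas[k])
            if ll - ll_prev < tol * max(1.0, abs(ll)) and it > 5:
                converged = True
                break
            ll_prev = ll
        log_comp = _dm_loglik_matrix(X, alphas)
        log_r = np.log(np.maximum(weights, 1e-300)) + log_comp
        ll = float(logsumexp(log_r, axis=1).sum())
        trace.append(ll)
        R = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
        return alphas, weights, R, ll, np.array(trace), converged, it

    def _laplace(self, alphas: np.ndarray, R: np.ndarray,
                 loglik: float) -> float:
        """Diagonal-curvature Laplace approximation to -log evidence.

        -log p(X) ~= -ll + d/2 log(2 pi) ... sign convention: smaller is
        better, comparable across K (Holmes-style approximation with the
        Hessian replaced by its diagonal).
        """
        X = self.X
        N = X.sum(axis=1)
        d = self.k * X.shape[1] + (self.k - 1)
        log_det = 0.0
        for k in range(self.k):
            a = alphas[k]
            A = a.sum()
            w = R[:, k]
            # second derivative of the weighted DM loglik wrt alpha_j
            curv = (w[:, None] * (polygamma(1, X + a) - polygamma(1, a))).sum(axis=0) \
                + (w * (polygamma(1, A) - polygamma(1, N + A))).sum()
            neg_curv = np.maximum(-curv, 1e-10)
            log_det += float(np.log(neg_curv).sum())
        return -loglik - 0.5 * d * np.log(2 * np.pi) + 0.5 * log_det

    # -- public API ------------------------------------------------------
    def fit(self, max_iter: int = 250, tol: float = 1e-7,
            n_restarts: int = 3, seed: int | None = 0) -> DMMResults:
        """Run EM from ``n_restarts`` initialisations, keep the best loglik."""
        rng = np.random.default_rng(seed)
        best = None
        for r in range(max(1, n_restarts)):
            R0 = self._init_responsibilities(rng, jitter=0.0 if r == 0 else 0.3)
            alphas, weights, R, ll, trace, conv, it = self._em(
                R0, max_iter, tol)
            if best is None or ll > best[3]:
                best = (alphas, weights, R, ll, trace, conv, it, r)
        alphas, weights, R, ll, trace, conv, it, r = best
        n, G = self.X.shape
        d = self.k * G + (self.k - 1)
        scores = {
            "BIC": -2 * ll + d * np.log(n),
            "AIC": -2 * ll + 2 * d,
            "Laplace": self._laplace(alphas, R, ll),
        }
        resp = pd.DataFrame(R, index=self.counts.index,
                            columns=[f"component_{k}" for k in range(self.k)])
        return DMMResults(
            k=self.k, alphas=alphas, weights=weights, responsibilities=resp,
            loglik=ll, n_parameters=d, scores=scores, converged=conv,
            n_iter=it, loglik_trace=trace, restart_index=r, seed=seed,
            genus_ids=list(self.counts.columns))


def select_k(counts: CountTable | pd.DataFrame, k_range=range(1, 4),
             criteria=("BIC", "AIC", "Laplace"), seed: int | None = 0,
             **fit_kwargs):
    """Fit every K in ``k_range`` and report the argmin per criterion.

    Returns ``(best, fits, score_table)`` where ``best`` maps criterion name
    to the selected K.
    """
    k_range = list(k_range)
    if not k_range:
        raise EnterotypeError("k_range must be non-empty")
    fits = {}
    for k in k_range:
        fits[k] = DirichletMultinomialMixture(counts, k).fit(
            seed=seed, **fit_kwargs)
    rows = [{"K": k, **{c: fits[k].scores[c] for c in criteria}}
            for k in k_range]
    table = pd.DataFrame(rows).set_index("K")
    best = {c: int(table[c].idxmin()) for c in criteria}
    return best, fits, table


def assign_enterotypes(fit: DMMResults) -> pd.Series:
    """Hard per-sample enterotype labels (argmax responsibility)."""
    return fit.assign()


def genus_contributions(fit_k: DMMResults, fit_1: DMMResults,
                        space: str = "clr") -> pd.Series:
    """Per-genus contribution to the multi-component split.

    For each genus the score is the sum over components of the absolute
    difference between the K-component mean profile and the single-component
    mean profile, computed either on CLR-transformed mean compositions
    (default, matching how the discriminating genera are usually displayed)
    or on raw proportions.
    """
    if fit_k.genus_ids != fit_1.genus_ids:
        raise EnterotypeError("fits cover different genus sets")
    if fit_1.k != 1:
        raise EnterotypeError("fit_1 must be a single-component fit")
    mk = fit_k.mean_profiles()
    m1 = fit_1.mean_profiles()[0]
    if space == "clr":
        def t(v):
            logv = np.log(v)
            return logv - logv.mean()
    elif space == "proportion":
        def t(v):
            return v
    else:
        raise EnterotypeError(f"unknown space {space!r}")
    t1 = t(m1)
    score = np.zeros(mk.shape[1])
    for k in range(fit_k.k):
        score += np.abs(t(mk[k]) - t1)
    return pd.Series(score, index=fit_k.genus_ids,
                     name="contribution").sort_values(ascending=False)
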