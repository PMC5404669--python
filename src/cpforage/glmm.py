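"""Mixed-model engine: random-intercept GLMMs and penalized-spline smooths.

Model: y ~ family(g^-1(X beta + sum_g Z_g b_g)), with independent gaussian
random-effect blocks b_g ~ N(0, sigma_g^2 I).  Blocks are either factor
intercepts (individual, year, colony) or the "wiggly" part of a penalized
regression spline, re-parameterized so that the smoothing parameter is a
variance component and REML selects the effective degrees of freedom.

Estimation:
 * gaussian/identity — exact marginal likelihood, profiled over beta and the
   residual variance; ML for likelihood-ratio comparisons, REML for reported
   coefficients and smooths.
 * poisson/log and binomial/logit — Laplace approximation to the marginal
   likelihood with joint penalized-IRLS for (beta, b), the approach of lme4's
   default glmer fit.  statsmodels offers no maximum-likelihood GLMM for
   these families, hence this implementation.

The outer optimization over log standard deviations uses Nelder-Mead, which
is derivative-free, deterministic, and robust to variance components
collapsing to the boundary (log sigma -> -inf is approached smoothly).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

class Family:
    name = "base"

    def loglik(self, y, mu):  # pragma: no cover - abstract
        raise NotImplementedError

    def mu(self, eta):
        raise NotImplementedError

    def weights(self, mu):
        """IRLS weights for the canonical link (= Var(mu))."""
        raise NotImplementedError


class Gaussian(Family):
    name = "gaussian"


class Poisson(Family):
    name = "poisson"

    def loglik(self, y, mu):
        from scipy.special import gammaln

        mu = np.clip(mu, 1e-10, None)
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))

    def mu(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def weights(self, mu):
        return mu


class Binomial(Family):
    name = "binomial"

    def loglik(self, y, mu):
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    def mu(self, eta):
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

    def weights(self, mu):
        return mu * (1.0 - mu)


FAMILIES = {"gaussian": Gaussian, "poisson": Poisson, "binomial": Binomial}


# ---------------------------------------------------------------------------
# random-effect blocks
# ---------------------------------------------------------------------------

@dataclass
class RandomBlock:
    """One iid random-effect block: ``Z`` (n x q_g) with variance sigma_g^2."""

    name: str
    Z: np.ndarray
    kind: str = "intercept"  # or "smooth"

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def factor_block(name: str, labels) -> RandomBlock:
    """Random-intercept block from a categorical label vector."""
    labels = np.asarray(labels)
    levels, idx = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return RandomBlock(name=name, Z=Z)


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class MixedFit:
    """Fitted mixed model: estimates, covariance, likelihood, bookkeeping."""

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    names: list[str]
    vc: dict  # block name -> random-effect sd
    sigma_resid: float | None  # gaussian only
    loglik: float
    method: str  # "ML", "REML" or "Laplace"
    family: str
    n: int
    k_params: int  # fixed + variance parameters (AIC bookkeeping)
    converged: bool
    edf: dict = field(default_factory=dict)  # block name -> effective df
    blups: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    def coef_table(self):
        import pandas as pd

        z = self.beta / self.se
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            },
            index=self.names,
        )


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# gaussian: exact profiled ML / REML
# ---------------------------------------------------------------------------

def _gaussian_profile(log_gamma, X, y, blocks, reml):
    """Profiled negative log-likelihood over variance *ratios* gamma_g =
    sigma_g^2 / sigma^2; beta and sigma^2 are profiled out exactly."""
    n, p = X.shape
    gam = np.exp(2.0 * np.asarray(log_gamma))  # gamma_g, one per block
    A_cols = [b.Z * np.sqrt(g) for b, g in zip(blocks, gam)]
    A = np.concatenate(A_cols, axis=1) if A_cols else np.zeros((n, 0))
    q = A.shape[1]
    if q:
        M = np.eye(q) + A.T @ A
        cF, low = _chol(M)
        logdet_v0 = 2.0 * np.sum(np.log(np.diag(cF)))

        def vinv(u):  # V0^{-1} u via Woodbury
            return u - A @ _chol_solve(cF, A.T @ u)
    else:
        logdet_v0 = 0.0

        def vinv(u):
            return u

    XtVX = X.T @ vinv(X)
    XtVy = X.T @ vinv(y)
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    quad = float(r @ vinv(r))
    if reml:
        dof = n - p
        sigma2 = quad / dof
        sign, logdet_x = np.linalg.slogdet(XtVX)
        nll = 0.5 * (dof * (np.log(sigma2) + _LOG2PI) + logdet_v0 + logdet_x + dof)
    else:
        dof = n
        sigma2 = quad / n
        nll = 0.5 * (n * (np.log(sigma2) + _LOG2PI) + logdet_v0 + n)
    return nll, beta, sigma2, XtVX, vinv, logdet_v0


def _chol(M):
    from scipy.linalg import cho_factor

    return cho_factor(M, lower=True)


def _chol_solve(cF, u):
    from scipy.linalg import cho_solve

    return cho_solve((cF, True) if not isinstance(cF, tuple) else cF, u)


def _fit_gaussian(X, y, blocks, names, method):
    n, p = X.shape
    reml = method == "REML"
    G = len(blocks)

    def obj(lg):
        try:
            return _gaussian_profile(lg, X, y, blocks, reml)[0]
        except np.linalg.LinAlgError:
            return 1e12

    x0 = np.zeros(G)
    if G:
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
        )
        lg = res.x
        converged = bool(res.success)
    else:
        lg = x0
        converged = True
    nll, beta, sigma2, XtVX, vinv, _ = _gaussian_profile(lg, X, y, blocks, reml)
    cov_beta = np.linalg.inv(XtVX) * sigma2
    # wait: XtVX is X' V0^{-1} X, and V = sigma2 V0 => cov = sigma2 (X'V0^{-1}X)^{-1}
    gam = np.exp(2.0 * lg)
    vc = {b.name: float(np.sqrt(g * sigma2)) for b, g in zip(blocks, gam)}

    # BLUPs and effective df per block
    r = y - X @ beta
    blups, edf = {}, {}
    if G:
        Zall = np.concatenate([b.Z for b in blocks], axis=1)
        gvec = np.concatenate([np.full(b.q, g) for b, g in zip(blocks, gam)])
        # b_hat = Gam Z' V0^{-1} r
        bhat = gvec * (Zall.T @ vinv(r))
        # ridge edf: trace over block columns of (C'C + P)^{-1} C'C
        C = np.concatenate([X, Zall], axis=1)
        P = np.zeros(C.shape[1])
        P[p:] = 1.0 / np.maximum(gvec, 1e-12)
        H = C.T @ C + np.diag(P)
        T = np.linalg.solve(H, C.T @ C)
        off = p
        for b in blocks:
            blups[b.name] = bhat[off - p : off - p + b.q]
            edf[b.name] = float(np.trace(T[off : off + b.q, off : off + b.q]))
            off += b.q
    return MixedFit(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        cov_beta=cov_beta,
        names=list(names),
        vc=vc,
        sigma_resid=float(np.sqrt(sigma2)),
        loglik=-nll,
        method=method,
        family="gaussian",
        n=n,
        k_params=p + G + 1,
        converged=converged,
        edf=edf,
        blups=blups,
    )


# ---------------------------------------------------------------------------
# poisson / binomial: Laplace approximation
# ---------------------------------------------------------------------------

def _pirls(X, y, Zall, pen_diag, fam, beta0, b0, max_iter=100, tol=1e-9):
    """Joint penalized IRLS for (beta, b) at fixed variance parameters."""
    n, p = X.shape
    q = Zall.shape[1]
    C = np.concatenate([X, Zall], axis=1)
    theta = np.concatenate([beta0, b0])
    P = np.concatenate([np.zeros(p), pen_diag])

    def penalized_ll(th):
        eta = C @ th
        mu = fam.mu(eta)
        return fam.loglik(y, mu) - 0.5 * float(np.sum(P * th * th))

    cur = penalized_ll(theta)
    for _ in range(max_iter):
        eta = C @ theta
        mu = fam.mu(eta)
        w = np.maximum(fam.weights(mu), 1e-10)
        grad = C.T @ (y - mu) - P * theta
        H = (C.T * w) @ C + np.diag(P)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            new = penalized_ll(cand)
            if new >= cur - 1e-12:
                break
            t *= 0.5
        theta = theta + t * step
        if new - cur < tol and np.max(np.abs(t * step)) < 1e-8:
            cur = new
            break
        cur = new
    return theta, cur


def _laplace_nll(log_sigma, X, y, blocks, fam, state):
    n, p = X.shape
    sig = np.exp(np.asarray(log_sigma))
    Zall = np.concatenate([b.Z for b in blocks], axis=1)
    svec = np.concatenate([np.full(b.q, s) for b, s in zip(blocks, sig)])
    pen = 1.0 / np.maximum(svec ** 2, 1e-12)
    beta0 = state.get("beta", np.zeros(p))
    b0 = state.get("b", np.zeros(Zall.shape[1]))
    theta, _h = _pirls(X, y, Zall, pen, fam, beta0, b0)
    beta, b = theta[:p], theta[p:]
    eta = X @ beta + Zall @ b
    mu = fam.mu(eta)
    w = np.maximum(fam.weights(mu), 1e-10)
    h = fam.loglik(y, mu) - 0.5 * float(np.sum(pen * b * b))
    # log det(I + S^(1/2) Z'WZ S^(1/2))
    ZtWZ = (Zall.T * w) @ Zall
    Mq = np.eye(len(b)) + (ZtWZ * svec[None, :]) * svec[:, None]
    sign, logdet = np.linalg.slogdet(Mq)
    ll = h - 0.5 * logdet
    state["beta"], state["b"] = beta, b
    state["last"] = (beta, b, w, Zall, pen, svec)
    return -ll


def _fit_laplace(X, y, blocks, names, family):
    fam = FAMILIES[family]()
    n, p = X.shape
    G = len(blocks)
    state: dict = {}
    x0 = np.full(G, np.log(0.5))
    res = optimize.minimize(
        _laplace_nll,
        x0,
        args=(X, y, blocks, fam, state),
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 3000},
    )
    nll = _laplace_nll(res.x, X, y, blocks, fam, state)
    beta, b, w, Zall, pen, svec = state["last"]
    # cov(beta): top-left block of inverse penalized Hessian
    C = np.concatenate([X, Zall], axis=1)
    P = np.concatenate([np.zeros(p), pen])
    H = (C.T * w) @ C + np.diag(P)
    Hinv = np.linalg.inv(H)
    cov_beta = Hinv[:p, :p]
    sig = np.exp(res.x)
    vc = {blk.name: float(s) for blk, s in zip(blocks, sig)}
    edf, blups = {}, {}
    T = np.linalg.solve(H, (C.T * w) @ C)
    off = p
    poff = 0
    for blk in blocks:
        blups[blk.name] = b[poff : poff + blk.q]
        edf[blk.name] = float(np.trace(T[off : off + blk.q, off : off + blk.q]))
        off += blk.q
        poff += blk.q
    return MixedFit(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        cov_beta=cov_beta,
        names=list(names),
        vc=vc,
        sigma_resid=None,
        loglik=-float(nll),
        method="Laplace",
        family=family,
        n=n,
        k_params=p + G,
        converged=bool(res.success),
        edf=edf,
        blups=blups,
    )


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def fit_mixed_model(
    X: np.ndarray,
    y: np.ndarray,
    blocks: list[RandomBlock],
    names: list[str] | None = None,
    family: str = "gaussian",
    method: str = "ML",
) -> MixedFit:
    """Fit a GLMM with independent random-intercept / smooth blocks.

    ``method`` ("ML" or "REML") applies to the gaussian family; poisson and
    binomial responses always use the Laplace-approximated ML fit.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be n x p and y length n")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    # drop degenerate blocks (fewer than 2 columns cannot identify a variance)
    kept = []
    for b in blocks:
        if b.q >= 2:
            kept.append(b)
        else:
            import warnings

            warnings.warn(f"random factor {b.name!r} has <2 levels; dropped")
    if family == "gaussian":
        return _fit_gaussian(X, y, kept, names, method)
    if kept:
        return _fit_laplace(X, y, kept, names, family)
    # fixed-effects-only GLM fallback via the same IRLS machinery
    fam = FAMILIES[family]()
    theta, _ = _pirls(X, y, np.zeros((len(y), 0)), np.zeros(0), fam,
                      np.zeros(X.shape[1]), np.zeros(0))
    eta = X @ theta
    mu = fam.mu(eta)
    w = np.maximum(fam.weights(mu), 1e-10)
    H = (X.T * w) @ X
    cov = np.linalg.inv(H)
    return MixedFit(
        beta=theta,
        se=np.sqrt(np.diag(cov)),
        cov_beta=cov,
        names=list(names),
        vc={},
        sigma_resid=None,
        loglik=fam.loglik(y, mu),
        method="ML",
        family=family,
        n=len(y),
        k_params=X.shape[1],
        converged=True,
    )


# ---------------------------------------------------------------------------
# penalized spline smooth (random-effect reparameterization)
# ---------------------------------------------------------------------------

@dataclass
class SmoothBasis:
    """Cubic B-spline basis split into a fixed linear part and a penalized
    "wiggly" random-effect part (second-difference penalty)."""

    x_min: float
    x_max: float
    knots: np.ndarray
    U_pos: np.ndarray  # k x (k-2), penalty range space
    scale: np.ndarray  # 1/sqrt(eigenvalues)
    x_mean: float
    x_sd: float

    def design(self, x):
        """Return (linear_column, Z_wiggly) evaluated at x."""
        B = _bspline_design(np.asarray(x, float), self.knots)
        lin = (np.asarray(x, float) - self.x_mean) / self.x_sd
        Z = B @ (self.U_pos * self.scale[None, :])
        return lin, Z


def _bspline_design(x, knots, degree=3):
    from scipy.interpolate import BSpline

    n_basis = len(knots) - degree - 1
    out = np.empty((len(x), n_basis))
    xc = np.clip(x, knots[degree], knots[-degree - 1])
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        out[:, i] = BSpline(knots, c, degree)(xc)
    return out


def make_smooth_basis(x, k: int = 10) -> SmoothBasis:
    """Build a k-basis cubic B-spline smooth over the range of x.

    Equally spaced interior knots; the second-order difference penalty's
    null space (constant + linear coefficient sequences) is removed from
    the random part: the constant is absorbed by the model intercept and
    the linear trend enters the fixed effects, so the REML variance of the
    wiggly block is the smoothing parameter and a pure-noise response
    shrinks back to an effective df of ~1 (the linear term).
    """
    x = np.asarray(x, float)
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo if hi > lo else 1.0
    degree = 3
    n_interior = k - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else np.array([])
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    # second-difference penalty on coefficients
    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D
    vals, vecs = np.linalg.eigh(S)
    pos = vals > vals.max() * 1e-10
    return SmoothBasis(
        x_min=lo,
        x_max=hi,
        knots=knots,
        U_pos=vecs[:, pos],
        scale=1.0 / np.sqrt(vals[pos]),
        x_mean=float(x.mean()),
        x_sd=float(x.std() if x.std() > 0 else 1.0),
    )
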