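"""Pooled-lag panel graphical vector autoregression (GVAR).

The panel GVAR decomposes a person's score on node ``i`` at wave ``t``
into a stable between-person level and a within-person deviation that
follows a lag-1 VAR pooled across consecutive wave pairs (stationarity):

    y_it = mu + b_i + w_it,     w_{i,t+1} = B w_it + zeta_it

* ``B`` (temporal matrix, row = outcome at t, column = predictor at t-1)
  yields the directed temporal network,
* the precision of the innovation covariance ``Sigma_zeta`` yields the
  contemporaneous partial-correlation network,
* the precision of the between-person covariance ``Sigma_b`` yields the
  between-person network.

Networks are parameterized the standard SEM way,
``Sigma = Delta (I - Omega)^-1 Delta`` with ``Omega`` the partial
correlation matrix and ``Delta`` diagonal scales, so fixing an entry of
``Omega`` (or of ``B``) to zero removes exactly one edge.  The model is fit
by Gaussian maximum likelihood on the stacked (p*T)-dimensional
observation vector; the ML discrepancy

    F = logdet(Sigma) + tr(S Sigma^-1) - logdet(S) - p*T

is minimized with an analytic gradient (the Lyapunov equation defining
the stationary within-person covariance is differentiated via its
adjoint), which keeps pruning, bootstrapping and permutation tests fast.
Nonsignificant edges are pruned by iterated Wald tests with refitting, and
edge stability is assessed by a case bootstrap (persons resampled with
replacement, all waves travelling together) with an inclusion-proportion
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .ggm import precision_to_partials

__all__ = [
    "GVARParameters",
    "PanelGVARFit",
    "BootstrapSummary",
    "stationary_within_cov",
    "implied_covariance",
    "fit_panel_gvar",
    "fit_panel_gvar_cov",
    "prune",
    "fit_indices",
    "bootstrap_edges",
    "stable_network",
    "temporal_std",
    "scores_to_wide",
    "NODES",
]

NODES = ["irr", "pstr", "nVio", "psyAgg", "phyAs", "neg"]

_RHO_MAX = 0.995


class GVARError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameters and pattern
# ---------------------------------------------------------------------------

def network_to_cov(omega: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Covariance implied by a partial-correlation network and scales."""
    p = omega.shape[0]
    Y = np.linalg.inv(np.eye(p) - omega)
    return (delta[:, None] * Y) * delta[None, :]


def cov_to_network(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`network_to_cov`: (omega, delta) from a PD cov."""
    K = np.linalg.inv(sigma)
    delta = 1.0 / np.sqrt(np.diag(K))
    omega = precision_to_partials(K)
    return omega, delta


@dataclass
class GVARParameters:
    """Point estimates of a panel GVAR (p nodes)."""

    nodes: list[str]
    beta: np.ndarray          # temporal matrix B (p, p)
    omega_zeta: np.ndarray    # contemporaneous partial correlations
    delta_zeta: np.ndarray    # innovation scales
    omega_b: np.ndarray       # between-person partial correlations
    delta_b: np.ndarray       # between-person scales
    mu: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def sigma_zeta(self) -> np.ndarray:
        return network_to_cov(self.omega_zeta, self.delta_zeta)

    @property
    def sigma_b(self) -> np.ndarray:
        return network_to_cov(self.omega_b, self.delta_b)

    def copy(self) -> "GVARParameters":
        return GVARParameters(
            list(self.nodes), self.beta.copy(), self.omega_zeta.copy(),
            self.delta_zeta.copy(), self.omega_b.copy(), self.delta_b.copy(),
            None if self.mu is None else self.mu.copy(),
        )


@dataclass
class Pattern:
    """Free/fixed masks for the structural parameters.

    Diagonal scales (delta) are always free; masks cover B entries and the
    strict lower triangles of the two symmetric networks.
    """

    free_beta: np.ndarray
    free_oz: np.ndarray  # (p, p) bool, strict lower triangle meaningful
    free_ob: np.ndarray

    @classmethod
    def saturated(cls, p: int) -> "Pattern":
        tl = np.tril(np.ones((p, p), dtype=bool), -1)
        return cls(np.ones((p, p), dtype=bool), tl.copy(), tl.copy())

    def n_free(self, p: int) -> int:
        return int(self.free_beta.sum() + self.free_oz.sum()
                   + self.free_ob.sum()) + 2 * p

    def copy(self) -> "Pattern":
        return Pattern(self.free_beta.copy(), self.free_oz.copy(),
                       self.free_ob.copy())


def _pack(params: GVARParameters, pat: Pattern) -> np.ndarray:
    il = _tril(params.p)
    return np.concatenate([
        params.beta[pat.free_beta],
        params.omega_zeta[il][pat.free_oz[il]],
        np.log(params.delta_zeta),
        params.omega_b[il][pat.free_ob[il]],
        np.log(params.delta_b),
    ])


def _unpack(theta: np.ndarray, pat: Pattern, p: int, nodes) -> GVARParameters:
    il = _tril(p)
    k = 0
    B = np.zeros((p, p))
    nb = int(pat.free_beta.sum())
    B[pat.free_beta] = theta[k:k + nb]
    k += nb
    oz = np.zeros((p, p))
    noz = int(pat.free_oz[il].sum())
    vals = np.zeros(len(il[0]))
    vals[pat.free_oz[il]] = theta[k:k + noz]
    oz[il] = vals
    oz = oz + oz.T
    k += noz
    dz = np.exp(theta[k:k + p])
    k += p
    ob = np.zeros((p, p))
    nob = int(pat.free_ob[il].sum())
    vals = np.zeros(len(il[0]))
    vals[pat.free_ob[il]] = theta[k:k + nob]
    ob[il] = vals
    ob = ob + ob.T
    k += nob
    db = np.exp(theta[k:k + p])
    return GVARParameters(list(nodes), B, oz, dz, ob, db)


# ---------------------------------------------------------------------------
# stationary covariance (discrete Lyapunov) and implied covariance
# ---------------------------------------------------------------------------

def _lyap_lu(B: np.ndarray):
    """LU factorization of I - kron(B, B) (row-major vec convention)."""
    p = B.shape[0]
    return linalg.lu_factor(np.eye(p * p) - np.kron(B, B))


def _lyap_solve(lu, Q: np.ndarray, trans: int = 0) -> np.ndarray:
    p = Q.shape[0]
    v = linalg.lu_solve(lu, Q.ravel(), trans=trans)
    return v.reshape(p, p)


def stationary_within_cov(B: np.ndarray, sigma_zeta: np.ndarray) -> np.ndarray:
    """Stationary covariance S solving ``S = B S B' + Sigma_zeta``.

    Requires spectral radius of B below 1 and PD ``sigma_zeta``.
    """
    B = np.asarray(B, dtype=float)
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    if rho >= 1.0:
        raise GVARError(f"temporal matrix is non-stationary (rho={rho:.3f})")
    S = _lyap_solve(_lyap_lu(B), np.asarray(sigma_zeta, dtype=float))
    return (S + S.T) / 2.0


def implied_covariance(params: GVARParameters, waves: int = 3) -> np.ndarray:
    """Model-implied covariance of the stacked (p*waves)-vector.

    Block (t, s) with t >= s equals ``B^(t-s) S + Sigma_b`` where S is the
    stationary within-person covariance; diagonal blocks are
    ``S + Sigma_b``.
    """
    p = params.p
    S0 = stationary_within_cov(params.beta, params.sigma_zeta)
    Sb = params.sigma_b
    big = np.zeros((p * waves, p * waves))
    Bk = [np.eye(p)]
    for _ in range(waves - 1):
        Bk.append(params.beta @ Bk[-1])
    for t in range(waves):
        for s in range(t + 1):
            blk = Bk[t - s] @ S0 + Sb
            big[t * p:(t + 1) * p, s * p:(s + 1) * p] = blk
            if t != s:
                big[s * p:(s + 1) * p, t * p:(t + 1) * p] = blk.T
    return (big + big.T) / 2.0


# ---------------------------------------------------------------------------
# ML objective with analytic gradient (T = 3 pooled-lag model)
# ---------------------------------------------------------------------------

def _sym(A):
    return (A + A.T) / 2.0


_TRIL_CACHE: dict = {}


def _tril(p):
    if p not in _TRIL_CACHE:
        _TRIL_CACHE[p] = np.tril_indices(p, -1)
    return _TRIL_CACHE[p]


def _objective_grad(theta, S_samp, pat, p, T, nodes, want_grad=True):
    """F_ML and its gradient w.r.t. the packed free parameters."""
    par = _unpack(theta, pat, p, nodes)
    B = par.beta
    # fast sufficient stationarity screen; exact check only near the edge
    if min(np.abs(B).sum(axis=1).max(), np.abs(B).sum(axis=0).max()) \
            >= _RHO_MAX:
        if np.max(np.abs(np.linalg.eigvals(B))) >= _RHO_MAX:
            return np.inf, np.zeros_like(theta)
    q = p * T
    Iq = np.eye(p)
    try:
        Yz = np.linalg.inv(Iq - par.omega_zeta)
        Yb = np.linalg.inv(Iq - par.omega_b)
        np.linalg.cholesky(_sym(Yz))
        np.linalg.cholesky(_sym(Yb))
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    dz, db = par.delta_zeta, par.delta_b
    Sz = (dz[:, None] * Yz) * dz[None, :]
    Sb = (db[:, None] * Yb) * db[None, :]
    # I - kron(B, B) without np.kron overhead
    M = np.eye(p * p) - (B[:, None, :, None] * B[None, :, None, :]
                         ).reshape(p * p, p * p)
    try:
        lu = linalg.lu_factor(M, check_finite=False)
    except (linalg.LinAlgError, ValueError):
        return np.inf, np.zeros_like(theta)
    S0 = linalg.lu_solve(lu, Sz.ravel(), check_finite=False).reshape(p, p)
    S0 = _sym(S0)
    Bk = [Iq]
    for _ in range(T - 1):
        Bk.append(B @ Bk[-1])
    Sigma = np.empty((q, q))
    for t in range(T):
        for s in range(t + 1):
            blk = Bk[t - s] @ S0 + Sb
            Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p] = blk
            if t != s:
                Sigma[s * p:(s + 1) * p, t * p:(t + 1) * p] = blk.T
    Sigma = _sym(Sigma)
    try:
        c = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    cinv = linalg.solve_triangular(c, np.eye(q), lower=True,
                                   check_finite=False)
    Sinv = cinv.T @ cinv
    F = logdet + float(np.sum(Sinv * S_samp))
    if not want_grad:
        return F, None

    # W = dF/dSigma (elementwise)
    W = Sinv - Sinv @ S_samp @ Sinv
    blocks = [[W[t * p:(t + 1) * p, s * p:(s + 1) * p] for s in range(T)]
              for t in range(T)]
    W0 = sum(blocks[t][t] for t in range(T))
    # lag-k collected lower blocks
    Wk = [None] * T
    for k in range(1, T):
        Wk[k] = sum(blocks[t][t - k] for t in range(k, T))

    G_B = np.zeros((p, p))
    G_S = W0.copy()
    for k in range(1, T):
        Wklow = Wk[k]
        G_S += 2.0 * Bk[k].T @ Wklow
        # d(B^k S0) w.r.t. B: sum_{m=0}^{k-1} B^m dB B^{k-1-m} S0
        for m in range(k):
            G_B += 2.0 * Bk[m].T @ Wklow @ (Bk[k - 1 - m] @ S0).T
    G_S = _sym(G_S)
    # adjoint of the Lyapunov solve: Ghat = B' Ghat B + G_S
    Ghat = _lyap_solve(lu, G_S, trans=1)
    G_B += (Ghat + Ghat.T) @ B @ S0
    G_Sz = _sym(Ghat)
    G_Sb = _sym(W0 + sum(2.0 * Wk[k] for k in range(1, T)))

    def chain_network(G, Y, d):
        M = Y @ (d[:, None] * G * d[None, :]) @ Y
        g_omega = 2.0 * M  # per strict-lower parameter
        g_logd = 2.0 * np.einsum("ij,ji->i", Y * d[None, :], G) * d
        # (Y Delta G)_ii * 2 * delta_i ; einsum row i of Y*d with col i of G
        return g_omega, g_logd

    g_oz, g_ldz = chain_network(G_Sz, Yz, dz)
    g_ob, g_ldb = chain_network(G_Sb, Yb, db)

    il = _tril(p)
    grad = np.concatenate([
        G_B[pat.free_beta],
        g_oz[il][pat.free_oz[il]],
        g_ldz,
        g_ob[il][pat.free_ob[il]],
        g_ldb,
    ])
    return F, grad


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class PanelGVARFit:
    """A fitted (possibly pruned) panel GVAR."""

    params: GVARParameters
    pattern: Pattern
    se: dict                      # name -> standard error arrays
    loglik: float                 # -(n-1)/2 * (F + logdet S + q) + c form
    discrepancy: float            # F_ML at the optimum
    df: int
    n: int
    waves: int
    sample_cov: np.ndarray
    converged: bool
    chi2: float
    baseline_chi2: float
    baseline_df: int
    theta: np.ndarray = field(repr=False, default=None)
    pvalues: dict = field(default_factory=dict)
    missing: str = "complete"

    @property
    def nodes(self):
        return self.params.nodes

    def indices(self) -> dict:
        return fit_indices(self.chi2, self.df, self.baseline_chi2,
                           self.baseline_df, self.n)

    def to_dict(self) -> dict:
        S0 = stationary_within_cov(self.params.beta, self.params.sigma_zeta)
        return {
            "nodes": list(self.params.nodes),
            "temporal": self.params.beta.tolist(),
            "temporal_std": temporal_std(self).tolist(),
            "contemporaneous": self.params.omega_zeta.tolist(),
            "between": self.params.omega_b.tolist(),
            "innovation_scales": self.params.delta_zeta.tolist(),
            "between_scales": self.params.delta_b.tolist(),
            "pattern": {
                "temporal": self.pattern.free_beta.astype(int).tolist(),
                "contemporaneous": self.pattern.free_oz.astype(int).tolist(),
                "between": self.pattern.free_ob.astype(int).tolist(),
            },
            "stationary_within_cov": S0.tolist(),
            "n": self.n,
            "df": self.df,
            "chi2": self.chi2,
            "fit_indices": self.indices(),
            "converged": bool(self.converged),
            "missing": self.missing,
        }


def scores_to_wide(scores: pd.DataFrame, nodes=NODES,
                   waves=(3, 5, 9)) -> np.ndarray:
    """Pivot a long score table (person_id, wave, nodes...) to n x (p*T)."""
    wide = scores.pivot_table(index="person_id", columns="wave",
                              values=list(nodes), dropna=False)
    cols = [(v, w) for w in waves for v in nodes]
    return wide.reindex(columns=pd.MultiIndex.from_tuples(cols)).to_numpy()


def _moment_start(Y: np.ndarray, p: int, T: int) -> GVARParameters:
    """Moment-based starting values from complete-case wide data."""
    n = Y.shape[0]
    yw = Y.reshape(n, T, p)
    pm = yw.mean(axis=1, keepdims=True)
    dev = yw - pm
    C0 = sum(dev[:, t].T @ dev[:, t] for t in range(T)) / (n * T)
    C1 = sum(dev[:, t + 1].T @ dev[:, t] for t in range(T - 1)) / (n * (T - 1))
    C0 = _sym(C0) + 1e-6 * np.eye(p)
    B0 = C1 @ np.linalg.inv(C0)
    rho = np.max(np.abs(np.linalg.eigvals(B0)))
    if rho > 0.9:
        B0 *= 0.85 / rho
    Sz0 = _sym(C0 - B0 @ C0 @ B0.T)
    Sz0 = _pd_clip(Sz0, 0.05 * np.trace(Sz0) / p)
    Sb0 = _sym(np.cov(pm[:, 0, :], rowvar=False, ddof=1) - C0 / T)
    Sb0 = _pd_clip(Sb0, 0.05 * max(np.trace(Sb0), 0.1 * np.trace(C0)) / p)
    oz, dz = cov_to_network(Sz0)
    ob, db = cov_to_network(Sb0)
    return GVARParameters(list(NODES[:p]) if p == len(NODES) else
                          [f"V{i}" for i in range(p)],
                          B0, oz, dz, ob, db)


def _pd_clip(A: np.ndarray, floor: float) -> np.ndarray:
    w, V = np.linalg.eigh(A)
    return (V * np.maximum(w, floor)) @ V.T


def fit_panel_gvar_cov(
    S_samp: np.ndarray,
    n: int,
    nodes,
    *,
    waves: int = 3,
    pattern: Pattern | None = None,
    start: GVARParameters | None = None,
    compute_se: bool = True,
    maxiter: int = 400,
) -> PanelGVARFit:
    """Fit the pooled-lag panel GVAR to a stacked sample covariance."""
    p = len(nodes)
    q = p * waves
    if S_samp.shape != (q, q):
        raise GVARError("sample covariance has wrong shape")
    wmin = np.linalg.eigvalsh(S_samp)[0]
    if wmin <= 1e-10:
        warnings.warn("sample covariance not PD; ridge-regularized",
                      stacklevel=2)
        S_samp = S_samp + (1e-8 - min(wmin, 0)) * np.eye(q)
    pat = pattern if pattern is not None else Pattern.saturated(p)
    if start is None:
        # neutral start: diagonal B, diagonal networks sized from S_samp
        d = np.sqrt(np.diag(S_samp)[:p])
        start = GVARParameters(
            list(nodes), 0.2 * np.eye(p), np.zeros((p, p)),
            d * 0.6, np.zeros((p, p)), d * 0.6)
    theta0 = _pack(start, pat)
    sign, logdetS = np.linalg.slogdet(S_samp)
    fun = lambda th: _objective_grad(th, S_samp, pat, p, waves, nodes)
    res = optimize.minimize(fun, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-12,
                                     "gtol": 1e-7})
    gnorm = np.linalg.norm(res.jac, np.inf)
    if not res.success and gnorm > 1e-3:
        # retry from a neutral diagonal start
        d = np.sqrt(np.diag(S_samp)[:p])
        neutral = GVARParameters(
            list(nodes), 0.2 * np.eye(p), np.zeros((p, p)), d * 0.6,
            np.zeros((p, p)), d * 0.6)
        res2 = optimize.minimize(fun, _pack(neutral, pat), jac=True,
                                 method="L-BFGS-B",
                                 options={"maxiter": 2 * maxiter,
                                          "ftol": 1e-12, "gtol": 1e-7})
        if res2.fun < res.fun:
            res = res2
            gnorm = np.linalg.norm(res.jac, np.inf)
    theta = res.x
    F = float(res.fun) - logdetS - q
    params = _unpack(theta, pat, p, nodes)
    if not np.isfinite(F):
        raise GVARError(f"panel GVAR fit diverged (status {res.status})")
    converged = bool(res.success or gnorm < 1e-4)
    if not converged and gnorm > 5e-2:
        raise GVARError(
            f"panel GVAR did not converge (grad norm {gnorm:.2e})")
    if not converged:
        warnings.warn(f"panel GVAR stopped with gradient norm {gnorm:.2e}",
                      stacklevel=2)

    nfree = pat.n_free(p)
    df = q * (q + 1) // 2 - nfree
    N = max(n - 1, 1)
    chi2 = max(N * F, 0.0)
    # independence baseline: free variances, zero covariances
    Fb = float(np.sum(np.log(np.diag(S_samp)))) - logdetS
    chi2_b = max(N * Fb, 0.0)
    df_b = q * (q + 1) // 2 - q

    se, pvals = {}, {}
    if compute_se:
        se, pvals = _wald(theta, S_samp, pat, p, waves, nodes, N)

    loglik = -0.5 * N * (float(res.fun))
    return PanelGVARFit(
        params=params, pattern=pat, se=se, loglik=loglik, discrepancy=F,
        df=df, n=n, waves=waves, sample_cov=S_samp, converged=converged,
        chi2=chi2, baseline_chi2=chi2_b, baseline_df=df_b, theta=theta,
        pvalues=pvals)


def _wald(theta, S_samp, pat, p, T, nodes, N):
    """SEs and Wald p-values via finite differences of the analytic grad."""
    k = len(theta)
    H = np.zeros((k, k))
    _, g0 = _objective_grad(theta, S_samp, pat, p, T, nodes)
    eps = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for i in range(k):
        th = theta.copy()
        th[i] += eps[i]
        _, gi = _objective_grad(th, S_samp, pat, p, T, nodes)
        H[i] = (gi - g0) / eps[i]
    H = _sym(H)
    try:
        cov = 2.0 / N * np.linalg.pinv(H, hermitian=True)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((k, k), np.nan)
    var = np.clip(np.diag(cov), 0, None)
    sd = np.sqrt(var)
    z = np.where(sd > 0, theta / np.where(sd > 0, sd, 1.0), np.inf)
    pv = 2.0 * stats.norm.sf(np.abs(z))
    # unpack into named blocks
    il = _tril(p)
    out_se, out_p = {}, {}
    k0 = 0
    for name, mask_len in [
        ("beta", int(pat.free_beta.sum())),
        ("omega_zeta", int(pat.free_oz[il].sum())),
        ("log_delta_zeta", p),
        ("omega_b", int(pat.free_ob[il].sum())),
        ("log_delta_b", p),
    ]:
        out_se[name] = sd[k0:k0 + mask_len]
        out_p[name] = pv[k0:k0 + mask_len]
        k0 += mask_len
    return out_se, out_p


def fit_panel_gvar(
    scores: pd.DataFrame,
    nodes=NODES,
    *,
    waves=(3, 5, 9),
    missing: str = "complete",
    compute_se: bool = True,
    min_n: int = 100,
) -> PanelGVARFit:
    """Fit the panel GVAR to a long score table for one group.

    ``missing='complete'`` (default) drops persons with any missing wave;
    ``missing='fiml'`` uses full-information ML over the monotone
    missingness patterns (slower; numeric gradient).
    """
    Y = scores_to_wide(scores, nodes, waves)
    p, T = len(nodes), len(waves)
    complete = ~np.isnan(Y).any(axis=1)
    Yc = Y[complete]
    if missing == "complete":
        n = Yc.shape[0]
        if n < min_n:
            raise GVARError(f"need >= {min_n} complete cases, got {n}")
        S = np.cov(Yc, rowvar=False, ddof=1)
        start = _moment_start(Yc, p, T)
        start.nodes = list(nodes)
        fit = fit_panel_gvar_cov(S, n, nodes, waves=T, start=start,
                                 compute_se=compute_se)
        fit.params.mu = Yc.mean(axis=0)[:p]
        return fit
    if missing == "fiml":
        return _fit_fiml(Y, Yc, nodes, T, compute_se=compute_se, min_n=min_n)
    raise ValueError(f"unknown missing-data mode {missing!r}")


def _fit_fiml(Y, Yc, nodes, T, *, compute_se, min_n):
    """Flagged FIML mode: monotone patterns, numeric gradient (slower)."""
    warnings.warn("FIML mode is slower than complete-case", stacklevel=3)
    p = len(nodes)
    q = p * T
    obs_rows = ~np.isnan(Y).all(axis=1)
    Y = Y[obs_rows]
    if Yc.shape[0] < min_n:
        raise GVARError("too few complete cases for starting values")
    pats = {}
    for row in Y:
        key = tuple(np.where(~np.isnan(row))[0])
        pats.setdefault(key, []).append(row)
    groups = []
    for key, rows in pats.items():
        X = np.asarray(rows)[:, list(key)]
        idx = np.array(key)
        nk = X.shape[0]
        groups.append((idx, nk, X.mean(axis=0),
                       np.cov(X, rowvar=False, ddof=0) if nk > 1 else
                       np.zeros((len(key), len(key)))))
    pat = Pattern.saturated(p)
    start = _moment_start(Yc, p, T)
    mu0 = np.nanmean(Y, axis=0)
    theta0 = np.concatenate([_pack(start, pat), mu0])
    nstruct = pat.n_free(p)

    def negll(th):
        par = _unpack(th[:nstruct], pat, p, nodes)
        mu = th[nstruct:]
        try:
            Sigma = implied_covariance(par, T)
        except GVARError:
            return np.inf
        tot = 0.0
        for idx, nk, xbar, Sk in groups:
            Sub = Sigma[np.ix_(idx, idx)]
            try:
                cf = linalg.cho_factor(Sub)
            except linalg.LinAlgError:
                return np.inf
            logdet = 2 * np.sum(np.log(np.diag(cf[0])))
            d = xbar - mu[idx]
            tot += nk * (logdet + np.sum(linalg.cho_solve(cf, Sk).diagonal())
                         + d @ linalg.cho_solve(cf, d))
        return 0.5 * tot

    res = optimize.minimize(negll, theta0, method="L-BFGS-B",
                            options={"maxiter": 3000, "maxfun": 200000})
    params = _unpack(res.x[:nstruct], pat, p, nodes)
    params.mu = res.x[nstruct:][:p]
    n = Y.shape[0]
    S = np.cov(Yc, rowvar=False, ddof=1)
    sign, logdetS = np.linalg.slogdet(S)
    df = q * (q + 1) // 2 - pat.n_free(p)
    return PanelGVARFit(
        params=params, pattern=pat, se={}, loglik=-res.fun,
        discrepancy=np.nan, df=df, n=n, waves=T, sample_cov=S,
        converged=bool(res.success), chi2=np.nan,
        baseline_chi2=np.nan, baseline_df=q * (q + 1) // 2 - q,
        theta=res.x, missing="fiml")


def fit_prune_wide(Y: np.ndarray, nodes, *, waves: int = 3,
                   alpha: float | None = 0.01,
                   start: GVARParameters | None = None,
                   min_n: int = 100) -> "PanelGVARFit":
    """Fit (and optionally prune) from an n x (p*waves) wide matrix.

    Used by the bootstrap and permutation machinery, which resample or
    relabel persons many times: the pivot to wide format happens once in
    the caller.  ``alpha=None`` skips pruning.
    """
    p = len(nodes)
    Yc = Y[~np.isnan(Y).any(axis=1)]
    n = Yc.shape[0]
    if n < min_n:
        raise GVARError(f"need >= {min_n} complete cases, got {n}")
    S = np.cov(Yc, rowvar=False, ddof=1)
    if start is None:
        start = _moment_start(Yc, p, waves)
    fit = fit_panel_gvar_cov(S, n, nodes, waves=waves, start=start,
                             compute_se=alpha is not None)
    if alpha is not None:
        fit = prune(fit, alpha)
    return fit


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune(fit: PanelGVARFit, alpha: float = 0.01,
          max_rounds: int = 20) -> PanelGVARFit:
    """Iteratively fix nonsignificant structural edges to zero and refit.

    All free entries of the temporal matrix (including autoregressive
    diagonals) and of the two partial-correlation networks with Wald
    p >= alpha are fixed to zero in each round; scales (variances) stay
    free.  Stops when no parameter is removable.  If a refit fails the
    last converged model is returned with a warning.
    """
    cur = fit
    p = fit.params.p
    il = np.tril_indices(p, -1)
    for _ in range(max_rounds):
        if not cur.pvalues:
            break
        pat = cur.pattern.copy()
        removed = 0
        pv_b = cur.pvalues.get("beta")
        if pv_b is not None and pv_b.size:
            drop = pv_b >= alpha
            if drop.any():
                idx = np.argwhere(pat.free_beta)
                for (i, j), d in zip(idx, drop):
                    if d:
                        pat.free_beta[i, j] = False
                        removed += 1
        for key, mask_attr in [("omega_zeta", "free_oz"),
                               ("omega_b", "free_ob")]:
            pv = cur.pvalues.get(key)
            if pv is None or not pv.size:
                continue
            mask = getattr(pat, mask_attr)
            sel = np.argwhere(mask[il].copy())
            flat = np.where(mask[il])[0]
            for pos, d in zip(flat, pv >= alpha):
                if d:
                    i, j = il[0][pos], il[1][pos]
                    mask[i, j] = False
                    removed += 1
        if removed == 0:
            break
        start = cur.params.copy()
        start.beta[~pat.free_beta] = 0.0
        oz = start.omega_zeta
        ob = start.omega_b
        full = np.zeros((p, p), dtype=bool)
        full[il] = pat.free_oz[il]
        oz[~(full | full.T)] = 0.0
        np.fill_diagonal(oz, 0.0)
        full = np.zeros((p, p), dtype=bool)
        full[il] = pat.free_ob[il]
        ob[~(full | full.T)] = 0.0
        np.fill_diagonal(ob, 0.0)
        try:
            cur = fit_panel_gvar_cov(cur.sample_cov, cur.n, cur.nodes,
                                     waves=cur.waves, pattern=pat,
                                     start=start, compute_se=True)
        except GVARError as e:
            warnings.warn(f"prune refit failed ({e}); returning last "
                          "converged model", stacklevel=2)
            break
    return cur


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def fit_indices(chi2_m: float, df_m: int, chi2_b: float, df_b: int,
                n: int) -> dict:
    """SEM fit indices from model and baseline chi-square statistics.

    CFI, TLI and RMSEA follow the standard covariance-structure formulas;
    the baseline is the independence model with free variances.  With
    ``df_m = 0`` the model is saturated: CFI = 1, RMSEA = 0, TLI flagged
    undefined (NaN).
    """
    chi2_m = float(chi2_m)
    if df_m == 0:
        return {"chi2": chi2_m, "df": 0, "cfi": 1.0, "tli": np.nan,
                "rmsea": 0.0}
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df_b > 0 and chi2_b / df_b != 1.0:
        tli = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = np.nan
    rmsea = np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * max(n - 1, 1)))
    return {"chi2": chi2_m, "df": int(df_m), "cfi": float(cfi),
            "tli": float(tli), "rmsea": float(rmsea)}


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

EDGE_KINDS = ("temporal", "contemporaneous", "between")


def edge_list(nodes) -> list[tuple[str, str, str]]:
    """All structural edges: directed temporal (incl. autoregressive) and
    undirected contemporaneous/between pairs."""
    p = len(nodes)
    out = []
    for i in range(p):
        for j in range(p):
            out.append(("temporal", nodes[j], nodes[i]))  # j at t-1 -> i at t
    for kind in ("contemporaneous", "between"):
        for i in range(p):
            for j in range(i):
                out.append((kind, nodes[j], nodes[i]))
    return out


def edge_value(fit_or_params, kind: str, frm: str, to: str) -> float:
    """Edge estimate; directed temporal edges read B[to, frm]."""
    par = fit_or_params.params if isinstance(fit_or_params, PanelGVARFit) \
        else fit_or_params
    i, j = par.nodes.index(to), par.nodes.index(frm)
    if kind == "temporal":
        return float(par.beta[i, j])
    if kind == "contemporaneous":
        return float(par.omega_zeta[i, j])
    if kind == "between":
        return float(par.omega_b[i, j])
    raise ValueError(kind)


def _edge_included(fit: PanelGVARFit, kind, frm, to) -> bool:
    par = fit.params
    i, j = par.nodes.index(to), par.nodes.index(frm)
    if kind == "temporal":
        return bool(fit.pattern.free_beta[i, j]
                    and abs(par.beta[i, j]) > 1e-10)
    a, b = max(i, j), min(i, j)
    mask = fit.pattern.free_oz if kind == "contemporaneous" \
        else fit.pattern.free_ob
    mat = par.omega_zeta if kind == "contemporaneous" else par.omega_b
    return bool(mask[a, b] and abs(mat[a, b]) > 1e-10)


@dataclass
class BootstrapSummary:
    """Per-edge inclusion proportions over case-bootstrap replicates."""

    edges: list[tuple[str, str, str]]
    proportions: np.ndarray
    R: int
    n_success: int
    seed: int
    threshold: float = 0.5

    def proportion(self, kind, frm, to) -> float:
        return float(self.proportions[self.edges.index((kind, frm, to))])

    def to_dict(self) -> dict:
        return {
            "R": self.R, "n_success": self.n_success, "seed": self.seed,
            "threshold": self.threshold,
            "edges": [{"kind": k, "from": f, "to": t, "inclusion": float(pr)}
                      for (k, f, t), pr in zip(self.edges, self.proportions)],
        }


def bootstrap_edges(
    scores: pd.DataFrame,
    nodes=NODES,
    *,
    waves=(3, 5, 9),
    R: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    base_fit: PanelGVARFit | None = None,
) -> BootstrapSummary:
    """Case bootstrap of the fit->prune pipeline.

    Persons are resampled with replacement (all of a person's waves travel
    together); each resample is refit and pruned; an edge counts as
    included when it is free and nonzero after pruning.  Failed replicates
    are excluded from the denominator and reported via ``n_success``.
    """
    rng = np.random.default_rng(seed)
    Y = scores_to_wide(scores, nodes, waves)
    Y = Y[~np.isnan(Y).any(axis=1)]
    n = Y.shape[0]
    p, T = len(nodes), len(waves)
    if base_fit is None:
        S = np.cov(Y, rowvar=False, ddof=1)
        base_fit = fit_panel_gvar_cov(S, n, nodes, waves=T,
                                      start=_moment_start(Y, p, T))
    edges = edge_list(nodes)
    counts = np.zeros(len(edges))
    n_success = 0
    for r in range(R):
        idx = rng.integers(0, n, n)
        Sb = np.cov(Y[idx], rowvar=False, ddof=1)
        try:
            f = fit_panel_gvar_cov(Sb, n, nodes, waves=T,
                                   start=base_fit.params.copy())
            f = prune(f, alpha)
        except (GVARError, np.linalg.LinAlgError):
            continue
        n_success += 1
        for e, (kind, frm, to) in enumerate(edges):
            if _edge_included(f, kind, frm, to):
                counts[e] += 1
    if n_success == 0:
        raise GVARError("all bootstrap replicates failed")
    if n_success < R:
        warnings.warn(f"{R - n_success} bootstrap replicates failed",
                      stacklevel=2)
    return BootstrapSummary(edges, counts / n_success, R, n_success, seed)


def stable_network(fit: PanelGVARFit, boots: BootstrapSummary,
                   threshold: float = 0.5) -> GVARParameters:
    """Mask edges whose bootstrap inclusion proportion is below threshold.

    The boundary is inclusive: proportion exactly equal to the threshold
    survives.  Surviving edges keep their original estimates.
    """
    if list(boots.edges[0][1:]) and set(fit.params.nodes) != \
            {n for e in boots.edges for n in e[1:]}:
        raise GVARError("bootstrap summary does not match fit's node set")
    par = fit.params.copy()
    for (kind, frm, to), pr in zip(boots.edges, boots.proportions):
        if pr >= threshold:
            continue
        i, j = par.nodes.index(to), par.nodes.index(frm)
        if kind == "temporal":
            par.beta[i, j] = 0.0
        elif kind == "contemporaneous":
            par.omega_zeta[i, j] = par.omega_zeta[j, i] = 0.0
        else:
            par.omega_b[i, j] = par.omega_b[j, i] = 0.0
    return par


# ---------------------------------------------------------------------------
# standardization of the temporal network
# ---------------------------------------------------------------------------

def temporal_std(fit: PanelGVARFit | GVARParameters) -> np.ndarray:
    """Temporal matrix on a correlation-like (unit-free) scale.

    ``std[i, j] = B[i, j] * sqrt(S_jj / S_ii)`` with S the stationary
    within-person covariance: each coefficient is expressed per standard
    deviation of the predictor, in standard deviations of the outcome.
    For a scalar AR(1) this is the lag-1 autocorrelation; for a
    unit-variance process it coincides with B.
    """
    par = fit.params if isinstance(fit, PanelGVARFit) else fit
    S0 = stationary_within_cov(par.beta, par.sigma_zeta)
    d = np.sqrt(np.diag(S0))
    return par.beta * (d[None, :] / d[:, None])
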