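"""Generic REML engine for Kronecker-structured variance components.

Every model in this package — single-trait GBLUP, bivariate multi-trait
GBLUP, and the linear-spline random-regression model — is a Gaussian mixed
model whose marginal covariance is *linear* in its parameters:

    V(θ) = Σ_c  Z_c (Σ_c ⊗ K_c) Z_c',

where each random term c has a design matrix Z_c (n × d·q), a known q × q
correlation structure K_c (a genomic relationship matrix, or the identity),
and an unknown d × d covariance Σ_c among its d correlated effect blocks
(traits, spline knots, or a single variance for d = 1). Residuals are just
another term (a selector Z with K = I), so heterogeneous and covarying
residual structures need no special casing: a per-trait record layout over
plots reproduces the standard unbalanced multi-trait residual (full 2×2 for
jointly recorded plots, marginal variance otherwise).

Fitting maximizes the restricted likelihood with EM burn-in followed by
average-information (AI) steps. An AI step is accepted only if it improves
the restricted log-likelihood (escalating Levenberg damping when the full
Newton step fails, then an EM fallback with monotone step amplification),
so the log-likelihood sequence is monotone by construction — the EM update

    Σ_c ← Σ_c + (1/q) Σ_c (W_c − T̃_c) Σ_c,
    W_c[t,s]  = g_t' K g_s,        g = Z_c' P y,
    T̃_c[t,s] = tr(K (Z_c' P Z_c)[t,s]),

never needs K⁻¹, which keeps singular relationship matrices usable.
Interim covariance estimates that drift non-PSD are bent by flooring
eigenvalues at a small fraction of the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import LinearAlgebraError, ParameterError

logger = logging.getLogger("vigblup.reml")

#: eigenvalue floor for bending, as a fraction of the matrix trace
BEND_FRACTION = 1e-6


def bend_psd(sigma: np.ndarray, floor_fraction: float = BEND_FRACTION) -> tuple[np.ndarray, bool]:
    """Floor the eigenvalues of a symmetric matrix to keep it positive definite.

    Returns the (possibly reconstructed) matrix and whether bending occurred.
    """
    sigma = 0.5 * (sigma + sigma.T)
    if sigma.shape == (1, 1):
        floor = floor_fraction * max(abs(sigma[0, 0]), 1.0e-300)
        if sigma[0, 0] < floor:
            return np.array([[floor]]), True
        return sigma, False
    eigval, eigvec = np.linalg.eigh(sigma)
    floor = floor_fraction * max(float(np.trace(sigma)), 0.0)
    floor = max(floor, floor_fraction * float(np.abs(eigval).max() + 1e-300))
    if eigval[0] >= floor:
        return sigma, False
    bent = (eigvec * np.maximum(eigval, floor)) @ eigvec.T
    return 0.5 * (bent + bent.T), True


@dataclass
class RandomTerm:
    """One variance component: effects u ~ N(0, Σ ⊗ K) entering as Z u.

    Parameters
    ----------
    name
        Label used in logs and reports.
    Z
        n × (dim · q) design; column block t (0-based) holds the loadings of
        effect block t, so columns are ordered block-major: (t, level j) →
        column t·q + j.
    K
        Known q × q structure (e.g. a GRM); ``None`` means the identity.
    dim
        Number of correlated effect blocks d (1 for a plain variance).
    start
        Initial d × d covariance Σ; must be symmetric positive definite.
    labels
        Optional names of the d blocks (trait or knot labels).
    """

    name: str
    Z: sp.spmatrix
    K: np.ndarray | None
    dim: int
    start: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.Z = sp.csr_matrix(self.Z)
        self.start = np.atleast_2d(np.asarray(self.start, dtype=float))
        if self.start.shape != (self.dim, self.dim):
            raise ParameterError(f"term {self.name!r}: start covariance must be {self.dim}×{self.dim}")
        if self.Z.shape[1] % self.dim != 0:
            raise ParameterError(f"term {self.name!r}: Z columns not a multiple of dim")
        self.q = self.Z.shape[1] // self.dim
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.q, self.q):
                raise ParameterError(
                    f"term {self.name!r}: K shape {self.K.shape} != ({self.q}, {self.q})"
                )


@dataclass
class REMLResult:
    """Converged (or flagged) REML fit."""

    sigmas: dict[str, np.ndarray]
    loglik: float
    loglik_history: list[float]
    converged: bool
    n_iter: int
    beta: np.ndarray
    beta_cov: np.ndarray
    blups: dict[str, np.ndarray]  # per term: q × dim matrix of effect solutions
    param_se: dict[str, np.ndarray] | None
    n_bendings: int


class MixedModelREML:
    """REML for V(θ) = Σ_c Z_c (Σ_c ⊗ K_c) Z_c' via monotone EM/AI iteration."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        terms: list[RandomTerm],
        tol_loglik: float = 1e-8,
        tol_param: float = 1e-6,
        max_iter: int = 500,
        n_em_burnin: int = 3,
        method: str = "ai",
    ):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n = self.y.size
        if self.X.shape[0] != self.n:
            raise ParameterError("X row count does not match y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ParameterError("fixed-effect design X is rank deficient")
        if not terms:
            raise ParameterError("at least one random term (the residual) is required")
        for t in terms:
            if t.Z.shape[0] != self.n:
                raise ParameterError(f"term {t.name!r}: Z row count does not match y")
        self.terms = terms
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.max_iter = max_iter
        self.n_em_burnin = n_em_burnin
        if method not in ("ai", "em"):
            raise ParameterError("method must be 'ai' or 'em'")
        self.method = method
        self.n_bendings = 0
        self._scale = float(np.var(self.y)) or 1.0
        # cache covariance kron factor helpers
        self._params = [
            (ci, a, b) for ci, t in enumerate(terms) for a in range(t.dim) for b in range(a, t.dim)
        ]

    # -- linear algebra at the current parameter values ----------------------

    def _build_v(self, sigmas: list[np.ndarray]) -> np.ndarray:
        v = np.zeros((self.n, self.n))
        for term, sigma in zip(self.terms, sigmas):
            if term.K is None:
                cov = sp.kron(sp.csr_matrix(sigma), sp.eye(term.q, format="csr"), format="csr")
                contrib = (term.Z @ cov @ term.Z.T).toarray()
            else:
                cov = np.kron(sigma, term.K)
                zc = term.Z @ cov  # dense n × dq
                contrib = (term.Z @ zc.T).T  # = zc @ Z', computed sparse-side
            v += contrib
        return 0.5 * (v + v.T)

    def _factorize(self, sigmas: list[np.ndarray]) -> dict | None:
        """Factorize V, form P implicitly, return likelihood pieces (None if V not PD)."""
        v = self._build_v(sigmas)
        try:
            chol = sla.cho_factor(v, lower=True, check_finite=False)
        except sla.LinAlgError:
            return None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        vinv, info = sla.lapack.dpotri(chol[0], lower=1)
        if info != 0:
            return None
        vinv = np.tril(vinv) + np.tril(vinv, -1).T
        vx = vinv @ self.X
        m = self.X.T @ vx
        sign, logdet_m = np.linalg.slogdet(m)
        if sign <= 0:
            return None
        m_inv = np.linalg.inv(m)
        p = vinv - vx @ m_inv @ vx.T
        p = 0.5 * (p + p.T)
        py = p @ self.y
        loglik = -0.5 * (logdet_v + logdet_m + float(self.y @ py))
        return {
            "vinv": vinv,
            "p": p,
            "py": py,
            "m_inv": m_inv,
            "vx": vx,
            "loglik": loglik,
        }

    def _term_stats(self, state: dict) -> list[dict]:
        """Per-term g blocks, W and T̃ matrices feeding both EM and AI updates."""
        stats = []
        p = state["p"]
        py = state["py"]
        for term in self.terms:
            g = term.Z.T @ py  # dq vector
            gb = g.reshape(term.dim, term.q)
            zp = term.Z.T @ p  # dq × n (dense)
            t_full = zp @ term.Z  # dq × dq
            d, q = term.dim, term.q
            w = np.empty((d, d))
            t_tilde = np.empty((d, d))
            for a in range(d):
                for b in range(a, d):
                    block = t_full[a * q : (a + 1) * q, b * q : (b + 1) * q]
                    if term.K is None:
                        w[a, b] = w[b, a] = float(gb[a] @ gb[b])
                        t_tilde[a, b] = t_tilde[b, a] = float(np.trace(block))
                    else:
                        w[a, b] = w[b, a] = float(gb[a] @ term.K @ gb[b])
                        t_tilde[a, b] = t_tilde[b, a] = float(np.sum(block * term.K.T))
                    # tr(K @ block) via elementwise product; K symmetric
            stats.append({"g": gb, "w": w, "t_tilde": t_tilde})
        return stats

    # -- updates --------------------------------------------------------------

    def _em_step(self, sigmas: list[np.ndarray], stats: list[dict]) -> list[np.ndarray]:
        new = []
        for term, sigma, st in zip(self.terms, sigmas, stats):
            update = sigma + (sigma @ (st["w"] - st["t_tilde"]) @ sigma) / term.q
            bent, did = bend_psd(update)
            self.n_bendings += int(did)
            if did:
                logger.debug("EM bending applied to term %s", term.name)
            new.append(bent)
        return new

    def _score_and_ai(self, sigmas: list[np.ndarray], state: dict, stats: list[dict]):
        n_par = len(self._params)
        score = np.empty(n_par)
        h = np.empty((n_par, self.n))
        for i, (ci, a, b) in enumerate(self._params):
            term = self.terms[ci]
            st = stats[ci]
            mult = 1.0 if a == b else 2.0
            score[i] = 0.5 * mult * (st["w"][a, b] - st["t_tilde"][a, b])
            # h_i = dV_i @ Py = Z (E_ab ⊗ K) g
            gb = st["g"]
            blocks = np.zeros_like(gb)
            if term.K is None:
                blocks[a] += gb[b]
                if a != b:
                    blocks[b] += gb[a]
            else:
                blocks[a] += term.K @ gb[b]
                if a != b:
                    blocks[b] += term.K @ gb[a]
            h[i] = term.Z @ blocks.ravel()
        ph = state["p"] @ h.T  # n × n_par
        ai = 0.5 * (h @ ph)
        ai = 0.5 * (ai + ai.T)
        return score, ai

    def _theta_to_sigmas(self, theta: np.ndarray) -> list[np.ndarray]:
        sigmas = [np.zeros((t.dim, t.dim)) for t in self.terms]
        for val, (ci, a, b) in zip(theta, self._params):
            sigmas[ci][a, b] = sigmas[ci][b, a] = val
        return sigmas

    def _sigmas_to_theta(self, sigmas: list[np.ndarray]) -> np.ndarray:
        return np.array([sigmas[ci][a, b] for ci, a, b in self._params])

    # -- main loop ------------------------------------------------------------

    def fit(self) -> REMLResult:
        sigmas = []
        for term in self.terms:
            bent, _ = bend_psd(term.start.copy())
            sigmas.append(bent)
        state = self._factorize(sigmas)
        if state is None:
            raise LinearAlgebraError("covariance matrix not positive definite at starting values")
        history = [state["loglik"]]
        converged = False
        plateau = 0  # consecutive iterations with sub-tolerance loglik change
        it = 0
        for it in range(1, self.max_iter + 1):
            stats = self._term_stats(state)
            theta_old = self._sigmas_to_theta(sigmas)
            accepted = None
            if self.method == "ai" and it > self.n_em_burnin:
                accepted = self._try_ai(sigmas, state, stats)
            if accepted is None:
                new_sigmas = self._em_step(sigmas, stats)
                new_state = self._factorize(new_sigmas)
                if new_state is None or new_state["loglik"] < state["loglik"] - 1e-8:
                    # EM cannot decrease the likelihood; failure here means V
                    # lost positive definiteness numerically — stop flagged.
                    logger.warning("EM step failed to improve the restricted likelihood; stopping")
                    break
                accepted = (new_sigmas, new_state)
                if self.method == "ai" and it > self.n_em_burnin:
                    # EM crawls along a PSD boundary; amplify the EM step as
                    # far as the restricted likelihood keeps improving
                    accepted = self._extrapolate_em(sigmas, new_sigmas, accepted)
            sigmas_new, state_new = accepted
            delta_ll = state_new["loglik"] - state["loglik"]
            theta_new = self._sigmas_to_theta(sigmas_new)
            rel_change = np.max(
                np.abs(theta_new - theta_old) / np.maximum(np.abs(theta_old), 1e-8 * self._scale)
            )
            sigmas, state = sigmas_new, state_new
            history.append(state["loglik"])
            plateau = plateau + 1 if abs(delta_ll) < self.tol_loglik else 0
            if plateau >= 1 and rel_change < self.tol_param:
                converged = True
                break
            # boundary estimates creep in parameter space long after the
            # likelihood has flattened; a sustained plateau is convergence
            if plateau >= 5:
                converged = True
                break
        if not converged:
            logger.warning("REML did not converge in %d iterations", it)
        return self._result(sigmas, state, history, converged, it)

    def _extrapolate_em(self, sigmas, em_sigmas, accepted):
        """Extend the EM step θ + α(EM(θ) − θ), keeping the best improving α."""
        best_sigmas, best_state = accepted
        for alpha in (32.0, 16.0, 8.0, 4.0, 2.0):
            cand = []
            for cur, em in zip(sigmas, em_sigmas):
                bent, did = bend_psd(cur + alpha * (em - cur))
                self.n_bendings += int(did)
                cand.append(bent)
            cand_state = self._factorize(cand)
            if cand_state is not None and cand_state["loglik"] > best_state["loglik"]:
                return cand, cand_state
        return best_sigmas, best_state

    def _try_ai(self, sigmas, state, stats):
        """AI step with step halving; None if no improving step was found."""
        score, ai = self._score_and_ai(sigmas, state, stats)
        theta = self._sigmas_to_theta(sigmas)
        damping = np.diag(np.maximum(np.diag(ai), 1e-12))
        # undamped Newton first; escalating Levenberg damping keeps making
        # interior progress when a boundary direction blocks the full step
        for lam in (0.0, 1e-2, 1e-1, 1.0, 10.0):
            try:
                delta = np.linalg.solve(ai + lam * damping + 1e-10 * np.eye(len(theta)), score)
            except np.linalg.LinAlgError:
                delta = np.linalg.pinv(ai) @ score
            cand = self._theta_to_sigmas(theta + delta)
            bent_cand = []
            for c in cand:
                bent, did = bend_psd(c)
                self.n_bendings += int(did)
                bent_cand.append(bent)
            cand_state = self._factorize(bent_cand)
            if cand_state is not None and cand_state["loglik"] >= state["loglik"]:
                return bent_cand, cand_state
        return None

    def _result(self, sigmas, state, history, converged, n_iter) -> REMLResult:
        blups = {}
        for term, sigma in zip(self.terms, sigmas):
            g = (term.Z.T @ state["py"]).reshape(term.dim, term.q)
            if term.K is None:
                u = sigma @ g
            else:
                u = sigma @ (g @ term.K.T)
            blups[term.name] = u.T  # q × dim
        xvy = self.X.T @ (state["vinv"] @ self.y)
        beta = state["m_inv"] @ xvy
        param_se = None
        try:
            stats = self._term_stats(state)
            _, ai = self._score_and_ai(sigmas, state, stats)
            cov = np.linalg.pinv(ai)
            se_flat = np.sqrt(np.maximum(np.diag(cov), 0.0))
            param_se = {}
            for se, (ci, a, b) in zip(se_flat, self._params):
                param_se.setdefault(self.terms[ci].name, np.zeros_like(sigmas[ci]))
                param_se[self.terms[ci].name][a, b] = se
                param_se[self.terms[ci].name][b, a] = se
        except Exception:  # SE failure must not void a fit
            param_se = None
        return REMLResult(
            sigmas={t.name: s for t, s in zip(self.terms, sigmas)},
            loglik=state["loglik"],
            loglik_history=history,
            converged=converged,
            n_iter=n_iter,
            beta=beta,
            beta_cov=state["m_inv"],
            blups=blups,
            param_se=param_se,
            n_bendings=self.n_bendings,
        )

    def evaluate(self, sigmas: list[np.ndarray]) -> REMLResult:
        """Restricted log-likelihood and BLUP solutions at *fixed* components."""
        state = self._factorize(sigmas)
        if state is None:
            raise LinearAlgebraError("covariance matrix not positive definite")
        return self._result([np.atleast_2d(np.asarray(s, float)) for s in sigmas], state, [state["loglik"]], True, 0)
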