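"""Latent class mixed models (LCMM) for longitudinal growth z-scores.

A K-class LCMM is a finite mixture of linear mixed models with an
intercept-only multinomial class-membership submodel.  For subject i
with observation stack Y_i (one growth response, or two responses
modelled jointly with shared class membership), the marginal
likelihood contribution is

    L_i = sum_g pi_g N(Y_i; X_i beta_g, Z_i B Z_i' + sigma^2 I)

with pi = softmax(xi), class-specific broken-stick fixed effects
beta_g, subject-level random effects (intercept, or intercept +
age slope) with covariance B = L L' shared across classes (optionally
scaled per class by a proportional factor omega_g), and i.i.d.
residual noise.  In the joint bivariate model each response carries
its own latent structure (basis, random effects, residual variance)
and responses are conditionally independent given the class.

Estimation is maximum likelihood: an EM warm-up with monotone
log-likelihood, followed by quasi-Newton (L-BFGS-B) refinement of all
parameters, taken over multiple perturbed restarts seeded from the
single-class fit.  Fitted classes are reported sorted by descending
estimated class probability so labelings are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize
from scipy.special import logsumexp

from lcgrowth.basis import DEFAULT_KNOTS, SplineSpec, broken_stick_basis

LOG2PI = float(np.log(2.0 * np.pi))
SIGMA_FLOOR = 1e-4
CHOL_DIAG_FLOOR = 1e-6


class EstimationError(RuntimeError):
    """Non-finite density or singular covariance during estimation."""


# ---------------------------------------------------------------------------
# Specs and parameters
# ---------------------------------------------------------------------------


@dataclass
class MixtureSpec:
    """Specification of one latent class mixed model.

    ``responses`` holds one name (univariate) or two (joint bivariate
    with shared class membership).  ``spline`` maps each response to
    its broken-stick :class:`SplineSpec` (defaults to the packaged
    per-response knots).  ``link`` is 'identity' (default: the
    responses are already z-scores), 'linear' (estimated location and
    scale with latent residual variance fixed at 1), or
    'cubic_spline3' (monotone cubic spline transform with three
    equally spaced interior knots, latent residual variance fixed
    at 1).
    """

    responses: tuple
    K: int
    spline: dict = None
    random_effects: str = "intercept+slope"
    re_class_variance: str = "shared"
    link: dict = None

    def __post_init__(self) -> None:
        self.responses = tuple(self.responses)
        if not 1 <= len(self.responses) <= 2:
            raise ValueError("1 or 2 responses supported")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.random_effects not in ("intercept", "intercept+slope"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if self.re_class_variance not in ("shared", "proportional"):
            raise ValueError(f"unknown re_class_variance {self.re_class_variance!r}")
        spline = dict(self.spline or {})
        for r in self.responses:
            if r not in spline:
                spline[r] = SplineSpec(DEFAULT_KNOTS.get(r, (0.25, 0.75, 1.5, 2.5)))
        self.spline = spline
        link = dict(self.link or {})
        for r in self.responses:
            link.setdefault(r, "identity")
            if link[r] not in ("identity", "linear", "cubic_spline3"):
                raise ValueError(f"unknown link {link[r]!r}")
        self.link = link

    @property
    def q(self) -> int:
        return 2 if self.random_effects == "intercept+slope" else 1

    def basis_dim(self, response: str) -> int:
        return self.spline[response].dim

    def n_link_params(self, response: str) -> int:
        kind = self.link[response]
        if kind == "identity":
            return 0
        if kind == "linear":
            return 2
        return 1 + _N_SPLINE_LINK  # eta0 + positive spline weights

    @property
    def n_params(self) -> int:
        q = self.q
        n = self.K - 1
        for r in self.responses:
            n += self.K * self.basis_dim(r)
            n += q * (q + 1) // 2
            n += 1 if self.link[r] == "identity" else self.n_link_params(r)
        if self.re_class_variance == "proportional":
            n += self.K - 1
        return n

    def to_dict(self) -> dict:
        return {
            "responses": list(self.responses),
            "K": self.K,
            "spline": {r: list(s.knots) for r, s in self.spline.items()},
            "random_effects": self.random_effects,
            "re_class_variance": self.re_class_variance,
            "link": dict(self.link),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(
            responses=tuple(d["responses"]),
            K=int(d["K"]),
            spline={r: SplineSpec(tuple(k)) for r, k in d["spline"].items()},
            random_effects=d["random_effects"],
            re_class_variance=d["re_class_variance"],
            link=dict(d["link"]),
        )


_N_SPLINE_LINK = 6  # quadratic B-spline basis size with 3 interior knots


@dataclass
class ParameterSet:
    """All free parameters of a :class:`MixtureSpec` model.

    xi are class-membership logits (last class is the reference);
    beta maps response -> (K, p) fixed-effect rows on the spline
    basis; re_chol maps response -> lower-triangular Cholesky factor
    of the random-effect covariance; sigma maps response -> residual
    SD (fixed at 1 for non-identity links); omega holds per-class
    proportional random-effect scales (all ones when shared, the
    reference class fixed at 1); link_params maps response -> link
    coefficient vector or None.
    """

    xi: np.ndarray
    beta: dict
    re_chol: dict
    sigma: dict
    omega: np.ndarray
    link_params: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.xi) + 1

    @property
    def pi(self) -> np.ndarray:
        logits = np.append(self.xi, 0.0)
        logits -= logits.max()
        w = np.exp(logits)
        return w / w.sum()

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            xi=self.xi.copy(),
            beta={r: b.copy() for r, b in self.beta.items()},
            re_chol={r: c.copy() for r, c in self.re_chol.items()},
            sigma=dict(self.sigma),
            omega=self.omega.copy(),
            link_params={r: (None if v is None else np.asarray(v).copy()) for r, v in self.link_params.items()},
        )

    def permuted(self, order) -> "ParameterSet":
        """Relabel classes by ``order`` (new class g = old class order[g])."""
        order = np.asarray(order)
        pi = self.pi[order]
        xi = np.log(pi[:-1] / pi[-1])
        return ParameterSet(
            xi=xi,
            beta={r: b[order] for r, b in self.beta.items()},
            re_chol={r: c.copy() for r, c in self.re_chol.items()},
            sigma=dict(self.sigma),
            omega=self.omega[order],
            link_params={r: (None if v is None else np.asarray(v).copy()) for r, v in self.link_params.items()},
        )

    def to_dict(self) -> dict:
        return {
            "xi": self.xi.tolist(),
            "beta": {r: b.tolist() for r, b in self.beta.items()},
            "re_chol": {r: c.tolist() for r, c in self.re_chol.items()},
            "sigma": {r: float(s) for r, s in self.sigma.items()},
            "omega": self.omega.tolist(),
            "link_params": {r: (None if v is None else np.asarray(v).tolist()) for r, v in self.link_params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            xi=np.asarray(d["xi"], dtype=float),
            beta={r: np.asarray(b, dtype=float) for r, b in d["beta"].items()},
            re_chol={r: np.asarray(c, dtype=float) for r, c in d["re_chol"].items()},
            sigma={r: float(s) for r, s in d["sigma"].items()},
            omega=np.asarray(d["omega"], dtype=float),
            link_params={r: (None if v is None else np.asarray(v, dtype=float)) for r, v in d.get("link_params", {}).items()},
        )


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


class _PatBlock:
    """Subjects sharing one observation-age pattern for one response."""

    __slots__ = ("ages", "subj_idx", "Y", "X", "Z", "n")

    def __init__(self, ages, subj_idx, Y):
        self.ages = ages
        self.subj_idx = subj_idx
        self.Y = Y
        self.n = len(ages)
        self.X = None
        self.Z = None


class GrowthData:
    """Long-format standardized observations grouped for fast likelihoods.

    Subjects are ordered by sorted subject id; within each response,
    subjects sharing the same visit-age pattern are blocked together
    so covariance factorizations are computed once per pattern.
    """

    def __init__(self, subjects, groups, n_obs):
        self.subjects = np.asarray(subjects)
        self._groups = groups  # response -> list[_PatBlock]
        self.n_obs = n_obs  # response -> int

    @classmethod
    def from_panel(cls, zpanel: pd.DataFrame, responses) -> "GrowthData":
        responses = tuple(responses)
        df = zpanel[zpanel["response"].isin(responses)]
        subjects = np.array(sorted(df["subject_id"].unique(), key=str))
        sidx = {s: i for i, s in enumerate(subjects)}
        groups: dict[str, list[_PatBlock]] = {}
        n_obs: dict[str, int] = {}
        for r in responses:
            sub = df[df["response"] == r].sort_values(["subject_id", "age_years"], kind="mergesort")
            n_obs[r] = len(sub)
            patterns: dict[tuple, list] = {}
            for sid, grp in sub.groupby("subject_id", sort=False):
                ages = grp["age_years"].to_numpy(dtype=float)
                key = tuple(np.round(ages, 9))
                patterns.setdefault(key, []).append((sidx[sid], grp["z"].to_numpy(dtype=float)))
            blocks = []
            for key in sorted(patterns):
                members = patterns[key]
                idx = np.array([m[0] for m in members], dtype=int)
                Y = np.vstack([m[1] for m in members])
                blocks.append(_PatBlock(np.asarray(key, dtype=float), idx, Y))
            groups[r] = blocks
        return cls(subjects, groups, n_obs)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def responses(self):
        return tuple(self._groups)

    def blocks(self, response: str):
        return self._groups[response]

    def subjects_with(self, response: str) -> int:
        return sum(len(b.subj_idx) for b in self._groups[response])

    def subset(self, subject_ids) -> "GrowthData":
        keep = set(subject_ids)
        subjects = np.array([s for s in self.subjects if s in keep])
        old_to_new = {}
        for new, s in enumerate(subjects):
            old_to_new[s] = new
        pos = {s: i for i, s in enumerate(self.subjects)}
        groups = {}
        n_obs = {}
        for r, blocks in self._groups.items():
            new_blocks = []
            total = 0
            for b in blocks:
                mask = np.array([self.subjects[i] in keep for i in b.subj_idx])
                if not mask.any():
                    continue
                idx = np.array([old_to_new[self.subjects[i]] for i in b.subj_idx[mask]], dtype=int)
                nb = _PatBlock(b.ages, idx, b.Y[mask])
                total += nb.Y.size
                new_blocks.append(nb)
            groups[r] = new_blocks
            n_obs[r] = total
        return GrowthData(subjects, groups, n_obs)

    def stacked(self, response: str):
        """(ages, values, subject index) stacked over all blocks of a response."""
        blocks = self._groups[response]
        ages = np.concatenate([np.tile(b.ages, len(b.subj_idx)) for b in blocks])
        vals = np.concatenate([b.Y.ravel() for b in blocks])
        idx = np.concatenate([np.repeat(b.subj_idx, b.n) for b in blocks])
        return ages, vals, idx


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------


class _Link:
    """Transform observed values to the latent scale, with log-Jacobian."""

    def __init__(self, kind: str, y_range):
        self.kind = kind
        self.lo, self.hi = y_range
        if kind == "cubic_spline3":
            from scipy.interpolate import BSpline

            lo, hi = self.lo, self.hi
            interior = np.linspace(lo, hi, 5)[1:-1]  # 3 equally spaced interior knots
            t = np.r_[[lo] * 3, interior, [hi] * 3]
            self._bases = []
            for k in range(_N_SPLINE_LINK):
                c = np.zeros(_N_SPLINE_LINK)
                c[k] = 1.0
                b = BSpline(t, c, 2, extrapolate=False)
                self._bases.append((b, b.antiderivative()))

    def n_params(self) -> int:
        return {"identity": 0, "linear": 2, "cubic_spline3": 1 + _N_SPLINE_LINK}[self.kind]

    def init_params(self):
        if self.kind == "identity":
            return None
        if self.kind == "linear":
            return np.array([0.0, 0.0])  # eta0, log eta1
        return np.r_[self.lo, np.zeros(_N_SPLINE_LINK)]  # identity map at init

    def transform(self, y: np.ndarray, params):
        """Return (latent values, elementwise log-Jacobian)."""
        if self.kind == "identity":
            return y, 0.0
        if self.kind == "linear":
            eta0, log_eta1 = params
            eta1 = np.exp(log_eta1)
            return eta0 + eta1 * y, np.full_like(y, log_eta1)
        eta0, alphas = params[0], np.exp(params[1:])
        yc = np.clip(y, self.lo, self.hi)
        lam = np.full_like(yc, eta0)
        deriv = np.zeros_like(yc)
        for a, (b, ib) in zip(alphas, self._bases):
            lam += a * np.nan_to_num(ib(yc))
            deriv += a * np.nan_to_num(b(yc))
        return lam, np.log(np.maximum(deriv, 1e-300))

    def inverse(self, lam: np.ndarray, params):
        if self.kind == "identity":
            return lam
        if self.kind == "linear":
            eta0, log_eta1 = params
            return (lam - eta0) / np.exp(log_eta1)
        grid = np.linspace(self.lo, self.hi, 2001)
        lam_grid, _ = self.transform(grid, params)
        return np.interp(lam, lam_grid, grid)


# ---------------------------------------------------------------------------
# Objective: marginal log-likelihood, posteriors, analytic gradient
# ---------------------------------------------------------------------------


class _Objective:
    def __init__(self, data: GrowthData, spec: MixtureSpec):
        self.data = data
        self.spec = spec
        self.N = data.n_subjects
        q = spec.q
        for r in spec.responses:
            for b in data.blocks(r):
                b.X = broken_stick_basis(b.ages, spec.spline[r])
                b.Z = np.column_stack([np.ones(b.n), b.ages])[:, :q]
        self.links = {}
        for r in spec.responses:
            _, vals, _ = data.stacked(r)
            rng = (float(vals.min()), float(vals.max())) if len(vals) else (0.0, 1.0)
            self.links[r] = _Link(spec.link[r], rng)

    # -- density ------------------------------------------------------------

    def _sigmas(self, params, r):
        """Per-class covariance Cholesky factors for one pattern: callable."""
        L = params.re_chol[r]
        B = L @ L.T
        s2 = params.sigma[r] ** 2
        omega = params.omega

        def factory(block):
            if np.allclose(omega, omega[0]):
                Sigma = (omega[0] ** 2) * (block.Z @ B @ block.Z.T) + s2 * np.eye(block.n)
                return [_chol(Sigma)] * params.K, True
            out = []
            for g in range(params.K):
                Sigma = (omega[g] ** 2) * (block.Z @ B @ block.Z.T) + s2 * np.eye(block.n)
                out.append(_chol(Sigma))
            return out, False

        return factory

    def logphi(self, params: ParameterSet, cache: dict | None = None) -> np.ndarray:
        """(N, K) within-class log densities summed over responses."""
        K = params.K
        out = np.zeros((self.N, K))
        for r in self.spec.responses:
            link = self.links[r]
            lpar = params.link_params.get(r)
            factory = self._sigmas(params, r)
            for bi, block in enumerate(self.data.blocks(r)):
                lam, logjac = (block.Y, 0.0) if link.kind == "identity" else link.transform(block.Y, lpar)
                means = block.X @ params.beta[r].T  # (n, K)
                R = lam[:, None, :] - means.T[None, :, :]  # (m, K, n)
                chols, shared = factory(block)
                if shared:
                    cf, logdet = chols[0]
                    S = _cho_solve_tensor(cf, R)
                    quad = np.einsum("mkn,mkn->mk", R, S)
                    lp = -0.5 * (block.n * LOG2PI + logdet + quad)
                else:
                    lp = np.empty((len(block.subj_idx), K))
                    S = np.empty_like(R)
                    for g in range(K):
                        cf, logdet = chols[g]
                        S[:, g, :] = cho_solve(cf, R[:, g, :].T).T
                        quad = np.einsum("mn,mn->m", R[:, g, :], S[:, g, :])
                        lp[:, g] = -0.5 * (block.n * LOG2PI + logdet + quad)
                if link.kind != "identity":
                    lp = lp + np.sum(logjac, axis=1)[:, None]
                if not np.all(np.isfinite(lp)):
                    raise EstimationError(
                        f"non-finite class density for response {r!r}; parameters: {params.to_dict()}"
                    )
                out[block.subj_idx] += lp
                if cache is not None:
                    cache[(r, bi)] = (R, S, chols[0])
        return out

    def loglik_and_post(self, params: ParameterSet):
        logphi = self.logphi(params)
        logpi = np.log(params.pi)
        joint = logphi + logpi[None, :]
        ll_i = logsumexp(joint, axis=1)
        post = np.exp(joint - ll_i[:, None])
        return float(ll_i.sum()), post

    def loglik(self, params: ParameterSet) -> float:
        return self.loglik_and_post(params)[0]

    # -- analytic gradient (shared RE variance, identity links) -------------

    def has_analytic_grad(self) -> bool:
        return self.spec.re_class_variance == "shared" and all(
            k == "identity" for k in self.spec.link.values()
        )

    def value_and_grad(self, params: ParameterSet):
        cache: dict = {}
        logphi = self.logphi(params, cache)
        pi = params.pi
        joint = logphi + np.log(pi)[None, :]
        ll_i = logsumexp(joint, axis=1)
        post = np.exp(joint - ll_i[:, None])
        ll = float(ll_i.sum())

        K = params.K
        g_xi = post.sum(axis=0)[:-1] - self.N * pi[:-1]
        grads = {"xi": g_xi, "beta": {}, "re_chol": {}, "sigma": {}}
        for r in self.spec.responses:
            L = params.re_chol[r]
            sig = params.sigma[r]
            p = self.spec.basis_dim(r)
            q = self.spec.q
            g_beta = np.zeros((K, p))
            GA = np.zeros((q, q))
            g_sig = 0.0
            for bi, block in enumerate(self.data.blocks(r)):
                R, S, (cf, _) = cache[(r, bi)]
                w = post[block.subj_idx]  # (m, K)
                T = np.einsum("mk,mkn->kn", w, S)
                g_beta += T @ block.X
                Sigma_inv = cho_solve(cf, np.eye(block.n))
                ZS = np.einsum("mkn,nq->mkq", S, block.Z)
                GA += np.einsum("mk,mkq,mkr->qr", w, ZS, ZS)
                wsum = w.sum()
                GA -= wsum * (block.Z.T @ Sigma_inv @ block.Z)
                g_sig += sig * (np.einsum("mk,mkn,mkn->", w, S, S) - wsum * np.trace(Sigma_inv))
            grads["beta"][r] = g_beta
            grads["re_chol"][r] = GA @ L
            grads["sigma"][r] = g_sig
        return ll, grads


def _chol(Sigma):
    try:
        cf = cho_factor(Sigma, lower=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise EstimationError(f"singular or non-finite within-class covariance: {exc}") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return cf, logdet


def _cho_solve_tensor(cf, R):
    m, K, n = R.shape
    flat = R.reshape(m * K, n).T
    return cho_solve(cf, flat).T.reshape(m, K, n)


# ---------------------------------------------------------------------------
# Parameter vector packing
# ---------------------------------------------------------------------------


def _pack(params: ParameterSet, spec: MixtureSpec) -> np.ndarray:
    parts = [params.xi]
    for r in spec.responses:
        parts.append(params.beta[r].ravel())
    q = spec.q
    for r in spec.responses:
        L = params.re_chol[r]
        vals = []
        for i in range(q):
            for j in range(i + 1):
                vals.append(np.log(max(L[i, j], CHOL_DIAG_FLOOR)) if i == j else L[i, j])
        parts.append(np.array(vals))
    for r in spec.responses:
        if spec.link[r] == "identity":
            parts.append(np.array([np.log(max(params.sigma[r], SIGMA_FLOOR))]))
        else:
            parts.append(np.asarray(params.link_params[r], dtype=float))
    if spec.re_class_variance == "proportional":
        parts.append(np.log(params.omega[:-1]))
    return np.concatenate(parts)


def _unpack(vec: np.ndarray, spec: MixtureSpec) -> ParameterSet:
    K, q = spec.K, spec.q
    pos = 0

    def take(n):
        nonlocal pos
        out = vec[pos : pos + n]
        pos += n
        return out

    xi = take(K - 1).copy()
    beta = {}
    for r in spec.responses:
        p = spec.basis_dim(r)
        beta[r] = take(K * p).reshape(K, p).copy()
    re_chol = {}
    for r in spec.responses:
        vals = take(q * (q + 1) // 2)
        L = np.zeros((q, q))
        k = 0
        for i in range(q):
            for j in range(i + 1):
                L[i, j] = np.exp(vals[k]) if i == j else vals[k]
                k += 1
        re_chol[r] = L
    sigma = {}
    link_params = {}
    for r in spec.responses:
        if spec.link[r] == "identity":
            sigma[r] = float(np.exp(take(1)[0]))
            link_params[r] = None
        else:
            sigma[r] = 1.0
            link_params[r] = take(spec.n_link_params(r)).copy()
    if spec.re_class_variance == "proportional":
        omega = np.append(np.exp(take(K - 1)), 1.0)
    else:
        omega = np.ones(K)
    return ParameterSet(xi=xi, beta=beta, re_chol=re_chol, sigma=sigma, omega=omega, link_params=link_params)


def _grad_to_vec(grads, params: ParameterSet, spec: MixtureSpec) -> np.ndarray:
    """Chain-rule the structured gradient into packed coordinates."""
    parts = [grads["xi"]]
    for r in spec.responses:
        parts.append(grads["beta"][r].ravel())
    q = spec.q
    for r in spec.responses:
        GL = grads["re_chol"][r]
        L = params.re_chol[r]
        vals = []
        for i in range(q):
            for j in range(i + 1):
                vals.append(GL[i, j] * L[i, j] if i == j else GL[i, j])
        parts.append(np.array(vals))
    for r in spec.responses:
        if spec.link[r] == "identity":
            parts.append(np.array([grads["sigma"][r] * params.sigma[r]]))
        else:  # pragma: no cover - analytic grad only on identity path
            raise AssertionError
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _em_step(params: ParameterSet, obj: _Objective):
    """One generalized EM iteration; returns (new params, loglik at input)."""
    spec = obj.spec
    K = params.K
    ll, post = obj.loglik_and_post(params)

    new = params.copy()
    pi = np.clip(post.mean(axis=0), 1e-10, None)
    pi /= pi.sum()
    new.xi = np.log(pi[:-1] / pi[-1])

    # beta: per-class weighted GLS with the current covariance
    for r in spec.responses:
        link = obj.links[r]
        lpar = params.link_params.get(r)
        factory = obj._sigmas(params, r)
        p = spec.basis_dim(r)
        A = np.zeros((K, p, p))
        bvec = np.zeros((K, p))
        for block in obj.data.blocks(r):
            chols, shared = factory(block)
            w = post[block.subj_idx]  # (m, K)
            lam = block.Y if link.kind == "identity" else link.transform(block.Y, lpar)[0]
            if shared:
                cf, _ = chols[0]
                SinvX = cho_solve(cf, block.X)
                XtSX = block.X.T @ SinvX
                wy = w.T @ lam  # (K, n)
                A += w.sum(axis=0)[:, None, None] * XtSX[None]
                bvec += wy @ SinvX
            else:
                for g in range(K):
                    cf, _ = chols[g]
                    SinvX = cho_solve(cf, block.X)
                    A[g] += w[:, g].sum() * (block.X.T @ SinvX)
                    bvec[g] += (w[:, g] @ lam) @ SinvX
        for g in range(K):
            try:
                new.beta[r][g] = np.linalg.solve(A[g] + 1e-10 * np.eye(p), bvec[g])
            except np.linalg.LinAlgError:
                new.beta[r][g] = np.linalg.lstsq(A[g], bvec[g], rcond=None)[0]

    # variance components: conditional random-effect moments at the new
    # mean parameters (shared-variance path only; the proportional path
    # leaves them to the quasi-Newton refinement)
    if spec.re_class_variance == "shared":
        _, post2 = obj.loglik_and_post(new)
        q = spec.q
        for r in spec.responses:
            link = obj.links[r]
            lpar = new.link_params.get(r)
            L = new.re_chol[r]
            B = L @ L.T
            s2 = new.sigma[r] ** 2
            Bsum = np.zeros((q, q))
            s2num = 0.0
            n_subj = 0
            n_obs = 0
            for block in obj.data.blocks(r):
                Z = block.Z
                Sigma = Z @ B @ Z.T + s2 * np.eye(block.n)
                cf, _ = _chol(Sigma)
                gain = B @ Z.T @ cho_solve(cf, np.eye(block.n))  # (q, n)
                V = B - gain @ Z @ B
                lam = block.Y if link.kind == "identity" else link.transform(block.Y, lpar)[0]
                means = block.X @ new.beta[r].T
                R = lam[:, None, :] - means.T[None, :, :]
                w = post2[block.subj_idx]
                bh = np.einsum("qn,mkn->mkq", gain, R)
                Bsum += np.einsum("mk,mkq,mkr->qr", w, bh, bh) + w.sum() * V
                resid = R - np.einsum("mkq,nq->mkn", bh, Z)
                s2num += np.einsum("mk,mkn,mkn->", w, resid, resid)
                s2num += w.sum() * np.trace(Z @ V @ Z.T)
                n_subj += len(block.subj_idx)
                n_obs += block.Y.size
            Bnew = Bsum / max(n_subj, 1)
            Bnew = 0.5 * (Bnew + Bnew.T) + 1e-10 * np.eye(q)
            new.re_chol[r] = cholesky(Bnew, lower=True)
            new.re_chol[r][np.diag_indices(q)] = np.maximum(np.diag(new.re_chol[r]), CHOL_DIAG_FLOOR)
            if spec.link[r] == "identity":
                new.sigma[r] = float(max(np.sqrt(max(s2num, 0.0) / max(n_obs, 1)), SIGMA_FLOOR))
    return new, ll


def _run_em(params, obj, max_iter, tol):
    """EM until the log-likelihood gain drops below ``tol``.

    Returns (params, loglik at params, last gain, n_iter).
    """
    ll_prev = -np.inf
    gain = np.inf
    for it in range(max_iter):
        new, ll = _em_step(params, obj)
        gain = ll - ll_prev
        if it > 0 and gain < tol:
            return params, ll, gain, it
        params, ll_prev = new, ll
    ll = obj.loglik(params)
    return params, ll, ll - ll_prev, max_iter


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """A fitted latent class mixed model with posteriors and diagnostics."""

    spec: MixtureSpec
    params: ParameterSet
    loglik: float
    n_params: int
    posteriors: np.ndarray  # (N, K)
    allocation: np.ndarray  # MAP class per subject (ties -> lowest index)
    subjects: np.ndarray
    n_subjects: int
    converged: bool
    n_restarts_used: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def posteriors_frame(self) -> pd.DataFrame:
        cols = {f"class_{g + 1}": self.posteriors[:, g] for g in range(self.spec.K)}
        return pd.DataFrame({"subject_id": self.subjects, "allocation": self.allocation + 1, **cols})

    def to_json(self, path=None):
        payload = {
            "spec": self.spec.to_dict(),
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_subjects": self.n_subjects,
            "converged": bool(self.converged),
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "diagnostics": {k: _jsonable(v) for k, v in self.diagnostics.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def marginal_loglik(params: ParameterSet, data: GrowthData, spec: MixtureSpec) -> float:
    """Marginal mixture log-likelihood sum_i log sum_g pi_g N(Y_i; ...)."""
    return _Objective(data, spec).loglik(params)


def posterior_probabilities(params: ParameterSet, data: GrowthData, spec: MixtureSpec) -> np.ndarray:
    """Posterior class-membership probabilities, log-sum-exp stabilized."""
    return _Objective(data, spec).loglik_and_post(params)[1]


def _init_single_class(data: GrowthData, spec: MixtureSpec) -> ParameterSet:
    beta = {}
    re_chol = {}
    sigma = {}
    link_params = {}
    q = spec.q
    for r in spec.responses:
        ages, vals, _ = data.stacked(r)
        X = broken_stick_basis(ages, spec.spline[r])
        coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
        resid_sd = float(np.std(vals - X @ coef)) or 0.5
        beta[r] = np.tile(coef, (spec.K, 1))
        L = np.zeros((q, q))
        L[0, 0] = max(0.5 * resid_sd, 0.05)
        if q == 2:
            L[1, 1] = max(0.1 * resid_sd, 0.02)
        re_chol[r] = L
        sigma[r] = max(0.7 * resid_sd, 0.05) if spec.link[r] == "identity" else 1.0
        if spec.link[r] == "identity":
            link_params[r] = None
        else:
            link = _Link(spec.link[r], (float(vals.min()), float(vals.max())))
            link_params[r] = link.init_params()
    return ParameterSet(
        xi=np.zeros(spec.K - 1),
        beta=beta,
        re_chol=re_chol,
        sigma=sigma,
        omega=np.ones(spec.K),
        link_params=link_params,
    )


def _quantile_init(base: ParameterSet, data: GrowthData, spec: MixtureSpec) -> ParameterSet:
    """Deterministic start: split subjects into K groups by mean level.

    Subjects are ranked by their average observed value on the first
    response and split into K equal groups; each group's pooled OLS
    coefficients initialize that class.  A strong, classic start for
    trajectory mixtures.
    """
    cand = base.copy()
    r0 = spec.responses[0]
    ages, vals, idx = data.stacked(r0)
    means = np.full(data.n_subjects, np.nan)
    sums = np.bincount(idx, weights=vals, minlength=data.n_subjects)
    cnts = np.bincount(idx, minlength=data.n_subjects)
    seen = cnts > 0
    means[seen] = sums[seen] / cnts[seen]
    order = np.argsort(means)
    groups = np.array_split(order[seen[order]], spec.K)
    for r in spec.responses:
        ages_r, vals_r, idx_r = data.stacked(r)
        X = broken_stick_basis(ages_r, spec.spline[r])
        for g, members in enumerate(groups):
            mask = np.isin(idx_r, members)
            if mask.sum() >= spec.basis_dim(r):
                cand.beta[r][g] = np.linalg.lstsq(X[mask], vals_r[mask], rcond=None)[0]
    return cand


def _refine(params, obj, spec, maxiter=300):
    """Quasi-Newton (L-BFGS-B) refinement of all parameters."""
    x0 = _pack(params, spec)
    analytic = obj.has_analytic_grad()

    if analytic:

        def fun(x):
            p = _unpack(x, spec)
            try:
                ll, grads = obj.value_and_grad(p)
            except EstimationError:
                return 1e12, np.zeros_like(x)
            return -ll, -_grad_to_vec(grads, p, spec)

        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 5 * maxiter, "ftol": 1e-14, "gtol": 1e-7},
        )
    else:

        def fun(x):
            try:
                return -obj.loglik(_unpack(x, spec))
            except EstimationError:
                return 1e12

        res = minimize(fun, x0, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-11})
    best = _unpack(res.x, spec)
    ll = -res.fun if np.isfinite(res.fun) and res.fun < 1e11 else obj.loglik(best)
    ll0 = obj.loglik(params)
    if ll < ll0:  # never accept a refinement that lost ground
        return params, ll0
    return best, float(ll)


def _grad_max_norm(params, obj, spec) -> float:
    if obj.has_analytic_grad():
        _, grads = obj.value_and_grad(params)
        return float(np.max(np.abs(_grad_to_vec(grads, params, spec))))
    x0 = _pack(params, spec)
    g = np.zeros_like(x0)
    for k in range(len(x0)):
        h = 1e-5 * (1.0 + abs(x0[k]))
        xp, xm = x0.copy(), x0.copy()
        xp[k] += h
        xm[k] -= h
        g[k] = (obj.loglik(_unpack(xp, spec)) - obj.loglik(_unpack(xm, spec))) / (2 * h)
    return float(np.max(np.abs(g)))


def fit(
    data: GrowthData,
    spec: MixtureSpec,
    n_restarts: int = 30,
    seed: int = 0,
    em_warm_iters: int = 30,
    em_max_iters: int = 500,
    em_tol: float = 1e-6,
    refine: bool = True,
    grad_tol: float = 1e-4,
) -> MixtureFit:
    """Maximum-likelihood fit of a latent class mixed model.

    A single-class fit initializes multiple restarts whose
    class-specific fixed effects are perturbed with N(0, 0.5^2) noise;
    each restart gets an EM warm-up, the best is run to EM convergence
    and refined by L-BFGS-B, and a final EM polish both certifies the
    log-likelihood gain below ``em_tol`` and yields the posteriors.
    Classes are reported sorted by descending estimated probability.
    Deterministic given ``seed``.
    """
    if isinstance(data, pd.DataFrame):
        data = GrowthData.from_panel(data, spec.responses)
    obj = _Objective(data, spec)
    rng = np.random.default_rng(seed)

    base = _init_single_class(data, spec)
    if spec.K == 1:
        start, n_used = base, 1
    else:
        k1_spec = MixtureSpec(
            responses=spec.responses,
            K=1,
            spline=spec.spline,
            random_effects=spec.random_effects,
            re_class_variance="shared",
            link=spec.link,
        )
        k1_obj = _Objective(data, k1_spec)
        k1_params, _, _, _ = _run_em(_init_single_class(data, k1_spec), k1_obj, 200, em_tol)
        candidates = []
        base_k = base.copy()
        for r in spec.responses:
            base_k.beta[r] = np.tile(k1_params.beta[r][0], (spec.K, 1))
            # shrink the single-class RE covariance: between-class separation
            # inflates the K=1 intercept variance, and starting EM there makes
            # the random effects absorb the class structure (collapsed optimum)
            base_k.re_chol[r] = k1_params.re_chol[r] / np.sqrt(spec.K)
            base_k.sigma[r] = k1_params.sigma[r]
        candidates.append(_quantile_init(base_k, data, spec))
        for _ in range(max(n_restarts - 1, 0)):
            cand = base.copy()
            for r in spec.responses:
                cand.beta[r] = np.tile(k1_params.beta[r][0], (spec.K, 1)) + rng.normal(0.0, 0.5, size=cand.beta[r].shape)
                cand.re_chol[r] = k1_params.re_chol[r].copy()
                cand.sigma[r] = k1_params.sigma[r]
            candidates.append(cand)
        best_ll, start, n_used = -np.inf, None, 0
        for cand in candidates:
            try:
                warmed, ll, _, _ = _run_em(cand, obj, em_warm_iters, em_tol)
            except EstimationError:
                continue
            n_used += 1
            if ll > best_ll:
                best_ll, start = ll, warmed
        if start is None:
            return MixtureFit(
                spec=spec, params=base, loglik=float("nan"), n_params=spec.n_params,
                posteriors=np.full((data.n_subjects, spec.K), np.nan),
                allocation=np.zeros(data.n_subjects, dtype=int), subjects=data.subjects,
                n_subjects=data.n_subjects, converged=False, n_restarts_used=0, seed=seed,
                diagnostics={"failure": "all restarts raised estimation errors"},
            )

    params, ll, gain, _ = _run_em(start, obj, em_max_iters, em_tol)
    # alternate quasi-Newton refinement with an EM polish: the polish both
    # certifies the remaining likelihood gain and never loses ground
    for _round in range(5 if refine else 1):
        if refine:
            params, ll = _refine(params, obj, spec, maxiter=500)
        params, ll, gain, _ = _run_em(params, obj, 50, em_tol)
        if not refine or _grad_max_norm(params, obj, spec) < grad_tol:
            break

    ll_final, post = obj.loglik_and_post(params)
    order = np.argsort(-params.pi, kind="stable")
    params = params.permuted(order)
    post = post[:, order]
    allocation = np.argmax(post, axis=1)

    grad_norm = _grad_max_norm(params, obj, spec)
    converged = bool(grad_norm < grad_tol and abs(gain) < em_tol)
    pi_hat = params.pi
    diagnostics = {
        "grad_max_norm": grad_norm,
        "final_em_gain": float(gain),
        "class_proportions": pi_hat,
        "empty_class": bool(np.any(pi_hat < 1.0 / max(data.n_subjects, 1))),
        "link_ranges": {r: [obj.links[r].lo, obj.links[r].hi] for r in spec.responses},
    }
    return MixtureFit(
        spec=spec,
        params=params,
        loglik=float(ll_final),
        n_params=spec.n_params,
        posteriors=post,
        allocation=allocation,
        subjects=data.subjects,
        n_subjects=data.n_subjects,
        converged=converged,
        n_restarts_used=(1 if spec.K == 1 else n_used),
        seed=seed,
        diagnostics=diagnostics,
    )


def class_mean_trajectories(fit_result: MixtureFit, age_grid) -> dict:
    """Per-class mean curves on an age grid, per response.

    Returns response -> (K, len(grid)) array.  For non-identity links
    the latent mean curve is mapped back to the observed scale.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    spec = fit_result.spec
    out = {}
    for r in spec.responses:
        X = broken_stick_basis(age_grid, spec.spline[r])
        curves = fit_result.params.beta[r] @ X.T
        if spec.link[r] != "identity":
            lo, hi = fit_result.diagnostics["link_ranges"][r]
            link = _Link(spec.link[r], (float(lo), float(hi)))
            curves = link.inverse(curves, fit_result.params.link_params[r])
        out[r] = curves
    return out
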