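"""Single-trait animal model and REML variance-component estimation.

The model is

    y = X b + sum_k Z_k u_k + e,      u_k ~ N(0, sigma2_k G_k),  e ~ N(0, sigma2_R I)

where one random term may be *additive* (G_k = A, the numerator relationship
matrix from the pedigree; its solutions are estimated breeding values) and any
number of identity-structured terms model family/common-environment or
permanent-environment variance.

Estimation maximises the restricted log-likelihood

    lR = -1/2 [ log|V| + log|X' V^-1 X| + y' P y + (n - p) log 2*pi ]

over non-negative variance components by average-information (AI) updates with
EM-REML fallback steps whenever the AI step leaves the parameter space or
decreases lR.  Components driven to the boundary are pinned at exactly zero and
flagged.  Models with a single non-residual component use a spectral
reparameterisation (one symmetric eigendecomposition, then O(n p^2) per
iteration); general models use dense V algebra, which is adequate for the few
hundred to few thousand observations this design produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps

from .pedigree import Pedigree, RelationshipMatrix, additive_relationship

__all__ = [
    "RandomTerm",
    "MixedModelSpec",
    "DesignBundle",
    "VarianceComponents",
    "ModelFit",
    "RemlOptions",
    "build_design",
    "reml_fit",
    "loglik_ratio_test",
    "wald_f",
    "extract_breeding_values",
    "LikelihoodRatioTest",
    "WaldFTest",
]

LOG2PI = float(np.log(2.0 * np.pi))


class ModelSpecError(ValueError):
    """Invalid model specification or data/spec mismatch."""


class ConvergenceError(RuntimeError):
    """REML failed to converge within the iteration cap."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass(frozen=True)
class RandomTerm:
    """One random effect.

    ``structure`` is ``"additive"`` (covariance proportional to the pedigree
    A matrix; ``column`` holds animal ids) or ``"identity"``.  ``role`` labels
    the biological meaning used by downstream parameter summaries:
    ``additive``, ``common_env`` (maternal/family), ``permanent_env``, or
    ``other``.
    """

    name: str
    column: str
    structure: str = "identity"
    role: str | None = None

    def resolved_role(self) -> str:
        if self.structure == "additive":
            return "additive"
        return self.role or "other"


@dataclass(frozen=True)
class MixedModelSpec:
    """Declarative model: response, fixed part, random part, pedigree.

    Fixed factors may use the nesting syntax ``"inner(outer)"`` — e.g.
    ``"order(year)"`` fits sampling order nested within measurement year.
    An intercept is always included.
    """

    response: str
    fixed_factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    random_terms: tuple[RandomTerm, ...] = ()
    pedigree: Pedigree | None = None

    def __post_init__(self):
        object.__setattr__(self, "fixed_factors", tuple(self.fixed_factors))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "random_terms", tuple(self.random_terms))
        additive = [t for t in self.random_terms if t.structure == "additive"]
        if len(additive) > 1:
            raise ModelSpecError("at most one additive (A-structured) random term")
        if additive and self.pedigree is None:
            raise ModelSpecError("additive random term requires a pedigree")
        names = [t.name for t in self.random_terms]
        if len(set(names)) != len(names):
            raise ModelSpecError("random term names must be unique")

    @property
    def additive_term(self) -> RandomTerm | None:
        for t in self.random_terms:
            if t.structure == "additive":
                return t
        return None

    def drop_random(self, name: str) -> "MixedModelSpec":
        """Spec with one random term removed (for likelihood-ratio testing)."""
        kept = tuple(t for t in self.random_terms if t.name != name)
        if len(kept) == len(self.random_terms):
            raise ModelSpecError(f"no random term named {name!r}")
        return replace(self, random_terms=kept)


@dataclass
class DesignBundle:
    """Design matrices ready for the REML engine."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    term_columns: dict[str, list[int]]  # fixed term -> column indices in X
    pruned_columns: list[str]
    Z: dict[str, np.ndarray]  # random term -> indicator matrix (n x q)
    levels: dict[str, list[str]]  # random term -> level labels
    G: dict[str, RelationshipMatrix | None]  # additive term -> A; identity -> None
    M: dict[str, np.ndarray]  # random term -> Z G Z' (n x n)
    n_dropped: int
    notes: list[str]

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def rank_X(self) -> int:
        return self.X.shape[1]


def _parse_fixed_term(term: str) -> tuple[str, str | None]:
    term = term.strip()
    if term.endswith(")") and "(" in term:
        inner, outer = term[:-1].split("(", 1)
        return inner.strip(), outer.strip()
    return term, None


def _factor_codes(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(series.astype(str).unique())
    lut = {lv: i for i, lv in enumerate(levels)}
    return series.astype(str).map(lut).to_numpy(), levels


def build_design(spec: MixedModelSpec, phenotypes: pd.DataFrame) -> DesignBundle:
    """Assemble y, a full-rank X, and one indicator Z per random term.

    Rows with missing response, factor or covariate values are dropped and
    counted.  Factor dummies are generated per level (per cell for nested
    terms) and pruned to a full-rank X by a sequential orthogonalisation that
    keeps the first estimable columns; pruned column names are reported.
    """
    notes: list[str] = []
    needed = [spec.response] + list(spec.covariates)
    for term in spec.fixed_factors:
        inner, outer = _parse_fixed_term(term)
        needed.append(inner)
        if outer:
            needed.append(outer)
    for rt in spec.random_terms:
        needed.append(rt.column)
    for col in dict.fromkeys(needed):
        if col not in phenotypes.columns:
            raise ModelSpecError(f"column {col!r} missing from phenotype table")

    df = phenotypes.copy()
    n0 = len(df)
    df = df.dropna(subset=list(dict.fromkeys(needed)))
    n_dropped = n0 - len(df)
    if n_dropped:
        notes.append(f"dropped {n_dropped} rows with missing values")
    if len(df) == 0:
        raise ModelSpecError("no usable rows (all responses or predictors missing)")

    y = df[spec.response].to_numpy(dtype=float)
    n = len(y)

    # --- fixed part: intercept, factors, covariates; prune to full rank ---
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    owners: list[str] = ["Intercept"]

    for term in spec.fixed_factors:
        inner, outer = _parse_fixed_term(term)
        if outer is None:
            codes, levels = _factor_codes(df[inner])
            if len(levels) < 2:
                raise ModelSpecError(f"fixed factor {term!r} has a single level")
            for i, lv in enumerate(levels):
                columns.append((codes == i).astype(float))
                names.append(f"{inner}[{lv}]")
                owners.append(term)
        else:
            cells = sorted(
                set(zip(df[outer].astype(str), df[inner].astype(str)))
            )
            if len(cells) < 2:
                raise ModelSpecError(f"nested factor {term!r} has a single cell")
            pair = list(zip(df[outer].astype(str), df[inner].astype(str)))
            for cell in cells:
                columns.append(
                    np.fromiter((p == cell for p in pair), dtype=float, count=n)
                )
                names.append(f"{inner}({outer})[{cell[0]}:{cell[1]}]")
                owners.append(term)
    for cov in spec.covariates:
        columns.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
        owners.append(cov)

    X_cols: list[np.ndarray] = []
    kept_names: list[str] = []
    kept_owner: list[str] = []
    pruned: list[str] = []
    Q: list[np.ndarray] = []
    for col, nm, ow in zip(columns, names, owners):
        r = col.astype(float)
        for q in Q:
            r = r - (q @ col) * q
        nrm = np.linalg.norm(r)
        if nrm > 1e-8 * max(1.0, np.linalg.norm(col)):
            Q.append(r / nrm)
            X_cols.append(col)
            kept_names.append(nm)
            kept_owner.append(ow)
        else:
            pruned.append(nm)
    X = np.column_stack(X_cols)
    term_columns: dict[str, list[int]] = {}
    for i, ow in enumerate(kept_owner):
        term_columns.setdefault(ow, []).append(i)
    for term in list(spec.fixed_factors) + list(spec.covariates):
        if term not in term_columns:
            raise ModelSpecError(
                f"fixed term {term!r} was aliased out entirely during pruning"
            )
    if pruned:
        notes.append(f"pruned {len(pruned)} redundant fixed-effect columns")

    # --- random part ---
    Z: dict[str, np.ndarray] = {}
    levels_map: dict[str, list[str]] = {}
    G: dict[str, RelationshipMatrix | None] = {}
    M: dict[str, np.ndarray] = {}
    for rt in spec.random_terms:
        vals = df[rt.column].astype(str)
        if rt.structure == "additive":
            ped = spec.pedigree
            missing = sorted(set(vals) - set(ped.animals))
            if missing:
                raise ModelSpecError(
                    "animals absent from pedigree: " + ", ".join(missing[:10])
                )
            lv = list(ped.animals)
            codes = vals.map(ped.index).to_numpy()
            A = additive_relationship(ped)
            G[rt.name] = A
            M[rt.name] = A.values[np.ix_(codes, codes)]
        else:
            codes, lv = _factor_codes(vals)
            G[rt.name] = None
            M[rt.name] = (codes[:, None] == codes[None, :]).astype(float)
        Zk = np.zeros((n, len(lv)))
        Zk[np.arange(n), codes] = 1.0
        Z[rt.name] = Zk
        levels_map[rt.name] = list(lv)

    return DesignBundle(
        y=y,
        X=X,
        x_names=kept_names,
        term_columns=term_columns,
        pruned_columns=pruned,
        Z=Z,
        levels=levels_map,
        G=G,
        M=M,
        n_dropped=n_dropped,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# REML kernels: given theta (component vector, residual last), return the
# restricted log-likelihood and, when asked, score / average-information.
# ---------------------------------------------------------------------------


class _SpectralKernel:
    """Exact REML algebra for V = s2_g * M + s2_e * I via one eigh(M)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, M: np.ndarray):
        w, U = np.linalg.eigh(M)
        self.w = np.clip(w, 0.0, None)
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.U = U
        self.n, self.p = X.shape

    def _core(self, theta):
        d = theta[0] * self.w + theta[1]
        if np.min(d) <= 0:
            return None
        dinv = 1.0 / d
        B = self.Xt * dinv[:, None]
        C = self.Xt.T @ B
        sign, ldC = np.linalg.slogdet(C)
        if sign <= 0:
            return None
        Cinv = np.linalg.inv(C)
        Bty = B.T @ self.yt
        Py = self.yt * dinv - B @ (Cinv @ Bty)
        yPy = float(self.yt @ Py)
        ld = float(np.sum(np.log(d)))
        ll = -0.5 * (ld + ldC + yPy + (self.n - self.p) * LOG2PI)
        return d, dinv, B, Cinv, Py, ll

    def loglik(self, theta) -> float:
        core = self._core(theta)
        return -np.inf if core is None else core[-1]

    def quantities(self, theta):
        core = self._core(theta)
        if core is None:
            return None
        d, dinv, B, Cinv, Py, ll = core
        s_diag = np.einsum("ij,ij->i", B @ Cinv, B)
        Pdiag = dinv - s_diag
        trPM = np.array([float(self.w @ Pdiag), float(np.sum(Pdiag))])
        t = [self.w * Py, Py]

        def applyP(v):
            # P v = D^-1 v - D^-1 X C^-1 X' D^-1 v ; B = D^-1 X
            return v * dinv - B @ (Cinv @ (self.Xt.T @ (v * dinv)))

        Pt = [applyP(tk) for tk in t]
        u = np.array([float(Py @ tk) for tk in t])
        score = -0.5 * (trPM - u)
        AI = 0.5 * np.array(
            [[float(t[k] @ Pt[m]) for m in range(2)] for k in range(2)]
        )
        return ll, score, AI, u, trPM

    def project_y(self, theta) -> np.ndarray:
        """P y in the original (unrotated) coordinates."""
        core = self._core(theta)
        d, dinv, B, Cinv, Py, ll = core
        return self.U @ Py


class _DenseKernel:
    """General REML algebra with dense V = sum_k theta_k M_k + theta_R I."""

    def __init__(self, y: np.ndarray, X: np.ndarray, M_list: list[np.ndarray]):
        self.y = y
        self.X = X
        self.M_list = M_list
        self.n, self.p = X.shape

    def _V(self, theta):
        V = np.zeros((self.n, self.n))
        for th, M in zip(theta[:-1], self.M_list):
            if th != 0.0:
                V += th * M
        V[np.diag_indices_from(V)] += theta[-1]
        return V

    def _core(self, theta, need_P: bool):
        try:
            c, low = linalg.cho_factor(self._V(theta), lower=True)
        except linalg.LinAlgError:
            return None
        ldV = 2.0 * float(np.sum(np.log(np.diag(c))))
        ViX = linalg.cho_solve((c, low), self.X)
        Viy = linalg.cho_solve((c, low), self.y)
        C = self.X.T @ ViX
        sign, ldC = np.linalg.slogdet(C)
        if sign <= 0:
            return None
        Cinv = np.linalg.inv(C)
        Py = Viy - ViX @ (Cinv @ (self.X.T @ Viy))
        yPy = float(self.y @ Py)
        ll = -0.5 * (ldV + ldC + yPy + (self.n - self.p) * LOG2PI)
        P = None
        if need_P:
            Vinv = linalg.cho_solve((c, low), np.eye(self.n))
            P = Vinv - ViX @ Cinv @ ViX.T
        return ll, Py, P, ViX, Cinv

    def loglik(self, theta) -> float:
        core = self._core(theta, need_P=False)
        return -np.inf if core is None else core[0]

    def quantities(self, theta):
        core = self._core(theta, need_P=True)
        if core is None:
            return None
        ll, Py, P, ViX, Cinv = core
        K = len(self.M_list)
        t = [M @ Py for M in self.M_list] + [Py]
        trPM = np.array(
            [float(np.sum(P * M)) for M in self.M_list] + [float(np.trace(P))]
        )
        u = np.array([float(Py @ tk) for tk in t])
        score = -0.5 * (trPM - u)
        Pt = [P @ tk for tk in t]
        AI = 0.5 * np.array(
            [
                [float(t[k] @ Pt[m]) for m in range(K + 1)]
                for k in range(K + 1)
            ]
        )
        return ll, score, AI, u, trPM

    def project_y(self, theta) -> np.ndarray:
        core = self._core(theta, need_P=False)
        return core[1]


@dataclass
class RemlOptions:
    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_theta: float = 1e-6
    init: np.ndarray | None = None  # component vector, residual last


@dataclass
class VarianceComponents:
    """Estimated variance components (residual last) with SEs and roles."""

    names: tuple[str, ...]
    estimates: dict[str, float]
    se: dict[str, float]
    boundary: dict[str, bool]
    roles: dict[str, str]
    varcov: np.ndarray

    @property
    def V_P(self) -> float:
        return float(sum(self.estimates.values()))

    def by_role(self, *roles: str) -> float:
        return float(
            sum(v for k, v in self.estimates.items() if self.roles[k] in roles)
        )

    @property
    def V_A(self) -> float:
        return self.by_role("additive")

    @property
    def V_R(self) -> float:
        return self.by_role("residual")

    def as_series(self) -> pd.Series:
        return pd.Series(self.estimates)


@dataclass
class ModelFit:
    """A converged REML fit: components, solutions, and test ingredients."""

    spec: MixedModelSpec
    design: DesignBundle
    components: VarianceComponents
    loglik: float
    blue: pd.DataFrame
    blue_cov: np.ndarray
    theta: np.ndarray
    ai: np.ndarray
    n_obs: int
    rank_X: int
    converged: bool
    n_iter: int
    trajectory: list[float] = field(default_factory=list)
    _kernel: object | None = field(default=None, repr=False)

    def loglik_at(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood at an arbitrary component vector."""
        return self._kernel.loglik(np.asarray(theta, dtype=float))


def _em_step(theta, u, trPM, q, pinned):
    cand = theta.copy()
    for k in range(len(theta)):
        if pinned[k]:
            continue
        cand[k] = theta[k] + theta[k] ** 2 * (u[k] - trPM[k]) / q[k]
    return np.clip(cand, 0.0, None)


def _fit_ols_only(design: DesignBundle) -> tuple[np.ndarray, float, np.ndarray]:
    """Closed-form REML for the residual-only model (no random terms)."""
    y, X = design.y, design.X
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    if n <= p:
        raise ModelSpecError("no residual degrees of freedom")
    s2 = rss / (n - p)
    sign, ldXX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - p) * (np.log(s2) + 1.0 + LOG2PI) + ldXX)
    return beta, s2, np.array([ll])


def reml_fit(
    spec: MixedModelSpec,
    phenotypes: pd.DataFrame,
    options: RemlOptions | None = None,
) -> ModelFit:
    """Fit the mixed model by AI-REML with EM fallback.

    Deterministic given data and options: initialisation is the equal
    partition of the sample phenotypic variance across all components.
    """
    opts = options or RemlOptions()
    design = build_design(spec, phenotypes)
    y, X = design.y, design.X
    n, p = X.shape
    if n <= p:
        raise ModelSpecError("fewer observations than fixed-effect parameters")
    names = [t.name for t in spec.random_terms] + ["residual"]
    roles = {t.name: t.resolved_role() for t in spec.random_terms}
    roles["residual"] = "residual"
    K = len(spec.random_terms)
    scale = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if scale <= 0:
        scale = 1.0

    if K == 0:
        beta, s2, ll = _fit_ols_only(design)
        XtX_inv = np.linalg.inv(X.T @ X)
        blue_cov = s2 * XtX_inv
        comps = VarianceComponents(
            names=("residual",),
            estimates={"residual": s2},
            se={"residual": float(s2 * np.sqrt(2.0 / (n - p)))},
            boundary={"residual": False},
            roles={"residual": "residual"},
            varcov=np.array([[2.0 * s2**2 / (n - p)]]),
        )
        blue = pd.DataFrame(
            {
                "term": design.x_names,
                "estimate": beta,
                "se": np.sqrt(np.diag(blue_cov)),
            }
        )
        kernel = _DenseKernel(y, X, [])
        return ModelFit(
            spec=spec,
            design=design,
            components=comps,
            loglik=float(ll[0]),
            blue=blue,
            blue_cov=blue_cov,
            theta=np.array([s2]),
            ai=np.array([[(n - p) / (2.0 * s2**2)]]),
            n_obs=n,
            rank_X=p,
            converged=True,
            n_iter=0,
            _kernel=kernel,
        )

    M_list = [design.M[t.name] for t in spec.random_terms]
    q = np.array(
        [design.Z[t.name].shape[1] for t in spec.random_terms] + [n], dtype=float
    )
    if K == 1:
        kernel = _SpectralKernel(y, X, M_list[0])
    else:
        kernel = _DenseKernel(y, X, M_list)

    theta = (
        np.asarray(opts.init, dtype=float).copy()
        if opts.init is not None
        else np.full(K + 1, scale / (K + 1))
    )
    if theta.shape != (K + 1,):
        raise ModelSpecError("init must have one entry per component incl. residual")
    theta = np.clip(theta, 0.0, None)
    theta[-1] = max(theta[-1], 1e-8 * scale)

    pinned = np.zeros(K + 1, dtype=bool)
    trajectory: list[float] = []
    converged = False
    it = 0
    ll_prev = -np.inf
    ai_final = np.eye(K + 1)

    for it in range(1, opts.max_iter + 1):
        quant = kernel.quantities(theta)
        if quant is None:
            raise ConvergenceError(
                "V numerically singular at current components", trajectory
            )
        ll, score, AI, u, trPM = quant
        trajectory.append(ll)
        ai_final = AI
        # KKT pinning: a component sitting on the boundary whose gradient
        # points outward stays there (score is evaluated at the boundary).
        for k in range(K):
            if not pinned[k] and theta[k] == 0.0 and score[k] <= 0.0:
                pinned[k] = True
        free = ~pinned

        # AI proposal on the free components, projected onto the boundary;
        # Levenberg-Marquardt damping handles ridges where the raw AI step
        # overshoots (nearly confounded components).
        AI_ff = AI[np.ix_(free, free)]
        diag_ff = np.diag(np.diag(AI_ff))
        accepted = False
        cand = theta
        ll_cand = ll
        for lam in (0.0, 0.1, 1.0, 10.0, 100.0):
            try:
                delta = np.linalg.solve(AI_ff + lam * diag_ff, score[free])
            except np.linalg.LinAlgError:
                continue
            trial = theta.copy()
            trial[free] = theta[free] + delta
            np.clip(trial, 0.0, None, out=trial)
            trial[-1] = max(trial[-1], 1e-10 * scale)
            ll_trial = kernel.loglik(trial)
            if ll_trial >= ll - 1e-10:
                cand, ll_cand, accepted = trial, ll_trial, True
                break
        if not accepted:  # EM-REML fallback, itself damped if needed
            cand = _em_step(theta, u, trPM, q, pinned)
            cand[-1] = max(cand[-1], 1e-12 * scale)
            ll_cand = kernel.loglik(cand)
            half = 0
            while ll_cand < ll - 1e-10 and half < 20:
                cand = 0.5 * (cand + theta)
                ll_cand = kernel.loglik(cand)
                half += 1

        dtheta = np.max(np.abs(cand - theta)) / max(scale, 1e-12)
        dll = abs(ll_cand - ll) / max(1.0, abs(ll))
        theta = cand
        if dll < opts.tol_loglik and dtheta < opts.tol_theta:
            converged = True
            ll = ll_cand
            break
        ll_prev = ll

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {opts.max_iter} iterations", trajectory
        )

    # classify boundary components (estimate pinned at zero, reported clean)
    for k in range(K):
        if theta[k] < 1e-8 * scale:
            theta[k] = 0.0
            pinned[k] = True

    # final quantities at the converged components
    quant = kernel.quantities(theta)
    ll, score, AI, u, trPM = quant
    ai_final = AI
    free = ~pinned
    varcov = np.zeros((K + 1, K + 1))
    se = np.zeros(K + 1)
    try:
        cov_free = np.linalg.inv(AI[np.ix_(free, free)])
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(AI[np.ix_(free, free)])
    idx_free = np.where(free)[0]
    for a, ia in enumerate(idx_free):
        for b, ib in enumerate(idx_free):
            varcov[ia, ib] = cov_free[a, b]
    se[free] = np.sqrt(np.clip(np.diag(cov_free), 0.0, None))

    comps = VarianceComponents(
        names=tuple(names),
        estimates={nm: float(th) for nm, th in zip(names, theta)},
        se={nm: float(s) for nm, s in zip(names, se)},
        boundary={nm: bool(b) for nm, b in zip(names, pinned)},
        roles=roles,
        varcov=varcov,
    )

    # BLUE and its covariance at the converged components
    Py = kernel.project_y(theta)
    if isinstance(kernel, _SpectralKernel):
        d = theta[0] * kernel.w + theta[1]
        B = kernel.Xt / d[:, None]
        C = kernel.Xt.T @ B
        Cinv = np.linalg.inv(C)
        beta = Cinv @ (B.T @ kernel.yt)
    else:
        core = kernel._core(theta, need_P=False)
        _, _, _, ViX, Cinv = core
        beta = Cinv @ (ViX.T @ y)
    blue = pd.DataFrame(
        {
            "term": design.x_names,
            "estimate": beta,
            "se": np.sqrt(np.clip(np.diag(Cinv), 0.0, None)),
        }
    )

    return ModelFit(
        spec=spec,
        design=design,
        components=comps,
        loglik=float(ll),
        blue=blue,
        blue_cov=Cinv,
        theta=theta,
        ai=ai_final,
        n_obs=n,
        rank_X=p,
        converged=True,
        n_iter=it,
        trajectory=trajectory,
        _kernel=kernel,
    )


@dataclass(frozen=True)
class LikelihoodRatioTest:
    term: str
    statistic: float
    df: int
    p_value: float
    boundary_mixture: bool

    @property
    def note(self) -> str:
        if self.boundary_mixture:
            return (
                "p-value from the 1/2*chi2(0) + 1/2*chi2(1) boundary mixture; "
                "a zero statistic reports p = 0.5 under this convention"
            )
        return "p-value from chi2(1)"


def loglik_ratio_test(
    full: ModelFit, reduced: ModelFit, *, boundary_mixture: bool = True
) -> LikelihoodRatioTest:
    """Test the single random term present in ``full`` but not ``reduced``.

    The null value (variance = 0) lies on the parameter boundary, so the
    default null distribution is the 1/2*chi2(0) + 1/2*chi2(1) mixture; plain
    chi2(1) is available for comparability with software that uses it.
    """
    if full.n_obs != reduced.n_obs:
        raise ModelSpecError("fits use different numbers of observations")
    if full.design.x_names != reduced.design.x_names:
        raise ModelSpecError("fits must share an identical fixed part")
    full_names = {t.name for t in full.spec.random_terms}
    red_names = {t.name for t in reduced.spec.random_terms}
    extra = full_names - red_names
    if len(extra) != 1 or not red_names.issubset(full_names):
        raise ModelSpecError(
            "reduced spec must be the full spec minus exactly one random term"
        )
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if boundary_mixture:
        p = 0.5 * float(sps.chi2.sf(stat, df=1))
    else:
        p = float(sps.chi2.sf(stat, df=1))
    return LikelihoodRatioTest(
        term=extra.pop(),
        statistic=stat,
        df=1,
        p_value=p,
        boundary_mixture=boundary_mixture,
    )


@dataclass(frozen=True)
class WaldFTest:
    term: str
    statistic: float
    ndf: int
    ddf: int
    p_value: float


def wald_f(fit: ModelFit, term: str) -> WaldFTest:
    """Wald F for a fixed term at the REML variance estimates.

    Tests the joint nullity of the term's retained (estimable) coefficients.
    Denominator df use the residual convention ddf = n - rank(X); this is a
    declared approximation, not an exact small-sample distribution.
    """
    if term not in fit.design.term_columns:
        raise ModelSpecError(f"no fixed term {term!r} in the fitted model")
    idx = fit.design.term_columns[term]
    b = fit.blue["estimate"].to_numpy()[idx]
    C = fit.blue_cov[np.ix_(idx, idx)]
    q = len(idx)
    stat = float(b @ np.linalg.solve(C, b)) / q
    ddf = fit.n_obs - fit.rank_X
    p = float(sps.f.sf(stat, q, ddf))
    return WaldFTest(term=term, statistic=stat, ndf=q, ddf=ddf, p_value=p)


def extract_breeding_values(fit: ModelFit) -> pd.DataFrame:
    """BLUP breeding values (EBVs) for every pedigree animal.

    Returns columns animal, ebv, pev (prediction-error variance).  Solutions
    satisfy u_hat = sigma2_A * A Z' P y; unphenotyped relatives receive
    shrunken predictions through the relationship matrix.  With V_A estimated
    at zero all EBVs are exactly zero.
    """
    term = fit.spec.additive_term
    if term is None:
        raise ModelSpecError("fit contains no additive (A-structured) term")
    design = fit.design
    A = design.G[term.name].values
    labels = design.levels[term.name]
    Z = design.Z[term.name]
    k = [t.name for t in fit.spec.random_terms].index(term.name)
    s2a = fit.theta[k]

    if s2a == 0.0:
        ebv = np.zeros(len(labels))
        pev = np.zeros(len(labels))
    else:
        # dense P at the converged components (one-off cost)
        n = fit.n_obs
        V = np.zeros((n, n))
        for th, t in zip(fit.theta[:-1], fit.spec.random_terms):
            if th != 0.0:
                V += th * design.M[t.name]
        V[np.diag_indices_from(V)] += fit.theta[-1]
        c, low = linalg.cho_factor(V, lower=True)
        Vinv = linalg.cho_solve((c, low), np.eye(n))
        ViX = Vinv @ design.X
        Cinv = np.linalg.inv(design.X.T @ ViX)
        P = Vinv - ViX @ Cinv @ ViX.T
        Py = P @ design.y
        ebv = s2a * (A @ (Z.T @ Py))
        T = Z.T @ P @ Z
        AT = A @ T
        pev = s2a * np.diag(A) - s2a**2 * np.einsum("ij,ji->i", AT, A)
        pev = np.clip(pev, 0.0, None)
    return pd.DataFrame({"animal": labels, "ebv": ebv, "pev": pev})
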