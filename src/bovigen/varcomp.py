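"""Variance-component estimation and phenotype adjustment.

Fits the trait-adjustment animal model

    y = X b + W c + u + e,    c ~ N(0, I sigma2_cg),
    u ~ N(0, G sigma2_a),     e ~ N(0, I sigma2_e)

by average-information REML, where X holds breed type, gender, production
system (reference-coded), and the linear covariates age at slaughter, days
to fatty-acid extraction, diet metabolic energy and (for muscle traits)
marbling score; W is the contemporary-group incidence matrix and G the
genomic relationship matrix.

Numerics: after one eigendecomposition of G + ridge*I the covariance is
diagonal-plus-low-rank in the rotated basis, so each AI iteration costs
O(n q^2) with q the number of contemporary groups.  AI updates that leave
the parameter space or decrease the restricted likelihood fall back to
step-halving and then to the (guaranteed non-negative) EM-REML update, so
the accepted log-likelihood path is non-decreasing and variances stay
within bounds by boundary projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .data import RelationshipMatrix
from .exceptions import ConvergenceError, DataError, IdentifiabilityWarning

FIXED_CATEGORICAL = ("breed", "gender", "system")
FIXED_COVARIATES = ("age", "days_ext", "diet_me")


def build_design(trait_table: pd.DataFrame, trait: str = "trait",
                 marbling: bool = False):
    """Design matrices for the adjustment model from a trait table.

    Categorical fixed effects are reference-coded (first level alphabetically
    is the reference); covariates enter linearly.  Rows with missing trait or
    covariate values are dropped with a warning.

    Returns (y, X, column_names, cg_labels, animal_ids).
    """
    needed = [trait, "cg", *FIXED_CATEGORICAL, *FIXED_COVARIATES]
    if marbling:
        needed.append("marbling")
    missing_cols = [c for c in needed if c not in trait_table.columns]
    if missing_cols:
        raise DataError(f"trait table lacks columns: {missing_cols}")
    tab = trait_table.copy()
    ok = tab[needed].notna().all(axis=1)
    if not ok.all():
        warnings.warn(
            f"dropping {(~ok).sum()} animals with missing trait/covariate values"
        )
        tab = tab[ok]
    y = tab[trait].to_numpy(dtype=float)
    cols = [np.ones(len(tab))]
    names = ["intercept"]
    for cat in FIXED_CATEGORICAL:
        levels = sorted(tab[cat].astype(str).unique())
        for lev in levels[1:]:
            cols.append((tab[cat].astype(str) == lev).to_numpy(float))
            names.append(f"{cat}[{lev}]")
    covs = list(FIXED_COVARIATES) + (["marbling"] if marbling else [])
    for cov in covs:
        cols.append(tab[cov].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("fixed-effect design matrix is rank deficient")
    return y, X, names, tab["cg"].to_numpy(), tab["animal_id"].to_numpy()


@dataclass
class REMLResults:
    """Estimates from one AI-REML fit."""

    sigma2_a: float
    sigma2_cg: float
    sigma2_e: float
    se_h2: float
    beta: pd.Series
    loglik_history: list
    converged: bool
    n_iter: int
    ai_matrix: np.ndarray
    model: "MixedREML" = field(repr=False)

    def heritability(self, include_cg: bool = True) -> float:
        """h2 = sigma2_a / (sigma2_a + [sigma2_cg] + sigma2_e).

        The contemporary-group variance is part of the denominator by
        default; pass include_cg=False for the purely additive+residual
        definition.
        """
        denom = self.sigma2_a + self.sigma2_e
        if include_cg:
            denom += self.sigma2_cg
        return self.sigma2_a / denom if denom > 0 else 0.0

    @property
    def h2(self) -> float:
        return self.heritability()

    @property
    def loglik(self) -> float:
        return self.loglik_history[-1]

    def cg_blup(self) -> np.ndarray:
        """BLUPs of the contemporary-group effects."""
        return self.model._cg_blup(self)

    def adjust(self) -> pd.Series:
        """Adjusted phenotypes y* = y - X b_hat - W c_hat.

        Fixed effects and contemporary-group BLUPs are removed; the additive
        genetic and residual parts remain.  Indexed by animal id.
        """
        return self.model._adjust(self)

    def summary(self) -> str:
        lines = [
            "Mixed-model REML (average information)",
            "=" * 46,
            f"{'n animals':<28}{self.model.n}",
            f"{'fixed-effect columns':<28}{self.model.X.shape[1]}",
            f"{'contemporary groups':<28}{self.model.n_cg}",
            f"{'iterations':<28}{self.n_iter}",
            f"{'converged':<28}{self.converged}",
            f"{'restricted logL':<28}{self.loglik:.4f}",
            "-" * 46,
            f"{'sigma2_a (additive)':<28}{self.sigma2_a:.6g}",
            f"{'sigma2_cg (contemp. group)':<28}{self.sigma2_cg:.6g}",
            f"{'sigma2_e (residual)':<28}{self.sigma2_e:.6g}",
            f"{'h2 (cg in denominator)':<28}{self.h2:.4f} +/- {self.se_h2:.4f}",
            f"{'h2 (cg excluded)':<28}{self.heritability(False):.4f}",
            "-" * 46,
            "fixed effects:",
        ]
        for name, val in self.beta.items():
            lines.append(f"  {name:<26}{val: .6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_cg": self.sigma2_cg,
            "sigma2_e": self.sigma2_e,
            "h2": self.h2,
            "se_h2": self.se_h2,
            "converged": self.converged,
            "loglik": self.loglik,
        }


class MixedREML:
    """Three-component animal model fitted by AI-REML.

    Parameters
    ----------
    y : array
        Trait values.
    X : array
        Fixed-effect design (full column rank, includes the intercept).
    cg_labels : array or None
        Contemporary-group label per animal; None drops the cg component.
    grm : RelationshipMatrix or array
        Additive relationship matrix (genomic or pedigree) over the same
        animals in the same order.
    """

    def __init__(self, y, X, cg_labels, grm, ridge: float = 1e-6,
                 x_names=None, animal_ids=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise DataError("X rows must match y length")
        if self.X.shape[1] + 10 > n:
            raise DataError("need n >= n_fixed_columns + 10 animals")
        G = grm.values if isinstance(grm, RelationshipMatrix) else np.asarray(grm)
        if G.shape != (n, n):
            raise DataError("relationship matrix dimension does not match animals")
        self.n = n
        self.x_names = list(x_names) if x_names is not None else [
            f"x{k}" for k in range(self.X.shape[1])
        ]
        self.animal_ids = (np.asarray(animal_ids) if animal_ids is not None
                           else np.arange(n))
        if cg_labels is not None:
            labels = pd.Categorical(np.asarray(cg_labels))
            self._cg_codes = labels.codes
            self._cg_names = list(labels.categories)
            self.n_cg = len(labels.categories)
            W = np.zeros((n, self.n_cg))
            W[np.arange(n), self._cg_codes] = 1.0
        else:
            self.n_cg = 0
            W = None
        self._has_cg = W is not None and self.n_cg > 1

        # one-off rotation to the eigenbasis of G + ridge*I
        d, U = eigh(G + ridge * np.eye(n))
        self._d = np.clip(d, 1e-12, None)
        self._U = U
        self._ty = U.T @ self.y
        self._tX = U.T @ self.X
        self._tW = U.T @ W if self._has_cg else None
        self._W = W

    @classmethod
    def from_trait_table(cls, trait_table: pd.DataFrame, grm,
                         trait: str = "trait", marbling: bool = False,
                         ridge: float = 1e-6) -> "MixedREML":
        """Build the adjustment-model design from a trait table.

        The relationship matrix must cover the trait table's animals in
        order; animals dropped for missing covariates are removed from it.
        """
        y, X, names, cg, ids = build_design(trait_table, trait, marbling)
        G = grm.values if isinstance(grm, RelationshipMatrix) else np.asarray(grm)
        if len(ids) != G.shape[0]:
            all_ids = list(trait_table["animal_id"])
            keep = [all_ids.index(a) for a in ids]
            G = G[np.ix_(keep, keep)]
        return cls(y, X, cg, G, ridge=ridge, x_names=names, animal_ids=ids)

    # ---- covariance algebra in the rotated basis ------------------------

    def _ops(self, theta):
        """Factorised state for one parameter point.

        Returns a dict with solve(v)->Sigma^-1 v, traces of Sigma^-1 V_i,
        and log|Sigma|, exploiting Sigma = diag(A) + sigma2_cg * W W'.
        """
        s_a, s_cg, s_e = theta
        A = s_a * self._d + s_e
        if np.any(A <= 0):
            return None
        st = {"A": A}
        if self._has_cg and s_cg > 0:
            W = self._tW
            S = W / A[:, None]                       # A^-1 W
            H = W.T @ S                               # W' A^-1 W
            Mmat = np.eye(self.n_cg) / s_cg + H
            try:
                cM = cho_factor(Mmat)
            except np.linalg.LinAlgError:
                return None
            Minv = cho_solve(cM, np.eye(self.n_cg))
            st["S"], st["Minv"], st["H"] = S, Minv, H
            st["logdet"] = (np.log(A).sum()
                            + np.linalg.slogdet(s_cg * Mmat)[1])

            def solve(v):
                v = np.asarray(v)
                return v / (A[:, None] if v.ndim == 2 else A) - S @ (Minv @ (S.T @ v))
        else:
            st["logdet"] = np.log(A).sum()

            def solve(v):
                v = np.asarray(v)
                return v / (A[:, None] if v.ndim == 2 else A)

        st["solve"] = solve
        return st

    def _core(self, theta, st):
        """P y, GLS pieces and restricted log-likelihood at theta."""
        solve = st["solve"]
        Siy = solve(self._ty)
        SiX = solve(self._tX)
        XtSiX = self._tX.T @ SiX
        cXX = cho_factor(XtSiX)
        beta = cho_solve(cXX, self._tX.T @ Siy)
        w = Siy - SiX @ beta                          # P y
        ll = -0.5 * (st["logdet"] + np.linalg.slogdet(XtSiX)[1]
                     + float(self._ty @ w))
        return {"w": w, "SiX": SiX, "cXX": cXX, "beta": beta, "ll": ll}

    def _applyP(self, v, st, core):
        Siv = st["solve"](v)
        alpha = cho_solve(core["cXX"], self._tX.T @ Siv)
        return Siv - core["SiX"] @ alpha

    def _traces(self, theta, st, core):
        """tr(P V_i) for V_i in (G, WW', I)."""
        A, d = st["A"], self._d
        SiX, cXX = core["SiX"], core["cXX"]
        if "S" in st:
            S, Minv = st["S"], st["Minv"]
            tr_g = float((d / A).sum() - np.sum(Minv * (S.T @ (d[:, None] * S))))
            tr_e = float((1.0 / A).sum() - np.sum(Minv * (S.T @ S)))
            H = st["H"]
            WtSiW = H - H @ Minv @ H
            tr_cg = float(np.trace(WtSiW))
            WtSiX = self._tW.T @ SiX
        else:
            tr_g = float((d / A).sum())
            tr_e = float((1.0 / A).sum())
            tr_cg = 0.0
        # subtract the fixed-effect projection tr(B V_i)
        C = cho_solve(cXX, np.eye(self.X.shape[1]))
        tr_g -= float(np.sum(C * (SiX.T @ (d[:, None] * SiX))))
        tr_e -= float(np.sum(C * (SiX.T @ SiX)))
        if self._has_cg:
            WtSiX = self._tW.T @ SiX
            tr_cg = tr_cg - float(np.sum(C * (WtSiX.T @ WtSiX))) if "S" in st \
                else float(np.trace(self._tW.T @ st["solve"](self._tW))) \
                - float(np.sum(C * (WtSiX.T @ WtSiX)))
        return tr_g, tr_cg, tr_e

    def _score_ai(self, theta, st, core):
        w = core["w"]
        d = self._d
        t_g = d * w
        t_e = w
        quads = {"g": float(w @ t_g), "e": float(w @ t_e)}
        if self._has_cg:
            Wtw = self._tW.T @ w
            t_cg = self._tW @ Wtw
            quads["cg"] = float(Wtw @ Wtw)
        else:
            t_cg = np.zeros_like(w)
            quads["cg"] = 0.0
        tr_g, tr_cg, tr_e = self._traces(theta, st, core)
        score = 0.5 * np.array([
            quads["g"] - tr_g, quads["cg"] - tr_cg, quads["e"] - tr_e,
        ])
        Pt = [self._applyP(t, st, core) for t in (t_g, t_cg, t_e)]
        ts = (t_g, t_cg, t_e)
        AI = 0.5 * np.array([[float(ts[i] @ Pt[j]) for j in range(3)]
                             for i in range(3)])
        traces = np.array([tr_g, tr_cg, tr_e])
        return score, AI, traces, quads

    # ---- fitting --------------------------------------------------------

    def fit(self, max_iter: int = 200, tol_ll: float = 1e-6,
            tol_param: float = 1e-8, start=None) -> REMLResults:
        vy = float(np.var(self.y))
        if vy <= 0:
            raise DataError("trait has zero variance")
        floor = 1e-8 * vy
        if start is None:
            theta = np.array([0.3, 0.1 if self._has_cg else floor, 0.6]) * vy
        else:
            theta = np.asarray(start, dtype=float).copy()
        if not self._has_cg:
            theta[1] = floor

        active = np.array([0, 1, 2]) if self._has_cg else np.array([0, 2])

        ll_hist = []
        st = self._ops(theta)
        core = self._core(theta, st)
        ll_hist.append(core["ll"])
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            theta_prev = theta.copy()
            score, AI, traces, quads = self._score_ai(theta, st, core)
            accepted = False
            # AI (Newton) direction with step-halving and boundary projection
            AIa = AI[np.ix_(active, active)]
            try:
                delta_a = np.linalg.solve(
                    AIa + 1e-12 * np.eye(len(active)) * np.trace(AIa),
                    score[active])
                delta = np.zeros(3)
                delta[active] = delta_a
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(25):
                    cand = np.maximum(theta + step * delta, floor)
                    if not self._has_cg:
                        cand[1] = floor
                    st_c = self._ops(cand)
                    if st_c is not None:
                        core_c = self._core(cand, st_c)
                        if core_c["ll"] >= ll_hist[-1] - 1e-10:
                            theta, st, core = cand, st_c, core_c
                            accepted = True
                            break
                    step *= 0.5
            if not accepted:
                # EM-REML fallback: sigma_i^2 <- sigma_i^2 +
                # sigma_i^4 (y'P V_i P y - tr(P V_i)) / q_i
                q = np.array([self.n, max(self.n_cg, 1), self.n], dtype=float)
                quadv = np.array([quads["g"], quads["cg"], quads["e"]])
                cand = theta + theta**2 * (quadv - traces) / q
                cand = np.maximum(cand, floor)
                if not self._has_cg:
                    cand[1] = floor
                st_c = self._ops(cand)
                if st_c is not None:
                    core_c = self._core(cand, st_c)
                    if core_c["ll"] >= ll_hist[-1] - 1e-8:
                        theta, st, core = cand, st_c, core_c
                        accepted = True
            if not accepted:
                # no direction improves the likelihood: local maximum
                converged = True
                ll_hist.append(core["ll"])
                break
            ll_hist.append(core["ll"])
            d_ll = abs(ll_hist[-1] - ll_hist[-2])
            d_th = float(np.max(np.abs(theta - theta_prev)))
            if d_ll < tol_ll or d_th < tol_param:
                converged = True
                break

        score, AI, _, _ = self._score_ai(theta, st, core)
        if not converged:
            raise ConvergenceError(
                f"AI-REML did not converge in {max_iter} iterations",
                last_estimates={"sigma2_a": theta[0], "sigma2_cg": theta[1],
                                "sigma2_e": theta[2]},
            )
        AIa = AI[np.ix_(active, active)]
        eigvals = np.linalg.eigvalsh(AIa)
        if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > 1e10:
            warnings.warn(
                "variance components are weakly identified (flat restricted "
                "likelihood); reporting the boundary solution",
                IdentifiabilityWarning,
            )
        se_h2 = self._se_h2(theta, AI, active)
        beta = pd.Series(core["beta"], index=self.x_names, name="estimate")
        res = REMLResults(
            sigma2_a=float(theta[0]),
            sigma2_cg=float(theta[1]) if self._has_cg else 0.0,
            sigma2_e=float(theta[2]),
            se_h2=se_h2,
            beta=beta,
            loglik_history=ll_hist,
            converged=converged,
            n_iter=it,
            ai_matrix=AI,
            model=self,
        )
        self._last_core = core
        self._last_st = st
        return res

    def _se_h2(self, theta, AI, active) -> float:
        """Delta-method SE of h2 from the inverse AI matrix."""
        s = float(theta[active].sum())
        if s <= 0:
            return float("nan")
        g = np.array([(s - theta[0]) / s**2, -theta[0] / s**2, -theta[0] / s**2])
        try:
            cov = np.linalg.pinv(AI[np.ix_(active, active)])
            ga = g[active]
            return float(np.sqrt(max(ga @ cov @ ga, 0.0)))
        except np.linalg.LinAlgError:
            return float("nan")

    # ---- post-fit quantities -------------------------------------------

    def _refresh(self, results: REMLResults):
        theta = np.array([results.sigma2_a,
                          results.sigma2_cg if self._has_cg else 1e-8 * np.var(self.y),
                          results.sigma2_e])
        st = self._ops(theta)
        core = self._core(theta, st)
        return theta, st, core

    def _cg_blup(self, results: REMLResults) -> np.ndarray:
        if not self._has_cg:
            return np.zeros(0)
        theta, st, core = self._refresh(results)
        return results.sigma2_cg * (self._tW.T @ core["w"])

    def _adjust(self, results: REMLResults) -> pd.Series:
        theta, st, core = self._refresh(results)
        y_star = self.y - self.X @ core["beta"]
        if self._has_cg:
            c_hat = results.sigma2_cg * (self._tW.T @ core["w"])
            y_star = y_star - self._W @ c_hat
        return pd.Series(y_star, index=self.animal_ids, name="y_star")
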