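"""EM-REML estimation of the genetic and residual covariance matrices.

The pipeline refuses to evaluate without variance components; this module lets a
user estimate G0/R0 from the data themselves.  The base iteration is EM-REML:
re-solve the mixed-model equations at the current components, then update

    G0[i,j] ← ( â_i' A⁻¹ â_j + tr(A⁻¹ · C^{aa}_{ij}) ) / q
    R0      ← ( Ê'Ê + Σ_r W_r C⁻¹ W_r' ) / n

built from animal-effect solutions, PEV traces and fitted residuals — the
conditional expectations (E-step) of the restricted likelihood's sufficient
statistics.  The restricted likelihood never decreases along the plain-EM
sequence.

Three implementation choices keep this exact yet affordable at herdbook scale:

* The E-step needs C⁻¹ only at equations touched by records.  The PEV trace over
  the A⁻¹ pattern is rewritten through the MME block identity
  G0⁻¹·T = q·I − (record-gathered terms), where T[i,j] = tr(A⁻¹ C^{aa}_{ij}),
  so every required entry of C⁻¹ lives in columns of recorded-animal or fixed
  equations; those columns come from chunked unit-vector solves against the
  sparse factorization — no dense inversion.
* A parameter-expansion (PX) rescaling of the genetic update — the regression Γ̂
  of the data on the predicted animal effects — is folded into the EM map, which
  sharply reduces the step count when per-animal information is low.
* The driver wraps the EM map in SQUAREM-style squared extrapolation cycles with
  a restricted-likelihood guard: an extrapolated candidate is kept only if the
  likelihood proxy does not decrease, otherwise the cycle falls back to the
  plain EM result, so the accepted sequence stays monotone.  ``accelerate=False``
  gives textbook EM (one update per iteration, no PX, no extrapolation).

Records with missing traits are dropped here with a warning (the evaluation
path handles missingness exactly); estimation uses complete records only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mme import (Design, MMESystem, ModelSpec, VarianceComponents, assemble_mme,
                  build_design, _pattern_rinv)
from .pedigree import Pedigree, build_a_inverse

__all__ = ["RemlState", "RemlError", "em_reml"]


@dataclass
class RemlState:
    iteration: int
    G0: np.ndarray
    R0: np.ndarray
    loglik_proxy: float
    delta: float
    accelerated: bool = False


class RemlError(RuntimeError):
    def __init__(self, message: str, trace: list[RemlState]):
        super().__init__(message)
        self.trace = trace


def _ridge_repair(m: np.ndarray, name: str, quiet: bool = False) -> np.ndarray:
    m = 0.5 * (m + m.T)
    w = np.linalg.eigvalsh(m)
    if w.min() > 0:
        return m
    ridge = abs(w.min()) + 1e-8 * abs(np.trace(m)) / m.shape[0] + 1e-12
    if not quiet:
        warnings.warn(f"EM update produced non-PD {name}; adding ridge {ridge:.3g}")
    return m + ridge * np.eye(m.shape[0])


class _RecordIndex:
    """Per record × trait: equation indices/values of the incidence row, plus the
    set of C⁻¹ columns the E-step gathers from (fixed + recorded-animal equations)."""

    def __init__(self, design: Design, system: MMESystem):
        n, t = design.n_records, design.n_traits
        width = int(max(np.diff(design.X[j].indptr).max() for j in range(t)))
        self.fix_idx = np.zeros((t, n, width), dtype=np.int64)
        self.fix_val = np.zeros((t, n, width))
        offset = 0
        for j in range(t):
            X = design.X[j].tocsr()
            for r in range(n):
                sl = slice(X.indptr[r], X.indptr[r + 1])
                k = sl.stop - sl.start
                self.fix_idx[j, r, :k] = offset + X.indices[sl]
                self.fix_val[j, r, :k] = X.data[sl]
            offset += X.shape[1]
        animal_pos = design.Z.indices  # one animal per record row
        self.anim_idx = np.stack(
            [system.animal_offset[j] + animal_pos for j in range(t)])  # (t, n)

        cols = set()
        for j in range(t):
            cols.update(self.fix_idx[j].ravel().tolist())
            cols.update(self.anim_idx[j].tolist())
        cols -= system.constraints
        self.columns = np.array(sorted(cols), dtype=np.int64)
        colpos = np.full(system.n_equations, len(self.columns), dtype=np.int64)
        colpos[self.columns] = np.arange(len(self.columns))
        # constrained columns map to a zero scratch row/column of the gathered block
        self.l_fix = np.stack([colpos[self.fix_idx[j]] for j in range(t)])
        self.l_anim = colpos[self.anim_idx]


def _selected_cinv(system: MMESystem, rix: _RecordIndex, chunk: int = 512) -> np.ndarray:
    """Dense C⁻¹ restricted to the record-touched equations, with an extra zero
    scratch row/column standing in for constrained equations (their generalized-
    inverse entries are zero)."""
    lu = system.factorize()
    s = len(rix.columns)
    out = np.zeros((s + 1, s + 1))
    N = system.n_equations
    for start in range(0, s, chunk):
        cols = rix.columns[start:start + chunk]
        E = np.zeros((N, len(cols)))
        E[cols, np.arange(len(cols))] = 1.0
        out[:s, start:start + len(cols)] = lu.solve(E)[rix.columns]
    return out


def _loglik_proxy(system: MMESystem, design: Design, vc: VarianceComponents,
                  x: np.ndarray) -> float:
    """Restricted-likelihood proxy −½(n·log|R0| + q·log|G0| + log|C| + y'Py);
    additive constants (log|A|, constrained unit pivots) dropped."""
    n = design.n_records
    q = len(design.ped)
    lu = system.factorize()
    logdet_c = float(np.log(np.abs(lu.U.diagonal())).sum())
    r_inv = np.linalg.inv(vc.R0)
    y_rinv_y = float(np.einsum("ri,ij,rj->", design.y, r_inv, design.y))
    ypy = y_rinv_y - float(system.rhs @ x)
    sign_r, logdet_r = np.linalg.slogdet(vc.R0)
    sign_g, logdet_g = np.linalg.slogdet(vc.G0)
    if sign_r <= 0 or sign_g <= 0:
        return -np.inf
    return -0.5 * (n * logdet_r + q * logdet_g + logdet_c + ypy)


class _EmEngine:
    """Holds the fixed problem structure and exposes the EM map and the
    restricted-likelihood proxy as functions of (G0, R0)."""

    def __init__(self, design: Design, relfac, tnames: list[str]):
        self.design = design
        self.relfac = relfac
        self.a_inv = relfac.a_inverse
        self.tnames = list(tnames)
        self.t = len(tnames)
        self.q = self.a_inv.shape[0]
        self.n = design.n_records
        self.rix: _RecordIndex | None = None

    def _system(self, G0, R0):
        vc = VarianceComponents(self.tnames, G0, R0)
        system = assemble_mme(self.design, self.relfac, vc)
        x = system.factorize().solve(system.rhs)
        return vc, system, x

    def loglik(self, G0, R0) -> float:
        try:
            vc, system, x = self._system(G0, R0)
        except ValueError:
            return -np.inf
        return _loglik_proxy(system, self.design, vc, x)

    def step(self, G0, R0, use_px: bool) -> tuple[np.ndarray, np.ndarray, float]:
        """One EM (or PX-EM) update; returns (G_new, R_new, loglik at input)."""
        t, q, n = self.t, self.q, self.n
        vc, system, x = self._system(G0, R0)
        loglik = _loglik_proxy(system, self.design, vc, x)
        if self.rix is None:
            self.rix = _RecordIndex(self.design, system)
        rix = self.rix
        csel = _selected_cinv(system, rix)
        rinv = _pattern_rinv(R0, self.design.observed)  # constant rows: complete data
        la, lf = rix.l_anim, rix.l_fix

        a_hat = np.stack([x[system.animal_offset[j]:system.animal_offset[j] + q]
                          for j in range(t)], axis=1)
        quad = a_hat.T @ np.stack([self.a_inv @ a_hat[:, j] for j in range(t)],
                                  axis=1)

        fitted = np.stack(
            [np.einsum("rk,rk->r", rix.fix_val[j], x[rix.fix_idx[j]])
             + x[rix.anim_idx[j]] for j in range(t)], axis=1)
        e_hat = self.design.y - fitted

        # PEV-trace matrix T[i,j] = tr(A⁻¹ C^{aa}_{ij}) via the MME block identity
        Caa_rec = csel[la[:, None, :], la[None, :, :]]  # (t, t2, n)
        Cfa_rec = np.stack([
            [np.einsum("rk,rk->r", rix.fix_val[ti], csel[lf[ti], la[t2][:, None]])
             for t2 in range(t)]
            for ti in range(t)
        ])
        Q = np.zeros((t, t))
        for t1 in range(t):
            for t2 in range(t):
                acc = 0.0
                for tt in range(t):
                    acc += np.sum(rinv[:, t1, tt] * Caa_rec[tt, t2])
                    acc += np.sum(rinv[:, t1, tt] * Cfa_rec[tt, t2])
                Q[t1, t2] = (q if t1 == t2 else 0.0) - acc
        T = G0 @ Q

        G_em = _ridge_repair((quad + 0.5 * (T + T.T)) / q, "G0")

        # R0 update: residual cross-products plus the incidence-sandwich term
        R_new = e_hat.T @ e_hat
        for t1 in range(t):
            for t2 in range(t1, t):
                ff = np.einsum(
                    "rk,rkl,rl->", rix.fix_val[t1],
                    csel[lf[t1][:, :, None], lf[t2][:, None, :]], rix.fix_val[t2])
                fa = np.einsum("rk,rk->r", rix.fix_val[t1],
                               csel[lf[t1], la[t2][:, None]]).sum()
                af = np.einsum("rk,rk->r", rix.fix_val[t2],
                               csel[lf[t2], la[t1][:, None]]).sum()
                aa = csel[la[t1], la[t2]].sum()
                sand = ff + fa + af + aa
                R_new[t1, t2] += sand
                if t1 != t2:
                    R_new[t2, t1] += sand
        R_new = _ridge_repair(R_new / n, "R0")

        if use_px:
            G_px = self._px_rescale(G_em, rinv, e_hat, x, Caa_rec)
            if G_px is not None and np.isfinite(G_px).all():
                G_em = _ridge_repair(G_px, "G0", quiet=True)
        return G_em, R_new, loglik

    def _px_rescale(self, G_em, rinv, e_hat, x, Caa_rec):
        """Parameter-expansion rescaling Γ̂ G Γ̂', with Γ̂ the expected-complete-data
        regression of the record data (minus fixed effects) on the predicted
        animal effects: [Σ_r R⁻¹_r ⊗-weighted E[a_i a_i']] vec(Γ) = vec(Σ_r R⁻¹_r ỹ_r â_i')."""
        t, rix = self.t, self.rix
        try:
            a_rec = np.stack([x[rix.anim_idx[j]] for j in range(t)], axis=1)
            ytilde = e_hat + a_rec  # data minus fixed part
            Eaa = np.einsum("ri,rj->rij", a_rec, a_rec)
            for t1 in range(t):
                for t2 in range(t):
                    Eaa[:, t1, t2] += Caa_rec[t1, t2]
            # normal equations in vec(Γ): rows (i,j), columns (k,l)
            lhs = np.einsum("rik,rlj->ijkl", rinv, Eaa).reshape(t * t, t * t)
            rhs = np.einsum("rik,rk,rj->ij", rinv, ytilde, a_rec)
            gamma = np.linalg.solve(lhs, rhs.reshape(t * t)).reshape(t, t)
            return gamma @ G_em @ gamma.T
        except np.linalg.LinAlgError:
            return None


def em_reml(records: pd.DataFrame, ped: Pedigree, spec: ModelSpec,
            start: VarianceComponents, tol: float = 1e-4, max_iter: int = 60,
            min_iter: int = 3, accelerate: bool = True,
            ) -> tuple[VarianceComponents, list[RemlState]]:
    """Estimate G0/R0 by (accelerated) EM-REML.

    ``tol`` is the maximum relative change of any component across one driver
    iteration (one EM update, or one two-step extrapolation cycle when
    ``accelerate``); the returned trace carries per-iteration estimates, the
    likelihood proxy and whether an extrapolated candidate was accepted.
    """
    tnames = spec.trait_names
    t = len(tnames)
    complete = records.copy()
    for tn in tnames:
        complete = complete[pd.to_numeric(complete[tn], errors="coerce").notna()]
    n_dropped = len(records) - len(complete)
    if n_dropped:
        warnings.warn(f"em_reml uses complete records only: dropped {n_dropped} "
                      f"of {len(records)} records with missing traits")
    if complete.empty:
        raise ValueError("no complete records available for EM-REML")

    relfac = build_a_inverse(ped)
    design = build_design(complete, ped, spec)
    engine = _EmEngine(design, relfac, tnames)

    G0 = np.array(start.G0, dtype=float, copy=True).reshape(t, t)
    R0 = np.array(start.R0, dtype=float, copy=True).reshape(t, t)

    def pack(G, R):
        return np.concatenate([G.ravel(), R.ravel()])

    def unpack(v):
        return v[:t * t].reshape(t, t), v[t * t:].reshape(t, t)

    trace: list[RemlState] = []
    small_steps = 0
    for it in range(1, max_iter + 1):
        accepted_ext = False
        if not accelerate:
            G_new, R_new, loglik = engine.step(G0, R0, use_px=False)
        else:
            G1, R1, loglik = engine.step(G0, R0, use_px=True)
            G2, R2, ll1 = engine.step(G1, R1, use_px=True)
            th0, th1, th2 = pack(G0, R0), pack(G1, R1), pack(G2, R2)
            r = th1 - th0
            v = (th2 - th1) - r
            G_new, R_new = G2, R2
            nv = np.linalg.norm(v)
            if nv > 0:
                alpha = -np.linalg.norm(r) / nv
                alpha = min(alpha, -1.0)
                th_sq = th0 - 2.0 * alpha * r + alpha * alpha * v
                G_sq, R_sq = unpack(th_sq)
                try:
                    G_sq = _ridge_repair(G_sq, "G0", quiet=True)
                    R_sq = _ridge_repair(R_sq, "R0", quiet=True)
                    if engine.loglik(G_sq, R_sq) >= engine.loglik(G2, R2):
                        G_new, R_new = G_sq, R_sq
                        accepted_ext = True
                except ValueError:
                    pass
            # monotonicity guard for the whole cycle (PX steps are one-step-late)
            if engine.loglik(G_new, R_new) < loglik:
                G_new, R_new, _ = engine.step(G0, R0, use_px=False)

        scale = np.concatenate([np.abs(np.diag(G0)), np.abs(np.diag(R0))]).max()
        delta = max(np.abs(G_new - G0).max(), np.abs(R_new - R0).max()) / scale
        G0, R0 = G_new, R_new
        trace.append(RemlState(it, G0.copy(), R0.copy(), loglik, float(delta),
                               accepted_ext))
        if not np.isfinite(delta):
            raise RemlError("EM-REML diverged (non-finite update)", trace)
        small_steps = small_steps + 1 if delta <= tol else 0
        if small_steps >= 2 and it >= min_iter:
            break

    return VarianceComponents(list(tnames), G0, R0), trace
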