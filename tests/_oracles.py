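"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the mixed-model oracle
works in the observation space (V = Z G Z' + R with generalized least squares),
not through Henderson's equations; the intensity oracle is Monte Carlo; the
restricted likelihood is evaluated directly from V on dense toy problems.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from herdblup.pedigree import Pedigree, tabular_a_matrix

TRAIT_ORDER = ["my305", "afc", "ci1"]


def random_pedigree(rng: np.random.Generator, n: int, p_founder: float = 0.3):
    """Random valid pedigree of n animals with sexed parents (acyclic by order)."""
    ids = [f"A{i:03d}" for i in range(n)]
    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female
    rows = []
    for i in range(n):
        sire = dam = "0"
        if i > 1 and rng.random() > p_founder:
            males = [j for j in range(i) if sex[j] == 0]
            females = [j for j in range(i) if sex[j] == 1]
            if males and rng.random() < 0.9:
                sire = ids[int(rng.choice(males))]
            if females and rng.random() < 0.9:
                dam = ids[int(rng.choice(females))]
        rows.append((ids[i], sire, dam))
    return pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"])


def dense_mixed_model_oracle(records: pd.DataFrame, ped: Pedigree,
                             trait_names, uses_age, G0, R0, pooled=False):
    """GLS/BLUP through the observation-space covariance V — no MME.

    Returns (ebv, pev) arrays of shape (n_animals, n_traits) over ped order.
    """
    G0 = np.atleast_2d(np.asarray(G0, float))
    R0 = np.atleast_2d(np.asarray(R0, float))
    t = len(trait_names)
    m = len(ped)
    A = tabular_a_matrix(ped)
    Gfull = np.kron(A, G0)  # animal-major (animal, trait) ordering

    herd = records["herd"].astype(str).to_numpy()
    hys = records["hys"].astype(str).to_numpy()
    country = records["country"].astype(str).to_numpy() if pooled else None
    if any(uses_age):
        age = records["age_months"].astype(float).to_numpy()
        age_c = age - age.mean()
    else:
        age_c = np.zeros(len(records))
    apos = np.array([ped.index[a] for a in records["animal_id"].astype(str)])

    obs_rows = []   # (record, trait_j) in record-major order
    for r in range(len(records)):
        for j, tn in enumerate(trait_names):
            v = pd.to_numeric(pd.Series([records.iloc[r][tn]]), errors="coerce")[0]
            if not np.isnan(v):
                obs_rows.append((r, j, float(v)))
    nobs = len(obs_rows)
    y = np.array([v for _, _, v in obs_rows])

    # fixed design: per trait, herd/hys (+country) dummies and the age column(s)
    X_cols = []
    def col_for(pred):
        c = np.zeros(nobs)
        for k, (r, j, _) in enumerate(obs_rows):
            c[k] = pred(r, j)
        return c
    for j in range(t):
        for lev in sorted(set(herd)):
            X_cols.append(col_for(lambda r, jj, lev=lev, j=j: float(jj == j and herd[r] == lev)))
        for lev in sorted(set(hys)):
            X_cols.append(col_for(lambda r, jj, lev=lev, j=j: float(jj == j and hys[r] == lev)))
        if pooled:
            for lev in sorted(set(country)):
                X_cols.append(col_for(lambda r, jj, lev=lev, j=j: float(jj == j and country[r] == lev)))
        if uses_age[j]:
            if pooled:
                for lev in sorted(set(country)):
                    X_cols.append(col_for(
                        lambda r, jj, lev=lev, j=j: age_c[r] if (jj == j and country[r] == lev) else 0.0))
            else:
                X_cols.append(col_for(lambda r, jj, j=j: age_c[r] if jj == j else 0.0))
    X = np.column_stack(X_cols)

    # C_ay = Cov(a, y): rows (animal, trait) animal-major; columns observations
    Cay = np.zeros((m * t, nobs))
    for k, (r, j, _) in enumerate(obs_rows):
        Cay[:, k] = Gfull[:, apos[r] * t + j]

    V = np.zeros((nobs, nobs))
    for k1, (r1, j1, _) in enumerate(obs_rows):
        for k2, (r2, j2, _) in enumerate(obs_rows):
            V[k1, k2] = Gfull[apos[r1] * t + j1, apos[r2] * t + j2]
            if r1 == r2:
                V[k1, k2] += R0[j1, j2]
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    XtViX_pinv = np.linalg.pinv(XtVi @ X)
    b = XtViX_pinv @ (XtVi @ y)
    resid = y - X @ b
    ebv = (Cay @ Vi @ resid).reshape(m, t)

    CVi = Cay @ Vi
    M = CVi @ X
    pev_mat = Gfull - CVi @ Cay.T + M @ XtViX_pinv @ M.T
    pev = np.diag(pev_mat).reshape(m, t)
    return ebv, pev


def dense_reml_loglik(records, ped, trait_names, uses_age, G0, R0):
    """Restricted log-likelihood −½(log|V| + log|X'V⁻¹X|₊ + y'Py) on dense toys,
    using the same observation-space route as the mixed-model oracle."""
    G0 = np.atleast_2d(np.asarray(G0, float))
    R0 = np.atleast_2d(np.asarray(R0, float))
    t = len(trait_names)
    A = tabular_a_matrix(ped)
    Gfull = np.kron(A, G0)
    apos = np.array([ped.index[a] for a in records["animal_id"].astype(str)])
    herd = records["herd"].astype(str).to_numpy()
    hys = records["hys"].astype(str).to_numpy()
    if any(uses_age):
        age = records["age_months"].astype(float).to_numpy()
        age_c = age - age.mean()
    else:
        age_c = np.zeros(len(records))

    obs_rows = []
    for r in range(len(records)):
        for j, tn in enumerate(trait_names):
            v = pd.to_numeric(pd.Series([records.iloc[r][tn]]), errors="coerce")[0]
            if not np.isnan(v):
                obs_rows.append((r, j, float(v)))
    nobs = len(obs_rows)
    y = np.array([v for _, _, v in obs_rows])
    X_cols = []
    for j in range(t):
        for lev in sorted(set(herd)):
            X_cols.append([float(jj == j and herd[r] == lev) for r, jj, _ in obs_rows])
        for lev in sorted(set(hys)):
            X_cols.append([float(jj == j and hys[r] == lev) for r, jj, _ in obs_rows])
        if uses_age[j]:
            X_cols.append([age_c[r] if jj == j else 0.0 for r, jj, _ in obs_rows])
    X = np.array(X_cols).T
    # reduce to independent columns for a clean log|X'V⁻¹X|
    qx, rx = np.linalg.qr(X)
    keep = np.abs(np.diag(rx)) > 1e-9 * np.abs(np.diag(rx)).max()
    X = X[:, keep] if keep.any() else X[:, :1]

    V = np.zeros((nobs, nobs))
    for k1, (r1, j1, _) in enumerate(obs_rows):
        for k2, (r2, j2, _) in enumerate(obs_rows):
            V[k1, k2] = Gfull[apos[r1] * t + j1, apos[r2] * t + j2]
            if r1 == r2:
                V[k1, k2] += R0[j1, j2]
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ b
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_v + ld_x + resid @ Vi @ resid)


def mc_selection_intensity(k: int, n: int, reps: int, rng: np.random.Generator) -> float:
    """Monte-Carlo mean of the top-k standardized order statistics of N(0,1)."""
    total = 0.0
    for _ in range(reps):
        x = rng.standard_normal(n)
        total += np.sort(x)[-k:].mean()
    return total / reps
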