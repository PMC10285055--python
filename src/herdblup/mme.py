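"""Multi-trait animal-model mixed-model equations (Henderson MME).

The observation model for each trait is

    y = herd + herd-year-season + age·b (optional) [+ country when pooled] + a + e

with a ~ N(0, A ⊗ G0) over *all* pedigree animals and record-level residuals drawn
from R0 restricted to the observed-trait pattern of the record.  The MME are

    [ X'R⁻¹X        X'R⁻¹Z                ] [b]   [X'R⁻¹y]
    [ Z'R⁻¹X   Z'R⁻¹Z + A⁻¹ ⊗ G0⁻¹       ] [a] = [Z'R⁻¹y]

where R⁻¹ for a record is the inverse of the R0 submatrix of its observed traits,
scattered back to trait coordinates (zero rows/columns for missing traits) — the
standard exact treatment of pattern-missing multi-trait data.

Because HYS is nested in herd and herd in country, the fixed part of the model is
rank-deficient by construction; a deterministic nested constraint set (one HYS level
per herd, one herd per non-last country, the last country level, plus any level
unobserved for a trait) fixes enough solutions to zero to make the system nonsingular.
Predictions of the random animal effects are invariant to this choice.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla

from .pedigree import Pedigree, RelationshipFactors

__all__ = [
    "TraitSpec",
    "VarianceComponents",
    "ModelSpec",
    "Design",
    "MMESystem",
    "EvaluationResult",
    "DEFAULT_TRAITS",
    "build_design",
    "assemble_mme",
    "solve_mme",
    "reliabilities",
    "run_evaluation",
]


@dataclass(frozen=True)
class TraitSpec:
    name: str
    uses_age_covariate: bool = True


#: the three first-lactation traits of the dairy evaluation: 305-day milk yield (kg),
#: age at first calving (months; no age covariate by definition) and first calving
#: interval (months)
DEFAULT_TRAITS = (
    TraitSpec("my305", True),
    TraitSpec("afc", False),
    TraitSpec("ci1", True),
)


def _check_spd(m: np.ndarray, name: str) -> None:
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        raise ValueError(f"{name} is not positive definite (eigenvalue {w.min():.3g})")


@dataclass
class VarianceComponents:
    """Genetic (G0) and residual (R0) trait×trait covariance matrices."""

    traits: list[str]
    G0: np.ndarray
    R0: np.ndarray

    def __post_init__(self) -> None:
        self.G0 = np.asarray(self.G0, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)
        t = len(self.traits)
        if self.G0.shape != (t, t) or self.R0.shape != (t, t):
            raise ValueError("G0/R0 shape must match the number of traits")
        _check_spd(self.G0, "G0")
        _check_spd(self.R0, "R0")

    @property
    def sigma_g(self) -> np.ndarray:
        """Genetic standard deviations per trait (the σg of the breeders' equation)."""
        return np.sqrt(np.diag(self.G0))

    def heritabilities(self) -> np.ndarray:
        return np.diag(self.G0) / (np.diag(self.G0) + np.diag(self.R0))

    def subset(self, names: list[str]) -> "VarianceComponents":
        idx = [self.traits.index(n) for n in names]
        return VarianceComponents(list(names), self.G0[np.ix_(idx, idx)],
                                  self.R0[np.ix_(idx, idx)])


@dataclass
class ModelSpec:
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    pooled: bool = False
    varcomp: VarianceComponents | None = None

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def fixed_effects(self) -> list[str]:
        return ["herd", "hys"] + (["country"] if self.pooled else [])

    def digest(self) -> str:
        parts = [f"{t.name}:{int(t.uses_age_covariate)}" for t in self.traits]
        parts.append(f"pooled={int(self.pooled)}")
        if self.varcomp is not None:
            parts.append(np.array2string(self.varcomp.G0, precision=10))
            parts.append(np.array2string(self.varcomp.R0, precision=10))
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


REQUIRED_RECORD_COLUMNS = ("animal_id", "herd", "hys")


@dataclass
class Design:
    """Per-trait incidence structures feeding :func:`assemble_mme`."""

    spec: ModelSpec
    ped: Pedigree
    n_records: int
    X: list[sparse.csr_matrix]          # per trait: records × fixed columns
    fixed_labels: list[list[tuple[str, str]]]  # per trait: (effect, level) per column
    Z: sparse.csr_matrix                # records × pedigree animals
    y: np.ndarray                       # records × traits, zero-filled where missing
    observed: np.ndarray                # records × traits boolean
    constrained_fixed: list[set[int]]   # per trait: local fixed-column indices set to zero
    age_center: float

    @property
    def n_traits(self) -> int:
        return len(self.spec.traits)


def build_design(records: pd.DataFrame, ped: Pedigree, spec: ModelSpec) -> Design:
    """Build per-trait fixed/random incidence structures and the constraint set.

    ``records`` needs columns ``animal_id, herd, hys`` (+ ``country`` when pooled,
    ``age_months`` when any trait uses the age covariate) and one column per trait;
    missing trait values are NaN/empty.  Animals without records still receive
    equations through A⁻¹, so EBVs cover the whole pedigree.
    """
    for col in REQUIRED_RECORD_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"performance table lacks required column {col!r}")
    if spec.pooled and "country" not in records.columns:
        raise ValueError("pooled model requires a 'country' column")
    missing_ids = sorted(set(records["animal_id"]) - set(ped.index))
    if missing_ids:
        raise ValueError(f"record animals absent from pedigree: {missing_ids[:10]}")

    n = len(records)
    tnames = spec.trait_names
    y = np.zeros((n, len(tnames)))
    observed = np.zeros((n, len(tnames)), dtype=bool)
    for j, t in enumerate(tnames):
        if t not in records.columns:
            raise ValueError(f"performance table lacks trait column {t!r}")
        vals = pd.to_numeric(records[t], errors="coerce").to_numpy(dtype=float)
        observed[:, j] = ~np.isnan(vals)
        if not observed[:, j].any():
            raise ValueError(f"trait column {t!r} has no observations")
        y[:, j] = np.where(observed[:, j], vals, 0.0)
    if not observed.any(axis=1).all():
        bad = records.loc[~observed.any(axis=1), "animal_id"].tolist()
        raise ValueError(f"records with no observed trait: animals {bad[:10]}")

    herd = records["herd"].astype(str).to_numpy()
    hys = records["hys"].astype(str).to_numpy()
    country = records["country"].astype(str).to_numpy() if spec.pooled else None
    herd_levels = sorted(set(herd))
    hys_levels = sorted(set(hys))
    country_levels = sorted(set(country)) if spec.pooled else []

    needs_age = any(t.uses_age_covariate for t in spec.traits)
    if needs_age:
        if "age_months" not in records.columns:
            raise ValueError("a trait uses the age covariate but 'age_months' is missing")
        age = pd.to_numeric(records["age_months"], errors="coerce").to_numpy(dtype=float)
        used = observed[:, [t.uses_age_covariate for t in spec.traits]].any(axis=1)
        if np.isnan(age[used]).any() or (age[used] <= 0).any():
            raise ValueError("age_months must be positive for records with age-covariate traits")
        age_center = float(np.nanmean(age))
        age_c = np.where(np.isnan(age), 0.0, age - age_center)
    else:
        age_center = 0.0
        age_c = np.zeros(n)

    herd_idx = {l: i for i, l in enumerate(herd_levels)}
    hys_idx = {l: i for i, l in enumerate(hys_levels)}
    ctry_idx = {l: i for i, l in enumerate(country_levels)}
    rows = np.arange(n)

    X_list, labels_list, constrained_list = [], [], []
    for j, tspec in enumerate(spec.traits):
        cols_blocks = []
        labels: list[tuple[str, str]] = []
        h_cols = sparse.coo_matrix(
            (np.ones(n), (rows, [herd_idx[v] for v in herd])), shape=(n, len(herd_levels))
        )
        cols_blocks.append(h_cols)
        labels += [("herd", l) for l in herd_levels]
        s_cols = sparse.coo_matrix(
            (np.ones(n), (rows, [hys_idx[v] for v in hys])), shape=(n, len(hys_levels))
        )
        cols_blocks.append(s_cols)
        labels += [("hys", l) for l in hys_levels]
        if spec.pooled:
            c_cols = sparse.coo_matrix(
                (np.ones(n), (rows, [ctry_idx[v] for v in country])),
                shape=(n, len(country_levels)),
            )
            cols_blocks.append(c_cols)
            labels += [("country", l) for l in country_levels]
        if tspec.uses_age_covariate:
            if spec.pooled:
                # country-nested age slopes: keeps two herdbooks without genetic
                # links exactly decoupled in the pooled solve
                for cl in country_levels:
                    col = np.where(country == cl, age_c, 0.0)
                    cols_blocks.append(sparse.coo_matrix(col.reshape(-1, 1)))
                    labels.append(("age", cl))
            else:
                cols_blocks.append(sparse.coo_matrix(age_c.reshape(-1, 1)))
                labels.append(("age", "slope"))
        X = sparse.hstack(cols_blocks).tocsr()
        labels_list.append(labels)
        X_list.append(X)
        constrained_list.append(
            _trait_constraints(tspec, labels, herd, hys, country, observed[:, j], age_c)
        )

    Z = sparse.coo_matrix(
        (np.ones(n), (rows, ped.subset_positions(records["animal_id"].astype(str)))),
        shape=(n, len(ped)),
    ).tocsr()

    return Design(spec, ped, n, X_list, labels_list, Z, y, observed,
                  constrained_list, age_center)


def _trait_constraints(tspec, labels, herd, hys, country, obs, age_c) -> set[int]:
    """Deterministic nested constraint set for one trait's fixed columns.

    Constrains (i) every level with no observation for this trait, (ii) the last
    observed HYS level within each herd, (iii) for pooled models the last observed
    country level and the last observed herd within every other country.
    """
    col_of = {lab: i for i, lab in enumerate(labels)}
    out: set[int] = set()
    herd_obs = sorted(set(herd[obs]))
    hys_obs = sorted(set(hys[obs]))

    hys_by_herd: dict[str, list[str]] = {}
    for h, s, o in zip(herd, hys, obs):
        if o:
            hys_by_herd.setdefault(h, set()).add(s)  # type: ignore[arg-type]
    for h, ss in hys_by_herd.items():
        out.add(col_of[("hys", max(ss))])

    for eff, levels_obs, all_levels in (
        ("herd", set(herd_obs), [l for e, l in labels if e == "herd"]),
        ("hys", set(hys_obs), [l for e, l in labels if e == "hys"]),
    ):
        for l in all_levels:
            if l not in levels_obs:
                out.add(col_of[(eff, l)])

    if country is not None:
        ctry_obs = sorted(set(country[obs]))
        all_ctry = [l for e, l in labels if e == "country"]
        for l in all_ctry:
            if l not in ctry_obs:
                out.add(col_of[("country", l)])
        if ctry_obs:
            out.add(col_of[("country", ctry_obs[-1])])
            herds_by_ctry: dict[str, set[str]] = {}
            for c, h, o in zip(country, herd, obs):
                if o:
                    herds_by_ctry.setdefault(c, set()).add(h)
            for c in ctry_obs[:-1]:
                out.add(col_of[("herd", max(herds_by_ctry[c]))])

    for i, (eff, lev) in enumerate(labels):
        if eff != "age":
            continue
        if lev == "slope":
            support = obs
        else:
            support = obs & (country == lev)
        col = np.where(support, age_c, 0.0)
        if np.abs(col[support]).sum() == 0:  # empty slope column for this trait
            out.add(i)
            continue
        # the slope is confounded with the contemporary groups when age does not
        # vary within any observed HYS cell (e.g. single-record cells)
        spread = 0.0
        for cell in set(hys[support]):
            vals = age_c[support & (hys == cell)]
            spread = max(spread, float(vals.max() - vals.min()))
        if spread < 1e-10 * max(1.0, float(np.abs(age_c[support]).max())):
            out.add(i)
    return out


@dataclass
class MMESystem:
    coefficient_matrix: sparse.csr_matrix
    rhs: np.ndarray
    equation_map: dict[tuple[str, str, str], int]
    constraints: set[int]
    spec: ModelSpec
    ped: Pedigree
    varcomp: VarianceComponents
    animal_offset: list[int]  # per trait, start of its animal equations
    inbreeding: np.ndarray | None = None  # per-animal F for (1+F)·σ²a scaling
    _factor: object | None = field(default=None, repr=False)

    @property
    def n_equations(self) -> int:
        return self.coefficient_matrix.shape[0]

    def factorize(self):
        if self._factor is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", sparse.SparseEfficiencyWarning)
                # the MME are SPD after constraining: symmetric-mode minimum-degree
                # ordering without pivoting cuts fill-in by orders of magnitude
                self._factor = spla.splu(
                    self.coefficient_matrix.tocsc(),
                    permc_spec="MMD_AT_PLUS_A",
                    diag_pivot_thresh=0.0,
                    options=dict(SymmetricMode=True),
                )
        return self._factor


def _pattern_rinv(R0: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Per-record scattered inverse of the R0 submatrix for each missingness pattern.

    Returns an array (n_records, t, t); rows/columns of unobserved traits are zero.
    """
    n, t = observed.shape
    out = np.zeros((n, t, t))
    patterns = {}
    for i in range(n):
        key = tuple(observed[i])
        if key not in patterns:
            idx = np.flatnonzero(observed[i])
            sub = np.linalg.inv(R0[np.ix_(idx, idx)])
            full = np.zeros((t, t))
            full[np.ix_(idx, idx)] = sub
            patterns[key] = full
        out[i] = patterns[key]
    return out


def assemble_mme(design: Design, relfac: RelationshipFactors,
                 varcomp: VarianceComponents) -> MMESystem:
    """Assemble the symmetric MME coefficient matrix and right-hand side.

    Equation layout: all fixed columns of trait 1, trait 2, …, then the animal
    equations of trait 1, trait 2, … (each over the full pedigree), so the genetic
    part adds G0⁻¹[t1,t2]·A⁻¹ to each animal block pair.
    """
    spec = design.spec
    tnames = spec.trait_names
    if varcomp.traits != tnames:
        varcomp = varcomp.subset(tnames)
    try:
        g0_inv = np.linalg.inv(varcomp.G0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by _check_spd
        raise ValueError("G0 is singular") from exc

    t = len(tnames)
    m = len(design.ped)
    rinv = _pattern_rinv(varcomp.R0, design.observed)  # (n, t, t)
    Z = design.Z

    blocks = [[None] * (2 * t) for _ in range(2 * t)]
    a_inv = relfac.a_inverse
    for t1 in range(t):
        for t2 in range(t):
            d = sparse.diags(rinv[:, t1, t2])
            X1, X2 = design.X[t1], design.X[t2]
            blocks[t1][t2] = (X1.T @ d @ X2).tocsr()
            blocks[t1][t + t2] = (X1.T @ d @ Z).tocsr()
            blocks[t + t1][t2] = (Z.T @ d @ X2).tocsr()
            aa = (Z.T @ d @ Z).tocsr() + g0_inv[t1, t2] * a_inv
            blocks[t + t1][t + t2] = aa
    C = sparse.bmat(blocks, format="csr")

    rhs_parts = []
    for t1 in range(t):
        acc = np.zeros(design.X[t1].shape[1])
        for t2 in range(t):
            acc += design.X[t1].T @ (rinv[:, t1, t2] * design.y[:, t2])
        rhs_parts.append(acc)
    for t1 in range(t):
        acc = np.zeros(m)
        for t2 in range(t):
            acc += Z.T @ (rinv[:, t1, t2] * design.y[:, t2])
        rhs_parts.append(acc)
    rhs = np.concatenate(rhs_parts)

    # global equation map and constraint indices
    equation_map: dict[tuple[str, str, str], int] = {}
    constraints: set[int] = set()
    offset = 0
    fixed_offsets = []
    for t1, tname in enumerate(tnames):
        fixed_offsets.append(offset)
        for j, (eff, lev) in enumerate(design.fixed_labels[t1]):
            equation_map[(eff, lev, tname)] = offset + j
        for j in design.constrained_fixed[t1]:
            constraints.add(offset + j)
        offset += design.X[t1].shape[1]
    animal_offset = []
    for t1, tname in enumerate(tnames):
        animal_offset.append(offset)
        for i, a in enumerate(design.ped.animals):
            equation_map[("animal", a, tname)] = offset + i
        offset += m

    C, rhs = _apply_constraints(C, rhs, constraints)
    return MMESystem(C, rhs, equation_map, constraints, spec, design.ped,
                     varcomp, animal_offset, inbreeding=relfac.inbreeding)


def _apply_constraints(C: sparse.csr_matrix, rhs: np.ndarray,
                       constraints: set[int]) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Zero constrained rows/columns and pin their solutions to 0 via a unit diagonal."""
    if not constraints:
        return C, rhs
    n = C.shape[0]
    keep = np.ones(n)
    idx = np.fromiter(constraints, dtype=np.int64)
    keep[idx] = 0.0
    P = sparse.diags(keep)
    C = (P @ C @ P + sparse.diags(1.0 - keep)).tocsr()
    rhs = rhs * keep
    return C, rhs


def solve_mme(system: MMESystem, method: str = "direct", tol: float = 1e-10,
              max_iter: int = 5000) -> tuple[np.ndarray, dict]:
    """Solve the assembled MME.

    ``direct`` uses a sparse LU factorization (cached on the system for later
    reliability computation); ``pcg`` uses conjugate gradients with diagonal
    preconditioning.  Both check the relative residual against ``tol``.
    """
    C, rhs = system.coefficient_matrix, system.rhs
    if method == "direct":
        x = system.factorize().solve(rhs)
    elif method == "pcg":
        d = C.diagonal()
        M = sparse.diags(1.0 / np.where(d > 0, d, 1.0))
        x, info = spla.cg(C, rhs, rtol=min(tol, 1e-12), atol=0.0, maxiter=max_iter, M=M)
        if info > 0:
            res = np.linalg.norm(C @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise RuntimeError(
                f"PCG did not converge in {max_iter} iterations (relative residual {res:.3g})"
            )
    else:
        raise ValueError(f"unknown solver method {method!r}")
    denom = np.linalg.norm(rhs)
    residual = float(np.linalg.norm(C @ x - rhs) / (denom if denom > 0 else 1.0))
    if residual > max(tol, 1e-8):
        raise RuntimeError(f"solver residual {residual:.3g} exceeds tolerance")
    return x, {"method": method, "relative_residual": residual}


def reliabilities(system: MMESystem, animals=None,
                  chunk: int = 64) -> pd.DataFrame:
    """Exact PEV, reliability and accuracy for the requested animals (all by default).

    PEV_it is the diagonal of the inverse constrained coefficient matrix at the
    animal×trait equation, obtained by unit-vector solves against the cached sparse
    factorization; r²_it = 1 − PEV_it/((1+F_i)·σ²_a,t) and accuracy = √r² — the
    (1+F_i) factor is the inbred animal's own genetic variance.
    """
    ped = system.ped
    if animals is None:
        animals = list(ped.animals)
    else:
        animals = list(animals)
        missing = [a for a in animals if ("animal", a, system.spec.trait_names[0])
                   not in system.equation_map]
        if missing:
            raise KeyError(f"animals without equations: {missing[:10]}")
    tnames = system.spec.trait_names
    sigma2 = np.diag(system.varcomp.G0)
    lu = system.factorize()

    eq_idx = np.array(
        [system.equation_map[("animal", a, tn)] for a in animals for tn in tnames],
        dtype=np.int64,
    )
    pev = np.empty(len(eq_idx))
    n = system.n_equations
    for start in range(0, len(eq_idx), chunk):
        cols = eq_idx[start:start + chunk]
        E = np.zeros((n, len(cols)))
        E[cols, np.arange(len(cols))] = 1.0
        S = lu.solve(E)
        pev[start:start + chunk] = S[cols, np.arange(len(cols))]

    f = system.inbreeding if system.inbreeding is not None else np.zeros(len(ped))
    rows = []
    k = 0
    for a in animals:
        fi = f[ped.index[a]]
        for j, tn in enumerate(tnames):
            s2 = (1.0 + fi) * sigma2[j]
            p = min(max(pev[k], 0.0), s2)
            r2 = 1.0 - p / s2
            rows.append((a, tn, p, r2, np.sqrt(r2)))
            k += 1
    return pd.DataFrame(rows, columns=["animal_id", "trait", "pev", "reliability",
                                       "accuracy"])


@dataclass
class EvaluationResult:
    """EBVs, reliabilities and fixed-effect solutions from one fitted model."""

    tag: str
    ebv: pd.DataFrame          # long: animal_id, trait, ebv
    reliability: pd.DataFrame  # long: animal_id, trait, pev, reliability, accuracy
    fixed_effects: pd.DataFrame  # effect, level, trait, estimate
    spec_digest: str
    diagnostics: dict

    def table(self) -> pd.DataFrame:
        """EBVs joined with reliabilities, the results-TSV layout."""
        out = self.ebv.merge(self.reliability, on=["animal_id", "trait"], how="left")
        out["model_tag"] = self.tag
        return out

    def ebv_series(self, trait: str) -> pd.Series:
        sub = self.ebv[self.ebv["trait"] == trait]
        return pd.Series(sub["ebv"].to_numpy(), index=sub["animal_id"].to_numpy())

    def accuracy_series(self, trait: str) -> pd.Series:
        sub = self.reliability[self.reliability["trait"] == trait]
        return pd.Series(sub["accuracy"].to_numpy(), index=sub["animal_id"].to_numpy())


def run_evaluation(records: pd.DataFrame, ped: Pedigree, spec: ModelSpec,
                   relfac: RelationshipFactors | None = None,
                   tag: str | None = None,
                   method: str = "direct",
                   reliability_animals="all") -> EvaluationResult:
    """Design → assembly → solve → reliabilities for one dataset.

    ``reliability_animals`` is ``"all"``, ``None`` (skip) or an iterable of ids —
    at herdbook scale restricting it to the sire list keeps the exact PEV solves cheap.
    """
    if spec.varcomp is None:
        raise ValueError(
            "no variance components supplied: provide ModelSpec.varcomp or estimate "
            "them first with varcomp.em_reml"
        )
    from .pedigree import build_a_inverse

    if relfac is None:
        relfac = build_a_inverse(ped)
    design = build_design(records, ped, spec)
    system = assemble_mme(design, relfac, spec.varcomp)
    x, diag = solve_mme(system, method=method)

    tnames = spec.trait_names
    ebv_rows = []
    for j, tn in enumerate(tnames):
        off = system.animal_offset[j]
        for i, a in enumerate(ped.animals):
            ebv_rows.append((a, tn, x[off + i]))
    ebv = pd.DataFrame(ebv_rows, columns=["animal_id", "trait", "ebv"])

    fe_rows = []
    for (eff, lev, tn), idx in system.equation_map.items():
        if eff != "animal":
            fe_rows.append((eff, lev, tn, x[idx]))
    fixed = pd.DataFrame(fe_rows, columns=["effect", "level", "trait", "estimate"])

    if reliability_animals is None:
        rel = pd.DataFrame(columns=["animal_id", "trait", "pev", "reliability",
                                    "accuracy"])
    elif isinstance(reliability_animals, str) and reliability_animals == "all":
        rel = reliabilities(system)
    else:
        rel = reliabilities(system, animals=reliability_animals)

    tag = tag or ("multi-country" if spec.pooled else "within-country")
    return EvaluationResult(tag, ebv, rel, fixed, spec.digest(), diag)
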