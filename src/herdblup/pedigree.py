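"""Pedigree handling and numerator-relationship machinery.

The random animal effect of the evaluation model is distributed a ~ N(0, A σ²_a)
where A is the numerator relationship matrix implied by the pedigree.  The mixed-model
equations only ever need A⁻¹, which is sparse and can be written down directly from
the pedigree by Henderson's rules; the dense A itself (tabular method) is kept as a
small-scale oracle.

Inbreeding coefficients F are computed with the Meuwissen & Luo algorithm, i.e. from
the Cholesky decomposition A = L D L' where L traces gene flow through the pedigree
and D holds the Mendelian-sampling variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "RelationshipFactors",
    "PedigreeError",
    "read_pedigree",
    "pedigree_from_frame",
    "write_pedigree",
    "compute_inbreeding",
    "build_a_inverse",
    "tabular_a_matrix",
]

#: encodings accepted for an unknown parent (configurable via read_pedigree)
DEFAULT_UNKNOWN = ("", "0", "NA")

#: animals above this count make the dense tabular A an oracle-only tool
DENSE_LIMIT = 5000


class PedigreeError(ValueError):
    """Raised for structural problems: duplicate ids, parentage cycles, sex conflicts."""


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: str | None  # None encodes an unknown parent
    dam_id: str | None


@dataclass
class Pedigree:
    """A validated pedigree in parent-before-offspring order.

    ``sire`` / ``dam`` hold integer positions into the ordered animal list,
    with -1 for an unknown parent.
    """

    animals: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {a: i for i, a in enumerate(self.animals)}

    def __len__(self) -> int:
        return len(self.animals)

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def records(self) -> list[PedigreeRecord]:
        out = []
        for i, a in enumerate(self.animals):
            s = self.animals[self.sire[i]] if self.sire[i] >= 0 else None
            d = self.animals[self.dam[i]] if self.dam[i] >= 0 else None
            out.append(PedigreeRecord(a, s, d))
        return out

    def subset_positions(self, ids) -> np.ndarray:
        missing = [a for a in ids if a not in self.index]
        if missing:
            raise PedigreeError(f"animals absent from pedigree: {missing[:10]}")
        return np.array([self.index[a] for a in ids], dtype=np.int64)


@dataclass
class RelationshipFactors:
    """Per-animal inbreeding plus the sparse symmetric A-inverse (CSR)."""

    inbreeding: np.ndarray
    a_inverse: sparse.csr_matrix


def _normalize_parent(value, unknown_codes) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if text in unknown_codes or text.lower() == "nan":
        return None
    return text


def pedigree_from_frame(
    frame: pd.DataFrame,
    dialect: dict[str, str] | None = None,
    unknown_codes=DEFAULT_UNKNOWN,
) -> Pedigree:
    """Validate and topologically order an animal/sire/dam table.

    Animals that appear only as parents are materialized as founders.  Raises
    :class:`PedigreeError` on duplicate ids, parentage cycles, self-parentage,
    or an id used both as a sire and as a dam.
    """
    dialect = dialect or {}
    cols = {k: dialect.get(k, k) for k in ("animal_id", "sire_id", "dam_id")}
    for logical, actual in cols.items():
        if actual not in frame.columns:
            raise PedigreeError(f"missing required column {actual!r} (for {logical})")

    parents: dict[str, tuple[str | None, str | None]] = {}
    declared: list[str] = []
    as_sire: set[str] = set()
    as_dam: set[str] = set()
    for row in frame.itertuples(index=False):
        a = _normalize_parent(getattr(row, cols["animal_id"]), unknown_codes)
        if a is None:
            raise PedigreeError("empty animal_id in pedigree file")
        if a in parents:
            raise PedigreeError(f"duplicate animal_id {a!r}")
        s = _normalize_parent(getattr(row, cols["sire_id"]), unknown_codes)
        d = _normalize_parent(getattr(row, cols["dam_id"]), unknown_codes)
        if a == s or a == d:
            raise PedigreeError(f"animal {a!r} listed as its own parent")
        parents[a] = (s, d)
        declared.append(a)
        if s is not None:
            as_sire.add(s)
        if d is not None:
            as_dam.add(d)

    both = as_sire & as_dam
    if both:
        raise PedigreeError(f"ids used both as sire and dam: {sorted(both)[:10]}")

    # materialize parent-only animals as founders, in first-appearance order
    for a in declared:
        for p in parents[a]:
            if p is not None and p not in parents:
                parents[p] = (None, None)

    order = _topological_order(parents)
    sire = np.full(len(order), -1, dtype=np.int64)
    dam = np.full(len(order), -1, dtype=np.int64)
    pos = {a: i for i, a in enumerate(order)}
    for a, (s, d) in parents.items():
        i = pos[a]
        if s is not None:
            sire[i] = pos[s]
        if d is not None:
            dam[i] = pos[d]
    return Pedigree(order, sire, dam)


def _topological_order(parents: dict[str, tuple[str | None, str | None]]) -> list[str]:
    """Kahn's algorithm over the parent→offspring DAG; deterministic, cycle-checked."""
    ids = list(parents)
    children: dict[str, list[str]] = {a: [] for a in ids}
    indeg = {a: 0 for a in ids}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    ready = [a for a in ids if indeg[a] == 0]
    out: list[str] = []
    while ready:
        a = ready.pop(0)
        out.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(out) != len(ids):
        stuck = next(a for a in ids if indeg[a] > 0)
        raise PedigreeError(f"cycle in parentage involving {stuck!r}")
    return out


def read_pedigree(path, dialect: dict[str, str] | None = None,
                  unknown_codes=DEFAULT_UNKNOWN) -> Pedigree:
    """Read a pedigree CSV (`animal_id,sire_id,dam_id`) and return it ordered."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return pedigree_from_frame(frame, dialect=dialect, unknown_codes=unknown_codes)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the ordered pedigree with its `order` column (unknown parents as '0')."""
    rows = []
    for i, rec in enumerate(ped.records()):
        rows.append((rec.animal_id, rec.sire_id or "0", rec.dam_id or "0", i))
    pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "order"]).to_csv(
        path, index=False
    )


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Meuwissen–Luo inbreeding coefficients.

    For each animal i the row L[i, :] of A = L D L' is accumulated by tracing
    ancestors, and F_i = Σ_j L_ij² d_j − 1.
    """
    n = len(ped)
    f = np.zeros(n)
    d = np.zeros(n)  # Mendelian-sampling variances, filled in pedigree order
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, dm = sire[i], dam[i]
        fs = f[s] if s >= 0 else -1.0  # -1 encodes the unknown-parent base draw
        fd = f[dm] if dm >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 and dm < 0:
            f[i] = 0.0
            continue
        # accumulate L-row contributions ancestor by ancestor (highest position first)
        row = {i: 1.0}
        acc = 0.0
        while row:
            j = max(row)
            lj = row.pop(j)
            acc += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    row[p] = row.get(p, 0.0) + 0.5 * lj
        f[i] = acc - 1.0
    return f


def build_a_inverse(ped: Pedigree, use_inbreeding: bool = True) -> RelationshipFactors:
    """Assemble the sparse A-inverse by Henderson's rules.

    Each animal contributes at most 9 entries built from the inverse Mendelian-sampling
    variance b_i = 1/d_i with d_i = 0.5 − 0.25 (F_s + F_d) (unknown parents enter with
    F = −1, giving d = 0.75 for one known parent and 1 for none).  ``use_inbreeding=False``
    assumes F ≡ 0, matching evaluations that ignore inbreeding.
    """
    n = len(ped)
    f = compute_inbreeding(ped) if use_inbreeding else np.zeros(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[dm] if dm >= 0 else -1.0
        b = 1.0 / (0.5 - 0.25 * (fs + fd))
        add(i, i, b)
        for p in (s, dm):
            if p >= 0:
                add(i, p, -b / 2)
                add(p, i, -b / 2)
        for p in (s, dm):
            for q in (s, dm):
                if p >= 0 and q >= 0:
                    add(p, q, b / 4)
    a_inv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipFactors(inbreeding=f, a_inverse=a_inv)


def tabular_a_matrix(ped: Pedigree, dense_limit: int = DENSE_LIMIT) -> np.ndarray:
    """Dense A by the recursive tabular method (oracle; small pedigrees only).

    a_ij = 0.5 (a_{s(i),j} + a_{d(i),j}) for j < i and a_ii = 1 + 0.5 a_{s(i),d(i)}.
    """
    n = len(ped)
    if n > dense_limit:
        raise PedigreeError(
            f"pedigree of {n} animals exceeds dense limit {dense_limit}; "
            "tabular A is an oracle for small pedigrees — use build_a_inverse instead"
        )
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * a[s, :i]
            if d >= 0:
                row += 0.5 * a[d, :i]
            a[i, :i] = row
            a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if s >= 0 and d >= 0 else 0.0)
    return a
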