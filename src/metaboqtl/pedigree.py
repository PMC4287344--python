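"""Multigeneration pedigree simulation and pedigree-based kinship.

The simulated design emulates a genetic-isolate family study: a small
number of founder couples, several generations of descendants, and
married-in spouses treated as unrelated founders.  Households are full
sibships (all children of one couple share a household), which is the
structure the shared-environment ("household") variance component acts on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, PedigreeError

MALE = "male"
FEMALE = "female"

#: Sentinel for a missing parent (founder).
MISSING = ""


@dataclass(frozen=True)
class Pedigree:
    """A validated pedigree table.

    ``table`` is indexed by individual id with columns ``father``,
    ``mother`` (empty string for founders), ``sex`` (``"male"``/
    ``"female"``), ``household`` and ``generation`` (non-negative int,
    strictly greater than both parents' generations).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_pedigree(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def founder_ids(self) -> list[str]:
        t = self.table
        return list(t.index[(t["father"] == MISSING) & (t["mother"] == MISSING)])

    @property
    def descendant_ids(self) -> list[str]:
        """Individuals with both parents in the pedigree (non-founders)."""
        t = self.table
        return list(t.index[(t["father"] != MISSING) & (t["mother"] != MISSING)])

    def sex_code(self, ids: list[str] | None = None) -> np.ndarray:
        """0/1 indicator of female sex (0 = male) for ``ids``."""
        sx = self.table["sex"] if ids is None else self.table.loc[ids, "sex"]
        return (sx == FEMALE).to_numpy(dtype=float)


def validate_pedigree(table: pd.DataFrame) -> None:
    required = {"father", "mother", "sex", "household", "generation"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise PedigreeError(f"pedigree table lacks columns: {sorted(missing_cols)}")
    if table.index.has_duplicates:
        raise PedigreeError("duplicate individual ids")
    ids = set(table.index)
    gen = table["generation"]
    if (gen < 0).any():
        raise PedigreeError("negative generation")
    for col in ("father", "mother"):
        parents = table[col]
        present = parents != MISSING
        unknown = set(parents[present]) - ids
        if unknown:
            raise PedigreeError(f"{col} ids not in pedigree: {sorted(unknown)[:5]}")
        pg = gen.reindex(parents[present]).to_numpy()
        if not (pg < gen[present].to_numpy()).all():
            raise PedigreeError(
                "parental generation must be strictly smaller than the child's "
                "(self-ancestry or inconsistent generations)"
            )
    has_f = table["father"] != MISSING
    has_m = table["mother"] != MISSING
    if (has_f != has_m).any():
        raise PedigreeError("non-founders must have both parents present")


def simulate_pedigree(
    n_founder_couples: int,
    n_generations: int,
    mean_children: float,
    seed: int,
    child_dist: str = "poisson",
) -> Pedigree:
    """Simulate an isolate-style pedigree from founder couples.

    Every couple in a non-final generation has at least one child
    (zero-truncated Poisson with mean parameter ``mean_children``) so the
    pedigree stays connected; children of non-final generations marry
    unrelated, married-in spouses who are recorded as founders of that
    generation.  All full siblings share one household; founders and
    spouses each get a singleton household.

    Parameters
    ----------
    child_dist:
        ``"poisson"`` (default) draws child counts from a zero-truncated
        Poisson; ``"fixed"`` gives every couple exactly
        ``round(mean_children)`` children (deterministic structure).
    """
    if n_founder_couples < 1 or n_generations < 1:
        raise InvalidArgumentError("n_founder_couples and n_generations must be >= 1")
    if mean_children < 0:
        raise InvalidArgumentError("mean_children must be >= 0")
    if child_dist not in ("poisson", "fixed"):
        raise InvalidArgumentError(f"unknown child_dist {child_dist!r}")

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, str, str, int]] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    def add(iid, father, mother, sex, household, generation):
        rows.append((iid, father, mother, sex, household, generation))

    couples: list[tuple[str, str]] = []
    for _ in range(n_founder_couples):
        f, m = new_id(), new_id()
        add(f, MISSING, MISSING, MALE, f"H_{f}", 0)
        add(m, MISSING, MISSING, FEMALE, f"H_{m}", 0)
        couples.append((f, m))

    for g in range(1, n_generations + 1):
        next_couples: list[tuple[str, str]] = []
        for father, mother in couples:
            if mean_children == 0:
                k = 0
            elif child_dist == "fixed":
                k = int(round(mean_children))
            else:
                k = int(rng.poisson(mean_children))
                while k == 0:  # zero-truncation keeps the pedigree connected
                    k = int(rng.poisson(mean_children))
            household = f"H_{father}x{mother}"
            for _ in range(k):
                child = new_id()
                sex = MALE if rng.random() < 0.5 else FEMALE
                add(child, father, mother, sex, household, g)
                if g < n_generations:
                    spouse = new_id()
                    spouse_sex = FEMALE if sex == MALE else MALE
                    add(spouse, MISSING, MISSING, spouse_sex, f"H_{spouse}", g)
                    pair = (child, spouse) if sex == MALE else (spouse, child)
                    next_couples.append(pair)
        couples = next_couples

    table = pd.DataFrame(
        rows, columns=["iid", "father", "mother", "sex", "household", "generation"]
    ).set_index("iid")
    return Pedigree(table)


@dataclass(frozen=True)
class KinshipMatrix:
    """Pairwise kinship coefficients phi over a fixed id order.

    ``values[i, j]`` is the probability that one allele drawn from
    individual i and one from j are identical by descent; the additive
    genetic relationship matrix is ``2 * values``.
    """

    values: np.ndarray = field(repr=False)
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise MatrixShapeError("kinship matrix shape inconsistent with ids")

    @property
    def index(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.ids)}

    def additive(self) -> np.ndarray:
        """The additive relationship matrix 2*Phi."""
        return 2.0 * self.values

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        pos = self.index
        rows = np.array([pos[i] for i in ids])
        return KinshipMatrix(self.values[np.ix_(rows, rows)], tuple(ids))


class MatrixShapeError(PedigreeError):
    pass


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Kinship by the recursive tabular method in generation order.

    phi(i, j) = (phi(f_i, j) + phi(m_i, j)) / 2 for j processed before i,
    and phi(i, i) = (1 + phi(f_i, m_i)) / 2, so inbreeding from related
    parents propagates automatically.  Founders are unrelated by
    definition.
    """
    t = ped.table
    order = t.sort_values("generation", kind="stable")
    ids = list(order.index)
    pos = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n))
    fathers = order["father"].to_numpy()
    mothers = order["mother"].to_numpy()
    for i in range(n):
        fa, mo = fathers[i], mothers[i]
        if fa == MISSING:
            K[i, i] = 0.5
            continue
        fi, mi = pos[fa], pos[mo]
        if fi >= i or mi >= i:
            raise PedigreeError("pedigree is not processable in generation order")
        row = 0.5 * (K[fi, :i] + K[mi, :i])
        K[i, :i] = row
        K[:i, i] = row
        K[i, i] = 0.5 * (1.0 + K[fi, mi])
    # restore the pedigree's original id order
    perm = np.array([pos[i] for i in ped.ids])
    return KinshipMatrix(K[np.ix_(perm, perm)], tuple(ped.ids))


def household_indicator(ped: Pedigree, ids: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Sample-by-household 0/1 indicator Z (household matrix is Z Z^T)."""
    ids = list(ped.ids) if ids is None else list(ids)
    hh = ped.table.loc[ids, "household"]
    labels = list(dict.fromkeys(hh))
    col = {h: j for j, h in enumerate(labels)}
    Z = np.zeros((len(ids), len(labels)))
    for i, h in enumerate(hh):
        Z[i, col[h]] = 1.0
    return Z, labels


def household_matrix(ped: Pedigree, ids: list[str] | None = None) -> np.ndarray:
    """Square 0/1 matrix: 1 iff two individuals share a household."""
    Z, _ = household_indicator(ped, ids)
    return Z @ Z.T
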