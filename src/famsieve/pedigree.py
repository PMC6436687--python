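"""Pedigree representation and founder-allele sharing.

The central quantity is the probability that every member of a set of
relatives carries a single allele introduced by one founder, conditioned on
a designated *reference* member carrying it.  For a pedigree without
inbreeding loops this has a closed form: if the union of transmission paths
from the founder to the members (their Steiner tree) contains ``m`` meioses
and the founder-to-reference path contains ``d`` of them, the conditional
sharing probability is ``2**-(m - d)``.  Two siblings referenced on one of
them share 1/2; first cousins through one grandparent share 1/4.

A gene-dropping Monte-Carlo (one founder allele transmitted with
probability 1/2 per meiosis) serves as an independent oracle for the closed
form and handles inbred, multi-path pedigrees that the closed form rejects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "SharedFractionResult",
    "PedigreeError",
    "UnsupportedPedigreeError",
    "parse_ped",
    "write_ped",
    "expected_shared_fraction",
    "gene_drop",
    "gene_drop_replicates",
    "shared_fraction",
]

SEXES = ("male", "female", "unknown")
AFFECTIONS = ("affected", "unaffected", "unknown")

_PED_SEX = {"1": "male", "2": "female"}
_PED_AFFECTION = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_SEX_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFFECTION_PED = {"unaffected": "1", "affected": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate id, cycle, half parents...)."""


class UnsupportedPedigreeError(PedigreeError):
    """Pedigree outside the closed form's domain (multiple transmission paths)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids are ``None`` for founders."""

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.affection not in AFFECTIONS:
            raise ValueError(f"invalid affection {self.affection!r}")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id!r} has only one parent specified; "
                "give both or neither"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass(frozen=True)
class SharedFractionResult:
    """Closed-form conditional sharing: ``fraction == 2**-(meioses - depth)``."""

    fraction: float
    meioses: int
    reference_depth: int


class Pedigree:
    """A validated acyclic pedigree with unique ids and fully-specified parents."""

    def __init__(self, individuals: Iterable[Individual], family_id: str = "FAM"):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        for ind in self._members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._members:
                    raise PedigreeError(
                        f"parent {pid!r} of {ind.id!r} is not in the pedigree"
                    )
        self._order = self._topological_order()
        if not self.founders:
            raise PedigreeError("pedigree has no founder")

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    @property
    def members(self) -> list[Individual]:
        return [self._members[i] for i in self._order]

    @property
    def ids(self) -> list[str]:
        return list(self._order)

    @property
    def founders(self) -> list[str]:
        return [i for i in self._order if self._members[i].is_founder]

    def children_of(self, iid: str) -> list[str]:
        return [
            i
            for i in self._order
            if self._members[i].father_id == iid or self._members[i].mother_id == iid
        ]

    def affection_counts(self) -> dict[str, int]:
        counts = {a: 0 for a in AFFECTIONS}
        for ind in self._members.values():
            counts[ind.affection] += 1
        return counts

    def by_affection(self, affection: str) -> list[str]:
        return [i for i in self._order if self._members[i].affection == affection]

    # -- structure ---------------------------------------------------------

    def _topological_order(self) -> list[str]:
        """Parents-before-children order; raises on cycles."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    "pedigree contains a cycle through " + " -> ".join(stack + [iid])
                )
            state[iid] = 0
            ind = self._members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1
            order.append(iid)

        for iid in sorted(self._members):
            visit(iid, [])
        return order

    def transmission_path(self, founder: str, member: str) -> list[str]:
        """The unique founder→member path of ids, founder first.

        Raises :class:`PedigreeError` if the founder is not an ancestor and
        :class:`UnsupportedPedigreeError` if more than one path exists
        (inbreeding loop), which puts the pedigree outside the closed form.
        """
        if founder not in self._members:
            raise PedigreeError(f"unknown founder id {founder!r}")
        if member not in self._members:
            raise PedigreeError(f"unknown member id {member!r}")

        paths: list[list[str]] = []

        def climb(iid: str, below: list[str]) -> None:
            if iid == founder:
                paths.append([founder] + below)
                return
            ind = self._members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    climb(pid, [iid] + below)

        climb(member, [])
        if not paths:
            raise PedigreeError(f"{founder!r} is not an ancestor of {member!r}")
        if len(paths) > 1:
            raise UnsupportedPedigreeError(
                f"multiple transmission paths from {founder!r} to {member!r}; "
                "use gene_drop for inbred pedigrees"
            )
        return paths[0]


# ---------------------------------------------------------------------------
# PED file I/O (6-column whitespace-delimited dialect)
# ---------------------------------------------------------------------------


def parse_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (fam, id, father, mother, sex, phenotype).

    Phenotype codes: 1 = unaffected, 2 = affected, 0 or -9 = unknown.
    Parent id 0 means missing; both parents must be given or both missing.
    """
    path = Path(path)
    individuals: list[Individual] = []
    family_id = "FAM"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PedigreeError(
                    f"{path.name}:{lineno}: expected 6 columns, found {len(fields)}"
                )
            fam, iid, father, mother, sex, pheno = fields
            family_id = fam
            if pheno not in _PED_AFFECTION:
                raise PedigreeError(
                    f"{path.name}:{lineno}: invalid phenotype code {pheno!r}"
                )
            individuals.append(
                Individual(
                    id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_PED_SEX.get(sex, "unknown"),
                    affection=_PED_AFFECTION[pheno],
                )
            )
    return Pedigree(individuals, family_id=family_id)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind in ped.members:
            fh.write(
                "\t".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_PED[ind.sex],
                        _AFFECTION_PED[ind.affection],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expected shared fraction (closed form)
# ---------------------------------------------------------------------------


def expected_shared_fraction(
    ped: Pedigree,
    members: Iterable[str],
    founder: str,
    reference: str,
) -> SharedFractionResult:
    """Probability all ``members`` carry a founder allele given ``reference`` does.

    ``m`` counts the meioses in the union of founder→member transmission
    paths and ``d`` the founder→reference depth; the result is
    ``2**-(m - d)``.  Requires unique transmission paths (no inbreeding
    loops); otherwise :class:`UnsupportedPedigreeError` is raised and
    :func:`gene_drop` should be used instead.
    """
    member_set = set(members)
    if reference not in member_set:
        raise ValueError("reference must be one of the members")
    edges: set[tuple[str, str]] = set()
    for m in member_set:
        path = ped.transmission_path(founder, m)
        edges.update(zip(path, path[1:]))
    ref_depth = len(ped.transmission_path(founder, reference)) - 1
    m_total = len(edges)
    return SharedFractionResult(
        fraction=2.0 ** -(m_total - ref_depth),
        meioses=m_total,
        reference_depth=ref_depth,
    )


# ---------------------------------------------------------------------------
# Gene dropping (Monte-Carlo oracle)
# ---------------------------------------------------------------------------


def gene_drop_replicates(
    ped: Pedigree,
    founder: str,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], np.ndarray]:
    """Drop one founder allele through the pedigree ``n_replicates`` times.

    The founder is heterozygous for a tracked allele; each meiosis transmits
    it with probability 1/2.  Returns the id order and a boolean array of
    shape (n_replicates, n_individuals) of carrier status.  Handles inbred
    pedigrees (a child of two carriers can inherit from either).
    """
    if founder not in ped:
        raise PedigreeError(f"unknown founder id {founder!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = ped.ids
    index = {iid: k for k, iid in enumerate(ids)}
    carriers = np.zeros((n_replicates, len(ids)), dtype=bool)
    carriers[:, index[founder]] = True
    for iid in ids:  # topological: parents precede children
        ind = ped[iid]
        if ind.is_founder or iid == founder:
            continue
        f = carriers[:, index[ind.father_id]]
        m = carriers[:, index[ind.mother_id]]
        from_father = f & (rng.random(n_replicates) < 0.5)
        from_mother = m & (rng.random(n_replicates) < 0.5)
        carriers[:, index[iid]] = from_father | from_mother
    return ids, carriers


def gene_drop(
    ped: Pedigree,
    founder: str,
    n_replicates: int,
    seed: int = 0,
) -> dict[str, float]:
    """Per-individual carrier probability of one founder allele (Monte Carlo)."""
    ids, carriers = gene_drop_replicates(ped, founder, n_replicates, seed)
    freqs = carriers.mean(axis=0)
    return {iid: float(freqs[k]) for k, iid in enumerate(ids)}


def shared_fraction(
    ped: Pedigree,
    members: Iterable[str],
    founder: str,
    reference: str,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> float:
    """Conditional sharing probability; Monte-Carlo fallback for inbred pedigrees.

    Uses the closed form when the pedigree admits unique transmission paths
    and otherwise estimates P(all members carry | reference carries) by
    gene dropping.
    """
    member_set = set(members)
    try:
        return expected_shared_fraction(ped, member_set, founder, reference).fraction
    except UnsupportedPedigreeError:
        ids, carriers = gene_drop_replicates(ped, founder, n_replicates, seed)
        index = {iid: k for k, iid in enumerate(ids)}
        ref = carriers[:, index[reference]]
        if not ref.any():
            return float("nan")
        cols = [index[m] for m in member_set]
        all_carry = carriers[:, cols].all(axis=1)
        return float(all_carry[ref].mean())


def shared_fraction_table(
    ped: Pedigree,
    prefixes: Sequence[Sequence[str]],
    founder: str,
    reference: str,
) -> list[SharedFractionResult]:
    """Closed-form results for nested member sets (curve x-axis helper)."""
    return [
        expected_shared_fraction(ped, prefix, founder, reference)
        for prefix in prefixes
    ]
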