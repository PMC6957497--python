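"""Pedigree structures: parsing, validation, division, nuclear-family extraction.

A pedigree is a directed acyclic family structure over named individuals.
Files follow the 6-column pre-makeped LINKAGE / PLINK ``.fam`` dialect
(family id, individual id, father id, mother id, sex, phenotype), whitespace
delimited, with ``0`` denoting a missing parent.

The ancestry model downstream is autosomal and sex-agnostic; sex is parsed
and carried but never used in any computation.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def from_code(cls, code: str) -> "Sex":
        return {"1": cls.MALE, "2": cls.FEMALE}.get(code, cls.UNKNOWN)

    def to_code(self) -> str:
        return {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[self]


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids are ``None`` when unrecorded."""

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    genotyped: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("individual id must be nonempty")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(p for p in (self.father_id, self.mother_id) if p is not None)


class FamilyType(enum.Enum):
    TWO_PARENT = "two_parent"
    ONE_PARENT = "one_parent"


@dataclass(frozen=True)
class NuclearFamily:
    """Parent(s) plus a sibship of m >= 1 children, used as the unit for
    Mendelian-error counting and allelic error-rate estimation."""

    parent_ids: tuple[str, ...]
    child_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.parent_ids) <= 2:
            raise ValueError("a nuclear family has 1 or 2 parents")
        if len(self.child_ids) < 1:
            raise ValueError("a nuclear family has at least one child")

    @property
    def type(self) -> FamilyType:
        return FamilyType.TWO_PARENT if len(self.parent_ids) == 2 else FamilyType.ONE_PARENT

    @property
    def m(self) -> int:
        return len(self.child_ids)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return self.parent_ids + self.child_ids


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """An ordered collection of individuals with resolved parent links."""

    name: str
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            seen: set[str] = set()
            for ind in self.individuals:
                if ind.id in seen:
                    raise PedigreeError(
                        f"duplicate individual id {ind.id!r} in pedigree {self.name!r}"
                    )
                seen.add(ind.id)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[self._index[iid]]

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals
            if iid in (ind.father_id, ind.mother_id)
        ]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for ind in self.individuals:
            for pid in ind.parent_ids:
                if pid not in self._index:
                    raise PedigreeError(
                        f"individual {ind.id!r} references missing parent {pid!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self._index:
            if start in state:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self[start].parent_ids))]
            state[start] = 0
            while stack:
                iid, it = stack[-1]
                advanced = False
                for pid in it:
                    if state.get(pid) == 0:
                        raise PedigreeError(
                            f"cyclic ancestry involving {pid!r} in pedigree {self.name!r}"
                        )
                    if pid not in state:
                        state[pid] = 0
                        stack.append((pid, iter(self[pid].parent_ids)))
                        advanced = True
                        break
                if not advanced:
                    state[iid] = 1
                    stack.pop()

    # -- derived structure ----------------------------------------------
    def topological_order(self) -> list[Individual]:
        """Individuals ordered so every parent precedes its children."""
        depth = self.generation_depth()
        return sorted(self.individuals, key=lambda ind: (depth[ind.id], self._index[ind.id]))

    def generation_depth(self) -> dict[str, int]:
        """Founder depth 0; child depth = 1 + max parental depth."""
        depth: dict[str, int] = {}

        def visit(iid: str) -> int:
            if iid in depth:
                return depth[iid]
            parents = self[iid].parent_ids
            depth[iid] = 0 if not parents else 1 + max(visit(p) for p in parents)
            return depth[iid]

        for ind in self.individuals:
            visit(ind.id)
        return depth

    def constraint_triples(self) -> list[tuple[int, int, int]]:
        """Per non-founder: (child, father, mother) positional indices, -1
        for an absent parent. These are the Mendelian constraints."""
        out = []
        for ind in self.individuals:
            if ind.is_founder:
                continue
            f = self._index[ind.father_id] if ind.father_id else -1
            m = self._index[ind.mother_id] if ind.mother_id else -1
            out.append((self._index[ind.id], f, m))
        return out

    def subset(self, keep_ids: Sequence[str], name: str | None = None) -> "Pedigree":
        """Restriction to ``keep_ids``; parent links to dropped individuals
        are nulled."""
        keep = set(keep_ids)
        inds = []
        for ind in self.individuals:
            if ind.id not in keep:
                continue
            f = ind.father_id if ind.father_id in keep else None
            m = ind.mother_id if ind.mother_id in keep else None
            inds.append(replace(ind, father_id=f, mother_id=m))
        return Pedigree(name=name or self.name, individuals=inds)

    # -- serialization ---------------------------------------------------
    def to_fam_text(self) -> str:
        buf = io.StringIO()
        for ind in self.individuals:
            buf.write(
                "\t".join(
                    [
                        self.name,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        ind.sex.to_code(),
                        "-9",
                    ]
                )
                + "\n"
            )
        return buf.getvalue()


def parse_pedigree(text: str) -> list[Pedigree]:
    """Parse 6-column ``.fam`` text into one :class:`Pedigree` per family id.

    Raises :class:`PedigreeError` on duplicate ids within a family, parent
    references to absent records, or cyclic ancestry.
    """
    families: dict[str, list[Individual]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"line {lineno}: expected 6 columns, got {len(fields)}")
        fam, iid, fid, mid, sex = fields[0], fields[1], fields[2], fields[3], fields[4]
        ind = Individual(
            id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=Sex.from_code(sex),
        )
        bucket = families.setdefault(fam, [])
        if any(other.id == iid for other in bucket):
            raise PedigreeError(f"duplicate individual id {iid!r} in family {fam!r}")
        bucket.append(ind)
    return [Pedigree(name=fam, individuals=inds) for fam, inds in families.items()]


def read_pedigree(path) -> list[Pedigree]:
    with open(path) as fh:
        return parse_pedigree(fh.read())


def split_on_missing_founders(
    ped: Pedigree, genotyped_ids: set[str] | frozenset[str]
) -> list[Pedigree]:
    """Remove ungenotyped top-generation members and split what remains.

    Top generation means individuals with no recorded parents (founders).
    Ungenotyped founders are removed; the remaining individuals are
    partitioned into connected sub-pedigrees (connectivity via retained
    parent-child links), and singletons — individuals left without any
    relative — are dropped. Returns an empty list if nothing survives.
    """
    unknown = set(genotyped_ids) - set(ped.ids)
    if unknown:
        raise PedigreeError(f"genotyped ids not in pedigree: {sorted(unknown)}")
    keep = [
        ind.id
        for ind in ped.individuals
        if not (ind.is_founder and ind.id not in genotyped_ids)
    ]
    trimmed = ped.subset(keep)

    # connected components over undirected parent-child edges
    adj: dict[str, set[str]] = {iid: set() for iid in trimmed.ids}
    for ind in trimmed.individuals:
        for pid in ind.parent_ids:
            adj[ind.id].add(pid)
            adj[pid].add(ind.id)
    components: list[list[str]] = []
    seen: set[str] = set()
    for iid in trimmed.ids:
        if iid in seen:
            continue
        comp, stack = [], [iid]
        seen.add(iid)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        components.append(comp)

    out = []
    kept_components = [c for c in components if len(c) > 1]
    if not kept_components:
        import warnings

        warnings.warn(
            f"pedigree {ped.name!r}: no individuals with relatives remain after "
            "removing ungenotyped founders",
            stacklevel=2,
        )
    for k, comp in enumerate(kept_components, start=1):
        suffix = f".{k}" if len(kept_components) > 1 else ""
        out.append(trimmed.subset(comp, name=f"{ped.name}{suffix}"))
    return out


def extract_nuclear_families(
    ped: Pedigree,
) -> tuple[list[NuclearFamily], list[str]]:
    """Greedy partition of a pedigree into non-overlapping nuclear families.

    Candidate units are (parent couple, their common sibship). Units are
    taken largest sibship first, then earliest generation, then input order;
    an individual already consumed by an earlier unit is excluded, which can
    downgrade a two-parent unit to a one-parent one. Returns the families
    and the leftover ids not placed in any family.
    """
    depth = ped.generation_depth()
    # group children by (father_id, mother_id) pair
    sibships: dict[tuple[str | None, str | None], list[str]] = {}
    for ind in ped.individuals:
        if ind.is_founder:
            continue
        sibships.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)

    def couple_depth(key: tuple[str | None, str | None]) -> int:
        return min(depth[p] for p in key if p is not None)

    order = sorted(
        sibships.items(),
        key=lambda kv: (-len(kv[1]), couple_depth(kv[0]), ped.index_of(kv[1][0])),
    )

    used: set[str] = set()
    families: list[NuclearFamily] = []
    for (fid, mid), kids in order:
        parents = tuple(p for p in (fid, mid) if p is not None and p not in used)
        children = tuple(c for c in kids if c not in used)
        if not parents or not children:
            continue
        fam = NuclearFamily(parent_ids=parents, child_ids=children)
        families.append(fam)
        used.update(fam.member_ids)
    leftovers = [iid for iid in ped.ids if iid not in used]
    return families, leftovers
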