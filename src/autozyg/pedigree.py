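"""Pedigree data model with recursive kinship and inbreeding coefficients.

The kinship coefficient phi(i, j) is the probability that alleles drawn
at random, one from each of i and j, are identical by descent.  It is
computed by the classic recursion: founders are mutually unrelated and
non-inbred, phi(i, i) = (1 + F_i) / 2, and for a non-founder i that is
not an ancestor of j, phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2.
An individual's inbreeding coefficient F equals the kinship of its
parents.

A parent coded as missing (``None``) is treated as an anonymous,
unrelated founder, which allows partial pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class UnknownIndividualError(KeyError):
    """An individual id not present in the pedigree was requested."""


class PedigreeStructureError(ValueError):
    """The parentage graph is malformed (cycle, missing or sex-conflicting parent)."""


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A single family's parentage graph.

    Validates on construction: named parents must exist, have a
    compatible sex for their role, and the graph must be acyclic.
    """

    individuals: dict[str, Individual] = field(default_factory=dict)
    _kinship_cache: dict[tuple[str, str], float] = field(
        default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_individuals(cls, individuals: list[Individual]) -> "Pedigree":
        ped = cls()
        for ind in individuals:
            if ind.id in ped.individuals:
                raise PedigreeStructureError(f"duplicate individual id {ind.id!r}")
            ped.individuals[ind.id] = ind
        ped.validate()
        return ped

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        for ind in self.individuals.values():
            for pid, role_sex in ((ind.father_id, Sex.MALE),
                                  (ind.mother_id, Sex.FEMALE)):
                if pid is None:
                    continue
                parent = self.individuals.get(pid)
                if parent is None:
                    raise PedigreeStructureError(
                        f"parent {pid!r} of {ind.id!r} not in pedigree")
                if parent.sex not in (role_sex, Sex.UNKNOWN):
                    raise PedigreeStructureError(
                        f"parent {pid!r} of {ind.id!r} has sex {parent.sex.value}, "
                        f"expected {role_sex.value}")
        self._depths()  # raises on cycles

    def _depths(self) -> dict[str, int]:
        """Generation depth per individual (founders 0); detects cycles."""
        depths: dict[str, int] = {}
        visiting: set[str] = set()

        def depth(iid: str) -> int:
            if iid in depths:
                return depths[iid]
            if iid in visiting:
                raise PedigreeStructureError(
                    f"cycle in parentage graph involving {iid!r}")
            visiting.add(iid)
            ind = self.individuals[iid]
            d = 0
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    d = max(d, depth(pid) + 1)
            visiting.discard(iid)
            depths[iid] = d
            return d

        for iid in self.individuals:
            depth(iid)
        return depths

    # -- accessors -----------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self.individuals[iid]
        except KeyError:
            raise UnknownIndividualError(iid) from None

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    @property
    def family_id(self) -> str:
        return next(iter(self.individuals.values())).family_id

    def members(self, affected: Affection | None = None) -> list[Individual]:
        inds = list(self.individuals.values())
        if affected is not None:
            inds = [i for i in inds if i.affected is affected]
        return inds

    def children_of(self, father_id: str, mother_id: str) -> list[Individual]:
        return [i for i in self.individuals.values()
                if i.father_id == father_id and i.mother_id == mother_id]

    def siblings_of(self, iid: str) -> list[Individual]:
        """Full siblings (same named father and mother), excluding iid."""
        ind = self[iid]
        if ind.father_id is None and ind.mother_id is None:
            return []
        return [s for s in self.individuals.values()
                if s.id != iid
                and s.father_id == ind.father_id
                and s.mother_id == ind.mother_id]

    # -- kinship -------------------------------------------------------

    @cached_property
    def _depth_map(self) -> dict[str, int]:
        return self._depths()

    def kinship(self, i: str, j: str) -> float:
        """Kinship coefficient phi(i, j), memoized on the unordered pair."""
        for iid in (i, j):
            if iid not in self.individuals:
                raise UnknownIndividualError(iid)
        return self._phi(i, j)

    def _phi(self, i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached

        if i == j:
            value = 0.5 * (1.0 + self.inbreeding(i))
        else:
            # Descend the individual further from the founders; an ancestor
            # always has strictly smaller depth than its descendants, so the
            # deeper of the two cannot be an ancestor of the other.
            if self._depth_map[i] < self._depth_map[j]:
                i, j = j, i
            ind = self.individuals[i]
            if ind.is_founder:
                value = 0.0  # two distinct founders (or founder vs non-descendant)
            else:
                value = 0.5 * (self._phi_or_zero(ind.father_id, j)
                               + self._phi_or_zero(ind.mother_id, j))
        self._kinship_cache[key] = value
        return value

    def _phi_or_zero(self, i: str | None, j: str) -> float:
        # A missing parent is an anonymous unrelated founder.
        return 0.0 if i is None else self._phi(i, j)

    def inbreeding(self, i: str) -> float:
        """Inbreeding coefficient F_i = phi(father_i, mother_i)."""
        ind = self[i]
        if ind.father_id is None or ind.mother_id is None:
            return 0.0
        return self._phi(ind.father_id, ind.mother_id)


def kinship_coefficient(ped: Pedigree, i: str, j: str) -> float:
    """Functional alias for :meth:`Pedigree.kinship`."""
    return ped.kinship(i, j)


def inbreeding_coefficient(ped: Pedigree, i: str) -> float:
    """Functional alias for :meth:`Pedigree.inbreeding`."""
    return ped.inbreeding(i)
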