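"""Pedigrees with phenotype events and study-role assignment.

Families with strong autosomal-dominant colorectal cancer (CRC) aggregation
are the unit of analysis.  Each member carries a list of phenotype events
(CRC, colonic polyps, other cancers, or an explicit clean observation) and is
assigned exactly one study role:

* ``case`` — diagnosed with CRC;
* ``possible_carrier`` — polyps, or an offspring of a CRC case who has not
  yet reached the age of the family's youngest CRC diagnosis;
* ``control`` — observed unaffected (clean colonoscopy / explicit
  ``unaffected`` event) with no CRC or polyp history;
* ``uninformative`` — everyone else (unobserved members, non-CRC cancers
  without colonoscopy clearance).

Only blood members of the lineage are constrained by the dominant-model
segregation filter; married-in spouses are tracked separately so an affected
spouse (a phenocopy) does not break segregation.

The on-disk format is an extended PED dialect: the five standard leading
columns (family, member, father, mother, sex), then a semicolon-separated
list of event descriptors ``kind:detail:age``, then a genotyped flag (0/1),
then the member's current age (or ``.``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Optional


class PedigreeError(ValueError):
    """Structural problem in a pedigree (dangling parent, duplicate ID...)."""


class EventKind(str, Enum):
    CRC = "CRC"
    POLYPS = "polyps"
    OTHER_CANCER = "other_cancer"
    UNAFFECTED = "unaffected"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Role(str, Enum):
    CASE = "case"
    POSSIBLE_CARRIER = "possible_carrier"
    CONTROL = "control"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class PhenotypeEvent:
    """One diagnosis or observation.

    ``kind=unaffected`` records adequate negative observation (e.g. a clean
    colonoscopy); per the dialect it carries no age — put context in
    ``detail`` if needed.
    """

    kind: EventKind
    detail: str = ""
    age_at_diagnosis: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind is EventKind.UNAFFECTED and self.age_at_diagnosis is not None:
            raise PedigreeError("'unaffected' events carry no age")
        if self.age_at_diagnosis is not None and self.age_at_diagnosis < 0:
            raise PedigreeError("negative age_at_diagnosis")


@dataclass
class Individual:
    member_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    events: list[PhenotypeEvent] = field(default_factory=list)
    genotyped: bool = False
    current_age: Optional[int] = None

    def __post_init__(self) -> None:
        if self.current_age is not None and self.current_age < 0:
            raise PedigreeError(f"{self.member_id}: negative current_age")
        if sum(1 for e in self.events if e.kind is EventKind.CRC) > 1:
            raise PedigreeError(f"{self.member_id}: more than one CRC event")

    @property
    def sample_id(self) -> str:
        """Cohort-wide unique sample name used in multi-sample VCFs."""
        return f"{self.family_id}_{self.member_id}"

    def has_event(self, kind: EventKind) -> bool:
        return any(e.kind is kind for e in self.events)

    def crc_event(self) -> Optional[PhenotypeEvent]:
        for e in self.events:
            if e.kind is EventKind.CRC:
                return e
        return None


@dataclass
class Family:
    family_id: str
    members: list[Individual]
    blood_member_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [m.member_id for m in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PedigreeError(
                f"family {self.family_id}: duplicate member IDs {sorted(dupes)}"
            )
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise PedigreeError(
                        f"family {self.family_id}: member {m.member_id} refers to "
                        f"unknown parent {pid!r}"
                    )
        if not self.blood_member_ids:
            self.blood_member_ids = _blood_members(self.members)
        elif not self.blood_member_ids <= known:
            raise PedigreeError(
                f"family {self.family_id}: blood_member_ids not a subset of members"
            )

    def member(self, member_id: str) -> Individual:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    def is_blood(self, member_id: str) -> bool:
        return member_id in self.blood_member_ids


def _ancestors(member: Individual, by_id: dict[str, Individual]) -> set[str]:
    out: set[str] = set()
    stack = [p for p in (member.father_id, member.mother_id) if p is not None]
    while stack:
        pid = stack.pop()
        if pid in out:
            continue
        out.add(pid)
        parent = by_id[pid]
        stack.extend(p for p in (parent.father_id, parent.mother_id) if p is not None)
    return out


def _blood_members(members: Iterable[Individual]) -> set[str]:
    """Blood lineage: CRC cases and their ancestors, closed under descent.

    Members with no parent records whose only link to the family is a
    partnership (married-in spouses) are excluded, which is what exempts an
    affected spouse from the dominant-model carrier requirement.  In a family
    without any CRC case, members with recorded parents anchor the lineage
    instead.
    """
    by_id = {m.member_id: m for m in members}
    anchors: set[str] = set()
    for m in by_id.values():
        if m.has_event(EventKind.CRC):
            # a parentless case anchors only through descent: a married-in
            # spouse with CRC (phenocopy) must stay outside the lineage
            if m.father_id is not None or m.mother_id is not None:
                anchors.add(m.member_id)
            anchors |= _ancestors(m, by_id)
    if not anchors:
        for m in by_id.values():
            if m.father_id is not None or m.mother_id is not None:
                anchors.add(m.member_id)
                anchors |= _ancestors(m, by_id)
    # close under the child relation: any member with a blood parent is blood
    blood = set(anchors)
    changed = True
    while changed:
        changed = False
        for m in by_id.values():
            if m.member_id in blood:
                continue
            if (m.father_id in blood) or (m.mother_id in blood):
                blood.add(m.member_id)
                changed = True
    return blood


# ---------------------------------------------------------------------------
# extended-PED I/O

_MISSING = {"0", ".", ""}


def _parse_events(text: str, where: str) -> list[PhenotypeEvent]:
    text = text.strip()
    if text in _MISSING:
        return []
    events = []
    for chunk in text.split(";"):
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 3:
            raise PedigreeError(f"{where}: bad event descriptor {chunk!r}")
        kind_s, detail, age_s = parts
        try:
            kind = EventKind(kind_s)
        except ValueError:
            raise PedigreeError(f"{where}: unknown event kind {kind_s!r}") from None
        age = None if age_s in _MISSING else int(age_s)
        events.append(PhenotypeEvent(kind=kind, detail=detail, age_at_diagnosis=age))
    return events


_SEX_IN = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


def parse_pedigree(stream: IO[str] | Iterable[str]) -> list[Family]:
    """Parse extended-PED text into :class:`Family` objects.

    Columns (tab-separated): family, member, father, mother, sex,
    events (``kind:detail:age`` joined by ``;``), genotyped flag, current age.
    Missing parents/values are ``0`` or ``.``.  Lines starting with ``#`` are
    comments.
    """
    per_family: dict[str, list[Individual]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise PedigreeError(f"line {lineno}: expected >=6 columns, got {len(cols)}")
        fam, mid, fid, mo, sex_s = (c.strip() for c in cols[:5])
        events = _parse_events(cols[5], f"line {lineno}")
        genotyped = False
        if len(cols) > 6 and cols[6].strip() not in _MISSING:
            genotyped = cols[6].strip() == "1"
        age = None
        if len(cols) > 7 and cols[7].strip() not in _MISSING:
            age = int(cols[7])
        ind = Individual(
            member_id=mid,
            family_id=fam,
            father_id=None if fid in _MISSING else fid,
            mother_id=None if mo in _MISSING else mo,
            sex=_SEX_IN.get(sex_s, Sex.UNKNOWN),
            events=events,
            genotyped=genotyped,
            current_age=age,
        )
        if fam not in per_family:
            per_family[fam] = []
            order.append(fam)
        if any(m.member_id == mid for m in per_family[fam]):
            raise PedigreeError(f"line {lineno}: duplicate member {mid!r} in family {fam}")
        per_family[fam].append(ind)
    return [Family(family_id=f, members=per_family[f]) for f in order]


def write_pedigree(families: Iterable[Family], stream: IO[str]) -> None:
    """Write families back out in the extended-PED dialect (round-trip safe)."""
    for fam in families:
        for m in fam.members:
            evs = ";".join(
                f"{e.kind.value}:{e.detail}:"
                f"{'' if e.age_at_diagnosis is None else e.age_at_diagnosis}"
                for e in m.events
            )
            stream.write(
                "\t".join(
                    [
                        fam.family_id,
                        m.member_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_OUT[m.sex],
                        evs or ".",
                        "1" if m.genotyped else "0",
                        "." if m.current_age is None else str(m.current_age),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# role assignment

def youngest_case_age(family: Family) -> int:
    """Age at diagnosis of the family's youngest CRC case."""
    ages = [
        e.age_at_diagnosis
        for m in family.members
        for e in m.events
        if e.kind is EventKind.CRC and e.age_at_diagnosis is not None
    ]
    if not ages:
        raise PedigreeError(
            f"family {family.family_id}: no CRC case with a recorded age"
        )
    return min(ages)


def assign_roles(family: Family) -> dict[str, Role]:
    """Assign every member exactly one study role (total, deterministic).

    Order of precedence: CRC diagnosis -> case; polyps -> possible carrier;
    offspring of a CRC case still younger than the family's earliest CRC
    onset -> possible carrier; explicit unaffected observation -> control;
    anything else (non-CRC cancer without colonoscopy clearance, unobserved
    members) -> uninformative.
    """
    try:
        cutoff: Optional[int] = youngest_case_age(family)
    except PedigreeError:
        cutoff = None
    by_id = {m.member_id: m for m in family.members}
    roles: dict[str, Role] = {}
    for m in family.members:
        if m.has_event(EventKind.CRC):
            roles[m.member_id] = Role.CASE
            continue
        if m.has_event(EventKind.POLYPS):
            roles[m.member_id] = Role.POSSIBLE_CARRIER
            continue
        parent_has_crc = any(
            pid is not None and by_id[pid].has_event(EventKind.CRC)
            for pid in (m.father_id, m.mother_id)
        )
        if (
            parent_has_crc
            and cutoff is not None
            and m.current_age is not None
            and m.current_age < cutoff
        ):
            roles[m.member_id] = Role.POSSIBLE_CARRIER
            continue
        if m.has_event(EventKind.UNAFFECTED):
            roles[m.member_id] = Role.CONTROL
            continue
        roles[m.member_id] = Role.UNINFORMATIVE
    return roles
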