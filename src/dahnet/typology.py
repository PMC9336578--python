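"""Actor typology for the development-assistance-for-health (DAH) landscape.

Actors in the DAH system fall into four broad categories — public entities,
private entities, civil society organizations (CSOs) and public–private
partnerships (PPPs) — each with a small set of subgroups (e.g. national
governments and multilateral organizations under "public"; NGOs, public
charities/NPOs and philanthropic foundations under "CSO").  Recipient
countries are carried as network actors in their own right and are typed as
public / national-government nodes, with their functional role (source,
channel, recipient) recorded separately per year.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator


class Category(str, Enum):
    """Broad actor category."""

    PUBLIC = "PUBLIC"
    PRIVATE = "PRIVATE"
    CSO = "CSO"
    PPP = "PPP"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # so f-strings and CSVs print the bare name
        return self.value


#: Subgroups admissible under each category.  The two foundation labels are
#: finer CSO distinctions used when profiling top-ranked CSOs.
CATEGORY_SUBGROUPS: dict[Category, frozenset[str]] = {
    Category.PUBLIC: frozenset({"national_government", "multilateral"}),
    Category.PRIVATE: frozenset({"individual", "sme_corporation"}),
    Category.CSO: frozenset(
        {"ngo", "public_charity_npo", "family_foundation", "corporate_foundation"}
    ),
    Category.PPP: frozenset({"global_health_network", "global_health_initiative"}),
    Category.UNKNOWN: frozenset({"unknown"}),
}

_ISO3_RE = re.compile(r"^[A-Za-z]{3}$")
_WS_RE = re.compile(r"\s+")


def canonical_id(raw: str) -> str:
    """Canonicalize an actor identifier: case-fold and collapse whitespace.

    A government and its bilateral agency remain distinct ids unless a
    registry explicitly maps them together.
    """
    return _WS_RE.sub(" ", raw.strip()).casefold()


def looks_like_iso3(raw: str) -> bool:
    """Heuristic for country identifiers: a bare three-letter code."""
    return bool(_ISO3_RE.match(raw.strip()))


class TypologyError(ValueError):
    """Raised for inconsistent actor annotations or unresolvable ids."""


@dataclass
class Actor:
    """A single global-health actor with its typology annotation.

    Parameters
    ----------
    actor_id:
        Canonical key (see :func:`canonical_id`).
    name:
        Display string; defaults to the id.
    category, subgroup:
        Typology assignment; subgroup must be admissible for the category.
    is_oecd_dac:
        Flag for national governments on the OECD Development Assistance
        Committee; implies ``subgroup == "national_government"``.
    iso3:
        Country code for country actors, ``None`` for organizations.
    """

    actor_id: str
    name: str = ""
    category: Category = Category.UNKNOWN
    subgroup: str = "unknown"
    is_oecd_dac: bool = False
    iso3: str | None = None

    def __post_init__(self) -> None:
        if not self.actor_id:
            raise TypologyError("actor_id must be a non-empty string")
        if not self.name:
            self.name = self.actor_id
        self.category = Category(self.category)
        if self.subgroup not in CATEGORY_SUBGROUPS[self.category]:
            raise TypologyError(
                f"subgroup {self.subgroup!r} is not admissible for category "
                f"{self.category}: allowed {sorted(CATEGORY_SUBGROUPS[self.category])}"
            )
        if self.is_oecd_dac and self.subgroup != "national_government":
            raise TypologyError(
                f"{self.actor_id}: is_oecd_dac requires subgroup national_government"
            )


@dataclass
class ActorRegistry:
    """Mapping from canonical actor id to :class:`Actor`.

    ``policy`` controls resolution of ids absent from the registry:
    ``"permissive"`` (default) fabricates an UNKNOWN-category actor (or a
    public national-government actor for ISO3-shaped country ids),
    ``"strict"`` raises :class:`TypologyError`.
    """

    actors: dict[str, Actor] = field(default_factory=dict)
    policy: str = "permissive"

    def __post_init__(self) -> None:
        if self.policy not in ("strict", "permissive"):
            raise TypologyError(f"unknown resolution policy {self.policy!r}")

    def __len__(self) -> int:
        return len(self.actors)

    def __contains__(self, actor_id: str) -> bool:
        return canonical_id(actor_id) in self.actors

    def __iter__(self) -> Iterator[Actor]:
        return iter(self.actors.values())

    def add(self, actor: Actor, replace: bool = False) -> None:
        if actor.actor_id in self.actors and not replace:
            raise TypologyError(f"duplicate actor id {actor.actor_id!r}")
        self.actors[actor.actor_id] = actor

    def resolve(self, actor_id: str) -> Actor:
        """Return the actor for ``actor_id``, applying the resolution policy."""
        key = canonical_id(actor_id)
        if key in self.actors:
            return self.actors[key]
        if self.policy == "strict":
            raise TypologyError(f"unresolvable actor id {actor_id!r} (strict mode)")
        if looks_like_iso3(actor_id):
            actor = country_actor(actor_id)
        else:
            actor = Actor(key, name=actor_id, category=Category.UNKNOWN,
                          subgroup="unknown")
        self.actors[key] = actor
        return actor

    def category_of(self, actor_id: str) -> Category:
        return self.resolve(actor_id).category

    # -- CSV round trip ----------------------------------------------------

    CSV_HEADER = ["actor_id", "name", "category", "subgroup", "is_oecd_dac", "iso3"]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(self.CSV_HEADER)
            for key in sorted(self.actors):
                a = self.actors[key]
                writer.writerow(
                    [a.actor_id, a.name, a.category.value, a.subgroup,
                     int(a.is_oecd_dac), a.iso3 or ""]
                )

    @classmethod
    def from_csv(cls, path: str | Path, policy: str = "permissive") -> "ActorRegistry":
        registry = cls(policy=policy)
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = set(cls.CSV_HEADER) - set(reader.fieldnames or [])
            if missing:
                raise TypologyError(f"registry CSV missing columns: {sorted(missing)}")
            for row in reader:
                registry.add(
                    Actor(
                        actor_id=canonical_id(row["actor_id"]),
                        name=row["name"] or row["actor_id"],
                        category=Category(row["category"]),
                        subgroup=row["subgroup"],
                        is_oecd_dac=row["is_oecd_dac"].strip() in ("1", "true", "True"),
                        iso3=row["iso3"] or None,
                    )
                )
        return registry


def country_actor(iso3: str) -> Actor:
    """Build the conventional actor for a recipient-country node.

    Recipient countries participate in the flow network (and may themselves
    donate), but the organizational typology does not cover states acting as
    aid endpoints; they are typed public / national-government by convention.
    """
    code = iso3.strip().upper()
    return Actor(
        actor_id=canonical_id(code),
        name=code,
        category=Category.PUBLIC,
        subgroup="national_government",
        iso3=code,
    )


def read_ppp_list(path: str | Path) -> set[str]:
    """Read a plain-text PPP membership list, one actor id per line."""
    with open(path, encoding="utf-8") as fh:
        return {canonical_id(line) for line in fh if line.strip()}


def assign_typology(
    ids: Iterable[str],
    registry: ActorRegistry,
    ppp_list: Iterable[str] = (),
) -> ActorRegistry:
    """Resolve every id to a category + subgroup, in place, and return registry.

    Membership of the configured PPP list overrides any other annotation,
    mirroring the convention that entities on the canonical list of global
    health partnerships are classified as PPPs regardless of their legal
    form.  ISO3-shaped ids absent from the registry become public
    national-government country actors.  In strict mode any other unresolved
    id raises; in permissive mode it is annotated UNKNOWN.
    """
    ppp_keys = {canonical_id(p) for p in ppp_list}
    for raw in ids:
        key = canonical_id(raw)
        if key in ppp_keys:
            existing = registry.actors.get(key)
            registry.add(
                Actor(
                    actor_id=key,
                    name=existing.name if existing else raw,
                    category=Category.PPP,
                    subgroup=(
                        existing.subgroup
                        if existing is not None
                        and existing.subgroup in CATEGORY_SUBGROUPS[Category.PPP]
                        else "global_health_initiative"
                    ),
                ),
                replace=True,
            )
        else:
            registry.resolve(raw)
    return registry
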