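"""Seeded synthetic generator for DAH-style disbursement flow tables.

The real disbursement data behind development-assistance-for-health (DAH)
resource tracking is available only on request, so this module generates
flow tables with the same schema and the structural features the analysis
relies on:

* annual snapshots over an inclusive year range (default 1990-2015);
* deterministic actor activation following per-category growth schedules
  (default: roughly five-fold growth in active actors, with a steep surge
  of civil society organizations between 2005 and 2011 and public-private
  partnerships entering from 2000);
* scheduled category shares of annual source and channel totals (default:
  the public share of sources declining 0.945 -> 0.813 and of channels
  0.924 -> 0.499 across the period);
* cause-specific CSO channels funding exactly one health area;
* actors occupying several roles (sources that also channel; recipient
  countries that also donate);
* a small fraction of records with UNSPECIFIED endpoints, exercising the
  cleaning filter.

Actor activation is deterministic given the growth schedule; only flow
placement and amounts are random.  Amounts are drawn log-normally and
rescaled so that each year's total (and each year's per-category source and
channel totals) matches the schedule exactly.  The generator is a pure
function of its config: the same config and seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ingest import FLOW_COLUMNS, UNSPECIFIED, write_flow_table
from .typology import Actor, ActorRegistry, Category, country_actor

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "default_config_mdg_era",
    "generate",
    "make_registry",
    "write_dataset",
    "health_area_labels",
]

CATEGORIES = [Category.PUBLIC, Category.PRIVATE, Category.CSO, Category.PPP]

#: Millennium-Development-Goal target areas; cause-specific CSOs concentrate
#: here, and these labels lead the health-area list.
MDG_AREAS = ["hiv_aids", "malaria", "child_health", "maternal_health", "nutrition"]

#: ISO3 codes used for synthetic recipient countries (major DAH recipients).
_RECIPIENT_ISO3 = [
    "AFG", "AGO", "BGD", "BEN", "BFA", "BDI", "KHM", "CMR", "CAF", "TCD",
    "COD", "CIV", "ERI", "ETH", "GHA", "GIN", "HTI", "IND", "IDN", "KEN",
    "LAO", "LBR", "MDG", "MWI", "MLI", "MOZ", "MMR", "NPL", "NER", "NGA",
    "PAK", "PNG", "RWA", "SEN", "SLE", "SOM", "SSD", "SDN", "TZA", "TGO",
    "UGA", "VNM", "YEM", "ZMB", "ZWE", "BOL", "GTM", "HND", "NIC", "PER",
]

_SUBGROUP_CHOICES: dict[Category, tuple[list[str], list[float]]] = {
    Category.PUBLIC: (["national_government", "multilateral"], [0.6, 0.4]),
    Category.PRIVATE: (["individual", "sme_corporation"], [0.3, 0.7]),
    Category.CSO: (
        ["ngo", "public_charity_npo", "family_foundation", "corporate_foundation"],
        [0.45, 0.30, 0.17, 0.08],
    ),
    Category.PPP: (["global_health_network", "global_health_initiative"], [0.5, 0.5]),
}


class ConfigError(ValueError):
    """Raised when a generator config violates its invariants."""


def health_area_labels(n: int) -> list[str]:
    """The configured health-area label set (MDG areas first)."""
    if n < len(MDG_AREAS):
        return MDG_AREAS[:n]
    return MDG_AREAS + [f"area_{i:02d}" for i in range(len(MDG_AREAS) + 1, n + 1)]


Schedule = dict[int, float]
ShareSchedule = dict[int, dict[str, float]]


def _interp_schedule(years: range, anchors: dict[int, float]) -> Schedule:
    xs = sorted(anchors)
    ys = [anchors[x] for x in xs]
    return {y: float(np.interp(y, xs, ys)) for y in years}


def _interp_shares(years: range, anchors: dict[int, dict[str, float]]) -> ShareSchedule:
    out: ShareSchedule = {}
    for cat in CATEGORIES:
        per_cat = _interp_schedule(years, {y: v.get(cat.value, 0.0)
                                           for y, v in anchors.items()})
        for y, v in per_cat.items():
            out.setdefault(y, {})[cat.value] = v
    return out


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic DAH flow generator.

    All schedules are fully materialized per calendar year.  Share schedules
    map year -> category name -> fraction of that year's total (summing to 1
    within 1e-9); the growth schedule maps category name -> year -> target
    count of active organizational actors.  ``records_per_actor`` scales the
    number of disbursement records per year with the active actor count.
    """

    years: tuple[int, int] = (1990, 2015)
    n_recipients: int = 30
    growth_schedule: dict[str, dict[int, int]] = field(default_factory=dict)
    annual_total: Schedule = field(default_factory=dict)
    source_share_schedule: ShareSchedule = field(default_factory=dict)
    channel_share_schedule: ShareSchedule = field(default_factory=dict)
    single_area_prob: float = 0.33
    n_health_areas: int = 22
    unspecified_rate: float = 0.02
    hybrid_recipient_donor_rate: float = 0.10
    records_per_actor: int = 5
    amount_sigma: float = 1.0
    seed: int = 1990

    @property
    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)

    def validate(self) -> "GeneratorConfig":
        """Check all invariants; raise :class:`ConfigError` naming the field."""
        if self.years[0] > self.years[1]:
            raise ConfigError("years: start must not exceed end")
        if self.n_recipients <= 0:
            raise ConfigError("n_recipients: must be positive")
        if self.records_per_actor <= 0:
            raise ConfigError("records_per_actor: must be positive")
        if self.amount_sigma < 0:
            raise ConfigError("amount_sigma: must be non-negative")
        for name in ("single_area_prob", "unspecified_rate",
                     "hybrid_recipient_donor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: probability {v} outside [0, 1]")
        if self.n_health_areas <= 0:
            raise ConfigError("n_health_areas: must be positive")
        for y in self.year_range:
            if y not in self.annual_total:
                raise ConfigError(f"annual_total: missing year {y}")
            if self.annual_total[y] <= 0:
                raise ConfigError(f"annual_total: non-positive total at {y}")
        for label, sched in (("source_share_schedule", self.source_share_schedule),
                             ("channel_share_schedule", self.channel_share_schedule)):
            for y in self.year_range:
                shares = sched.get(y)
                if shares is None:
                    raise ConfigError(f"{label}: missing year {y}")
                if any(v < 0 for v in shares.values()):
                    raise ConfigError(f"{label}: negative share at {y}")
                if abs(sum(shares.values()) - 1.0) > 1e-9:
                    raise ConfigError(f"{label}: shares at {y} do not sum to 1")
        for cat in CATEGORIES:
            counts = self.growth_schedule.get(cat.value)
            if counts is None:
                raise ConfigError(f"growth_schedule: missing category {cat.value}")
            prev = 0
            for y in self.year_range:
                if y not in counts:
                    raise ConfigError(
                        f"growth_schedule[{cat.value}]: missing year {y}")
                if counts[y] < 0:
                    raise ConfigError(
                        f"growth_schedule[{cat.value}]: negative count at {y}")
                if counts[y] < prev:
                    raise ConfigError(
                        f"growth_schedule[{cat.value}]: count decreases at {y} "
                        "(actors are never retired)")
                prev = counts[y]
        # a category scheduled to move money must have someone to move it
        for y in self.year_range:
            for cat in CATEGORIES:
                active = self.growth_schedule[cat.value][y]
                src = self.source_share_schedule[y].get(cat.value, 0.0)
                chn = self.channel_share_schedule[y].get(cat.value, 0.0)
                if cat is Category.PUBLIC:
                    # hybrid recipient-donors can carry public source share
                    src = 0.0 if self.hybrid_recipient_donor_rate > 0 else src
                if (src > 0 or chn > 0) and active == 0:
                    raise ConfigError(
                        f"growth_schedule[{cat.value}]: zero active actors at {y} "
                        "but positive share scheduled")
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        data = dict(data)
        if "years" in data:
            data["years"] = tuple(data["years"])
        cfg = cls(**data)
        cfg.growth_schedule = {
            str(k): {int(y): int(c) for y, c in v.items()}
            for k, v in cfg.growth_schedule.items()
        }
        for name in ("source_share_schedule", "channel_share_schedule"):
            sched = getattr(cfg, name)
            setattr(cfg, name, {int(y): dict(v) for y, v in sched.items()})
        cfg.annual_total = {int(y): float(v) for y, v in cfg.annual_total.items()}
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config_mdg_era() -> GeneratorConfig:
    """Default study conditions for the 1990-2015 (MDG-era) DAH landscape.

    Share schedules interpolate monotonically between the era's anchor
    values: the public share of source totals falls from 0.945 (1990) to
    0.813 (2015) and the public share of channel totals from 0.924 to 0.499,
    with PPP channels (absent before 2000) reaching 0.15 of channel totals
    by 2015.  Annual totals grow log-linearly from 7e9 to 36e9 constant USD.
    The growth schedule encodes roughly five-fold growth in active actors
    with a steep CSO ramp over 2005-2011.
    """
    years = range(1990, 2016)
    growth_anchors = {
        Category.PUBLIC.value: {1990: 20, 2015: 60},
        Category.PRIVATE.value: {1990: 4, 2015: 30},
        Category.CSO.value: {1990: 6, 2005: 30, 2011: 130, 2015: 150},
        Category.PPP.value: {1990: 0, 1999: 0, 2000: 2, 2015: 12},
    }
    growth = {
        cat: {y: int(round(np.interp(y, sorted(a), [a[x] for x in sorted(a)])))
              for y in years}
        for cat, a in growth_anchors.items()
    }
    source_anchors = {
        1990: {"PUBLIC": 0.945, "PRIVATE": 0.030, "CSO": 0.025, "PPP": 0.0},
        1999: {"PUBLIC": 0.900, "PRIVATE": 0.048, "CSO": 0.052, "PPP": 0.0},
        2000: {"PUBLIC": 0.895, "PRIVATE": 0.050, "CSO": 0.053, "PPP": 0.002},
        2015: {"PUBLIC": 0.813, "PRIVATE": 0.090, "CSO": 0.092, "PPP": 0.005},
    }
    channel_anchors = {
        1990: {"PUBLIC": 0.924, "PRIVATE": 0.0100, "CSO": 0.0660, "PPP": 0.0},
        1999: {"PUBLIC": 0.822, "PRIVATE": 0.0145, "CSO": 0.1635, "PPP": 0.0},
        2000: {"PUBLIC": 0.810, "PRIVATE": 0.0150, "CSO": 0.1650, "PPP": 0.010},
        2015: {"PUBLIC": 0.499, "PRIVATE": 0.0210, "CSO": 0.3300, "PPP": 0.150},
    }
    total = {y: float(7e9 * (36.0 / 7.0) ** ((y - 1990) / 25.0)) for y in years}
    cfg = GeneratorConfig(
        years=(1990, 2015),
        growth_schedule=growth,
        annual_total=total,
        source_share_schedule=_interp_shares(years, source_anchors),
        channel_share_schedule=_interp_shares(years, channel_anchors),
    )
    return cfg.validate()


# ---------------------------------------------------------------------------
# actor roster


@dataclass
class _OrgActor:
    actor_id: str
    category: Category
    subgroup: str
    created: int
    propensity: float          # relative size when sampled as a source
    single_area: str | None    # fixed health area for cause-specific CSOs
    is_oecd_dac: bool = False


@dataclass
class _Roster:
    orgs: dict[str, list[_OrgActor]]   # category name -> actors in creation order
    recipients: list[str]
    recipient_propensity: dict[str, float]
    hybrid_recipients: list[str]       # recipient countries that also donate

    def active(self, cfg: GeneratorConfig, cat: Category, year: int) -> list[_OrgActor]:
        return self.orgs[cat.value][: cfg.growth_schedule[cat.value][year]]


def _recipient_codes(n: int) -> list[str]:
    codes = list(_RECIPIENT_ISO3)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    i = 0
    while len(codes) < n:  # ISO 3166 user-assigned range as overflow
        codes.append("Q" + letters[i // 26] + letters[i % 26])
        i += 1
    return codes[:n]


def _creation_year(cfg: GeneratorConfig, cat: str, index: int) -> int:
    for y in cfg.year_range:
        if cfg.growth_schedule[cat][y] > index:
            return y
    return cfg.years[1]


def _build_roster(cfg: GeneratorConfig, rng: np.random.Generator) -> _Roster:
    areas = health_area_labels(cfg.n_health_areas)
    mdg = [a for a in MDG_AREAS if a in areas] or areas
    orgs: dict[str, list[_OrgActor]] = {}
    for cat in CATEGORIES:
        n_total = max(cfg.growth_schedule[cat.value].values(), default=0)
        subgroups, weights = _SUBGROUP_CHOICES[cat]
        single_count = 0
        members: list[_OrgActor] = []
        for k in range(n_total):
            subgroup = str(rng.choice(subgroups, p=weights))
            single_area = None
            if cat is Category.CSO:
                # quota assignment: realized cause-specific fraction tracks
                # single_area_prob to within 1/n even at small rosters
                target = int(np.floor((k + 1) * cfg.single_area_prob))
                if target > single_count:
                    single_count = target
                    if rng.random() < 2.0 / 3.0:  # MDG-focused majority
                        single_area = str(rng.choice(mdg))
                    else:
                        single_area = str(rng.choice(areas))
            is_dac = (cat is Category.PUBLIC and subgroup == "national_government"
                      and rng.random() < 0.6)
            members.append(
                _OrgActor(
                    actor_id=f"{cat.value.lower()}_{k + 1:04d}",
                    category=cat,
                    subgroup=subgroup,
                    created=_creation_year(cfg, cat.value, k),
                    propensity=float(rng.lognormal(0.0, 1.25)),
                    single_area=single_area,
                    is_oecd_dac=is_dac,
                )
            )
        orgs[cat.value] = members
    recipients = _recipient_codes(cfg.n_recipients)
    rec_prop = {r: float(rng.lognormal(0.0, 1.0)) for r in recipients}
    n_hybrid = int(round(cfg.hybrid_recipient_donor_rate * cfg.n_recipients))
    hybrid = sorted(
        rng.choice(recipients, size=min(n_hybrid, len(recipients)), replace=False)
    ) if n_hybrid else []
    return _Roster(orgs=orgs, recipients=recipients,
                   recipient_propensity=rec_prop, hybrid_recipients=list(hybrid))


def make_registry(config: GeneratorConfig) -> ActorRegistry:
    """The actor registry matching :func:`generate` for the same config."""
    config.validate()
    roster = _build_roster(config, np.random.default_rng([config.seed, 1]))
    registry = ActorRegistry()
    for cat in CATEGORIES:
        for org in roster.orgs[cat.value]:
            registry.add(Actor(
                actor_id=org.actor_id,
                name=org.actor_id.replace("_", " ").title(),
                category=org.category,
                subgroup=org.subgroup,
                is_oecd_dac=org.is_oecd_dac,
            ))
    for code in roster.recipients:
        registry.add(country_actor(code))
    return registry


# ---------------------------------------------------------------------------
# flow generation


def _apportion(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items over fractions (sum 1).

    Every strictly positive fraction receives at least one item (stolen from
    the largest cell) so no scheduled category budget goes unrepresented.
    """
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    while True:
        starved = np.flatnonzero((fractions > 0) & (counts == 0))
        if len(starved) == 0:
            break
        donor = int(np.argmax(counts))
        if counts[donor] <= 1:
            break
        counts[donor] -= 1
        counts[starved[0]] += 1
    return counts


class _RoleSampler:
    """Serve each eligible actor once per year, then sample by weight."""

    def __init__(self, ids: list[str], weights: dict[str, float],
                 rng: np.random.Generator):
        self._rng = rng
        self._queue = list(rng.permutation(ids)) if ids else []
        self._ids = sorted(ids)
        self._weights = np.array([weights[i] for i in self._ids], dtype=float)

    def draw(self, weights: dict[str, float] | None = None) -> str:
        if self._queue:
            return self._queue.pop()
        if weights is not None:
            w = np.array([weights[i] for i in self._ids], dtype=float)
        else:
            w = self._weights
        return self._ids[int(self._rng.choice(len(self._ids), p=w / w.sum()))]


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic DAH flow table for the configured conditions.

    Returns a DataFrame in the canonical flow-table schema, ordered by year
    then record creation.  Per-year per-category source and channel totals
    equal the scheduled shares of the annual total exactly before
    UNSPECIFIED relabeling; the relabeling never removes an actor's only
    appearance in a year, so the active-actor series is invariant to the
    cleaning filter.
    """
    config.validate()
    roster = _build_roster(config, np.random.default_rng([config.seed, 1]))
    rng = np.random.default_rng([config.seed, 2])
    areas = health_area_labels(config.n_health_areas)
    single_area_of = {
        o.actor_id: o.single_area
        for o in roster.orgs[Category.CSO.value] if o.single_area
    }
    inbound_records: dict[str, int] = {}

    rows: list[tuple] = []
    for year in config.year_range:
        active = {cat: roster.active(config, cat, year) for cat in CATEGORIES}
        n_orgs = sum(len(v) for v in active.values())
        n_rec = config.records_per_actor * (n_orgs + config.n_recipients)
        s_shares = config.source_share_schedule[year]
        c_shares = config.channel_share_schedule[year]

        cells = [(sc, cc) for sc in CATEGORIES for cc in CATEGORIES
                 if s_shares.get(sc.value, 0) > 0 and c_shares.get(cc.value, 0) > 0]
        frac = np.array([s_shares[sc.value] * c_shares[cc.value]
                         for sc, cc in cells])
        frac = frac / frac.sum()
        counts = _apportion(n_rec, frac)

        skeleton: list[int] = np.repeat(np.arange(len(cells)), counts).tolist()
        skeleton = [skeleton[i] for i in rng.permutation(len(skeleton))]

        source_pool: dict[Category, tuple[list[str], dict[str, float]]] = {}
        channel_pool: dict[Category, tuple[list[str], dict[str, float]]] = {}
        for cat in CATEGORIES:
            ids = [o.actor_id for o in active[cat]]
            props = {o.actor_id: o.propensity for o in active[cat]}
            if cat is Category.PUBLIC:
                for code in roster.hybrid_recipients:
                    ids = ids + [code]
                    props[code] = roster.recipient_propensity[code]
            source_pool[cat] = (ids, props)
            channel_pool[cat] = ([o.actor_id for o in active[cat]],
                                 {o.actor_id: o.propensity for o in active[cat]})
        src_samplers = {cat: _RoleSampler(*source_pool[cat], rng)
                        for cat in CATEGORIES if source_pool[cat][0]}
        chn_samplers = {cat: _RoleSampler(*channel_pool[cat], rng)
                        for cat in CATEGORIES if channel_pool[cat][0]}
        rec_sampler = _RoleSampler(roster.recipients,
                                   roster.recipient_propensity, rng)

        year_rows: list[list] = []
        for cell_idx in skeleton:
            sc, cc = cells[cell_idx]
            source = src_samplers[sc].draw()
            # preferential attachment: channels accumulate funders over time
            pref = {i: 1.0 + inbound_records.get(i, 0)
                    for i in channel_pool[cc][0]}
            channel = chn_samplers[cc].draw(weights=pref)
            inbound_records[channel] = inbound_records.get(channel, 0) + 1
            recipient = rec_sampler.draw(weights=roster.recipient_propensity)
            area = single_area_of.get(channel) or str(rng.choice(areas))
            year_rows.append([year, source, channel, recipient, area,
                              cell_idx, 0.0])

        # log-normal amounts, rescaled so every cell budget is met exactly
        cell_of = np.array([r[5] for r in year_rows])
        draws = rng.lognormal(0.0, config.amount_sigma, size=len(year_rows))
        total = config.annual_total[year]
        for ci, (sc, cc) in enumerate(cells):
            budget = total * s_shares[sc.value] * c_shares[cc.value]
            members = np.flatnonzero(cell_of == ci)
            scale = budget / draws[members].sum()
            for m in members:
                year_rows[m][6] = float(draws[m] * scale)
        rows.extend((r[0], r[1], r[2], r[3], r[4], r[6]) for r in year_rows)

    flows = pd.DataFrame(rows, columns=FLOW_COLUMNS)
    _inject_unspecified(flows, config, rng)
    return flows


def _inject_unspecified(flows: pd.DataFrame, config: GeneratorConfig,
                        rng: np.random.Generator) -> None:
    """Relabel a fraction of records with an UNSPECIFIED source or recipient.

    Only records whose three endpoints each appear in at least two records
    of the same year are eligible, so dropping the relabeled records never
    silences an actor for a year.
    """
    m = int(round(config.unspecified_rate * len(flows)))
    if m == 0:
        return
    counts: dict[tuple, int] = {}
    keys = list(zip(flows["year"], flows["source_id"], flows["channel_id"],
                    flows["recipient_id"]))
    for year, s, c, r in keys:
        for role, actor in (("s", s), ("c", c), ("r", r)):
            k = (year, role, actor)
            counts[k] = counts.get(k, 0) + 1
    chosen = 0
    for idx in rng.permutation(len(flows)):
        if chosen >= m:
            break
        year, s, c, r = keys[idx]
        if (counts[(year, "s", s)] > 1 and counts[(year, "c", c)] > 1
                and counts[(year, "r", r)] > 1):
            col = "source_id" if rng.random() < 0.5 else "recipient_id"
            flows.iat[int(idx), flows.columns.get_loc(col)] = UNSPECIFIED
            for role, actor in (("s", s), ("c", c), ("r", r)):
                counts[(year, role, actor)] -= 1
            chosen += 1


def write_dataset(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write flows.csv, actors.csv and config.yaml to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "flows": outdir / "flows.csv",
        "actors": outdir / "actors.csv",
        "config": outdir / "config.yaml",
    }
    write_flow_table(generate(config), paths["flows"])
    make_registry(config).to_csv(paths["actors"])
    config.to_yaml(paths["config"])
    return paths
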