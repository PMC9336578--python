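# Methods

`dahnet` analyses development assistance for health (DAH) as an evolving
directed weighted network.  The underlying data model is the standard
resource-tracking one: every disbursement record is a
`(year, source, channel, recipient country, health area, amount)` tuple —
funds originate with a *source* (a government treasury, a foundation, a
corporation), move through a *channel* (a bilateral agency, a multilateral
organization, an NGO, a global health initiative) and land in a *recipient
country*, earmarked for one of 22 health areas.  Records with an
`UNSPECIFIED` endpoint cannot be attributed to actors and are excluded
before any network is built.

## Actor typology

Actors are classified into four categories with fixed subgroups:

| Category | Subgroups |
|---|---|
| PUBLIC  | national_government, multilateral |
| PRIVATE | individual, sme_corporation |
| CSO     | ngo, public_charity_npo, family_foundation, corporate_foundation |
| PPP     | global_health_network, global_health_initiative |

Membership of a configured public–private-partnership list overrides any
other annotation.  Recipient countries are network actors in their own
right but fall outside the organizational typology; they are typed
PUBLIC / national_government by convention, with functional roles (source,
channel, recipient — non-exclusive, per year) recorded separately.  Ids are
canonicalized by case-folding and whitespace collapsing; a government and
its bilateral agency remain distinct unless a registry maps them together.
Resolution is permissive by default (unknown ids become UNKNOWN with a
warning); strict mode raises, which is what fixtures use.

## Network projections

For every year three simple directed graphs are built, edge weights being
summed constant-USD amounts and edges pointing in the direction money
moves:

* **source → channel** and **channel → recipient** bipartite projections,
  used for role-specific degree metrics;
* a **unimodal** all-actors graph in which each record deposits its amount
  on both of its hops, so total edge weight is exactly twice the summed
  record amounts.  How the original analyses weighted the unimodal graph is
  not documented; the two-hop deposit rule is this package's declared
  convention and is what the conservation tests pin down.

An actor active in several roles is a single node.  Self-loops (an actor
funding itself after canonicalization) are retained as data but excluded
from every metric.  The health-area dimension is summed out at construction
(a filter argument gives per-area subgraphs); it is otherwise used only for
the single-area CSO statistic.

## Metrics

Out-degree and in-degree count distinct funded / funding partners and
ignore weights.  **Channel degree centrality** is a channel's total degree
across the two bipartite projections: distinct funding sources plus
distinct recipient countries funded.

**Generalized closeness** follows the Opsahl–Agneessens–Skvoretz distance,
where a path's length is the sum of per-hop costs `(1/w)^alpha`:

    d_alpha(i, j) = min over directed paths  sum_hops (1 / w_hop)^alpha
    C(i)          = 1 / sum_j d_alpha(i, j)

`alpha` trades the number of ties against their intensity: `alpha = 0`
gives binary hop-count distance, `alpha = 1` classic weighted distance on
costs `1/w`, and the default `alpha = 0.5` (the value established for
international health-aid networks) balances both.  Distances are computed
by Dijkstra on the transformed costs, which are strictly positive, so
shortest paths are simple and no negative-edge issues arise.  No
normalization by network size is applied.

Two conventions are deliberately exposed as configuration rather than
hard-coded, because the directed aid network leaves them genuinely open:

* **Unreachable pairs.**  Summing over *all* other nodes makes closeness 0
  for any node with a single unreachable target, which zeroes most of a
  sparse directed network.  The default sums over the targets a node
  actually reaches (`reachable_only`, the tnet convention); the literal
  reading is available as `zero_if_any_unreachable`.
* **Direction.**  Default is outgoing distances ("how quickly a node can
  reach the rest of the network along the flow of money"); incoming and
  undirected (reciprocal edge weights summed) variants are available.

Rankings are ordinal, 1..k by descending value with lexicographic
tie-breaks on actor id, making tables fully deterministic and invariant to
input row order.

## Synthetic study conditions

The real disbursement dataset is available only on request, so a seeded
generator produces flow tables with the structural features the analysis
assumes.  Its defaults encode the 1990–2015 era:

* **Actors.**  Organizational rosters grow deterministically along
  per-category schedules — public 20→60, private 4→30, CSO 6→150 with the
  steep ramp concentrated in 2005–2011, PPPs entering in 2000 and reaching
  12 — over a constant pool of 30 recipient countries, three of which also
  donate.  Active counts therefore recover the schedule exactly, and
  annual actor counts rise monotonically roughly five-fold (60 → 282).
* **Money.**  Annual totals grow log-linearly from 7e9 to 36e9 constant
  USD.  Category shares of source and channel totals interpolate linearly
  between era anchors (public sources 0.945 → 0.813; public channels
  0.924 → 0.499; PPP channels 0 → 0.15).  Each record's source and channel
  categories come from the product of the two share schedules; log-normal
  amounts (sigma = 1) are rescaled within each category-pair cell so every
  scheduled share — and the annual total — is met exactly.
* **Placement.**  Within a category, each active actor is served once per
  role per year (when slots allow) so no actor silently disappears; the
  remaining source/recipient slots are sampled by a fixed log-normal size
  propensity and channel slots by preferential attachment with weight
  `1 + cumulative inbound record count`.  Record counts are used instead of
  USD in-strength because dollar-scale weights swamp the `+1` smoothing
  and collapse to winner-take-all after a single record; counts give the
  intended heavy-tailed concentration while letting newcomers in.
* **Cause-specific CSOs.**  A `single_area_prob` quota (default 0.33) of
  CSOs, assigned deterministically over creation order, funds exactly one
  health area, two-thirds of them an MDG target area (HIV/AIDS, malaria,
  child health, maternal health, nutrition).  The quota keeps the realized
  fraction within 1/n of the configured probability even at small rosters;
  `single_area_prob = 1.0` still makes every CSO channel single-area.
* **Unspecified endpoints.**  A 2% fraction of records has its source or
  recipient relabeled `UNSPECIFIED`.  Only records whose three endpoints
  each appear in at least two records of that year are eligible, so the
  cleaning filter never removes an actor's only appearance and the active
  actor series is identical before and after cleaning.

The generator is a pure function of its config (one RNG stream seeded from
`config.seed`; roster and flow placement use distinct sub-streams), so a
fixed config yields byte-identical CSVs.

**What the synthetic data does not emulate:** real actor identities and
their idiosyncratic portfolios, serial correlation of dyadic flows across
years beyond what preferential attachment induces, currency deflation,
within-year seasonality, and reporting artifacts other than unspecified
endpoints.  Passing tests therefore demonstrate that the *pipeline*
measures known structure correctly at desk scale (~280 actors, ~19k
records), not that the synthetic landscape reproduces the real one's
actor-level rankings.

## Numerical choices and limitations

* Amounts are non-negative by contract; negative amounts are rejected at
  parse, zero amounts retained on read and discarded at aggregation.
* Closeness oracle agreement is asserted to 1e-9 against exhaustive
  simple-path enumeration on random digraphs of up to 7 nodes; observed
  deviations are at machine precision (~1e-14).
* Degenerate inputs: empty years give empty graphs; a node reaching no
  others has closeness 0; a single-node graph scores 0; categories with no
  active actors are omitted from by-type averages.
* Desk-scale problem sizes (26 annual snapshots, ≤ ~282 nodes) keep the
  full pipeline — generation, 26 unimodal graphs, all-pairs Dijkstra per
  year, rankings and reports — under ten seconds on one CPU.
* The closeness ranking of synthetic CSOs versus public agencies depends
  on the configured share schedules, not on any real actor's behaviour; no
  conclusion about named organizations can be drawn from it.
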