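# dahnet

Network analysis of development assistance for health (DAH) flows.

Global health financing moves as annual flows of disbursed funds from
**sources** (governments, foundations, corporations) through **channels**
(bilateral and multilateral agencies, NGOs, global health initiatives) to
**recipient countries**, disaggregated by health area.  `dahnet` turns such
flow tables into annual directed weighted networks, classifies actors with
a four-category typology (public, private, civil society, public–private
partnership), and measures each actor's structural position — the
quantitative backbone for studying how financial power in global health
has shifted from an almost purely public landscape toward a mixed one.

The core metric is **generalized closeness centrality** on the weighted
directed graph.  With `w` the weighted adjacency (edge weights are summed
USD amounts in the direction money flows) and a tuning parameter `α`,

    d^{wα}(i, j) = min over paths i→j of Σ_hops (1 / w_hop)^α
    C_C^{wα}(i)  = [ Σ_j d^{wα}(i, j) ]^{-1}

`α = 0` counts hops, `α = 1` is classic weighted distance on costs `1/w`,
and the default `α = 0.5` balances the number of ties against their
intensity.  Alongside closeness the package computes out-degree, in-degree
and channel degree centrality (distinct funders + distinct recipient
countries per channel), per-year rankings, and by-type averages.

Because the underlying disbursement dataset is restricted-access, a seeded
synthetic generator reproduces its statistical structure — five-fold actor
growth with a 2005–2011 CSO surge, public source shares falling
0.945 → 0.813 and public channel shares 0.924 → 0.499 over 1990–2015,
annual totals rising from USD 7B to 36B, cause-specific single-area CSOs,
and records with unspecified endpoints — so the entire pipeline is testable
and reproducible from scratch.  See `docs/methods.md` for the model and
its assumptions.

## Worked example

```python
import dahnet

cfg = dahnet.default_config_mdg_era()          # seeded study conditions
flows = dahnet.drop_unspecified(dahnet.generate(cfg))
registry = dahnet.make_registry(cfg)

series = dahnet.graph_series(flows, registry=registry)
summary = dahnet.landscape_summary(flows, registry, series)
print(summary.loc[summary.year.isin([1990, 2002, 2015]),
                  ["year", "total_dah_usd", "n_actors", "n_edges",
                   "source_share_public", "channel_share_public"]])
```

```
 year  total_dah_usd  n_actors  n_edges  source_share_public  channel_share_public
 1990   6.771621e+09        60      404             0.943145              0.921437
 2002   1.516311e+10       113      811             0.883268              0.766435
 2015   3.540414e+10       282     1948             0.811076              0.497571
```

The cleaned 1990 snapshot holds 60 actors exchanging USD 6.77B (the 7B
schedule minus dropped unspecified records), 94.3% of it from public
sources; by 2015 the network has grown to 282 actors and USD 35.4B, with
public channels handling less than half.  Closeness then ranks actors by
how quickly their funding reaches the rest of the 2015 network:

```python
from dahnet import MetricConfig, generalized_closeness, rank_actors
closeness = generalized_closeness(series[2015], MetricConfig(alpha=0.5))
print(rank_actors(closeness, 2015, "closeness").head(3))
```

```
   year  actor_id     metric        value  rank
0  2015  cso_0063  closeness  7779.813689     1
1  2015  cso_0124  closeness  6491.122680     2
2  2015  cso_0121  closeness  5618.794760     3
```

(Values are unnormalized reciprocal distance sums; only their ordering is
meaningful.)  The single-area statistic counts cause-specific CSO channels:

```python
count, fraction = dahnet.single_health_area_share(flows, registry)
# -> (52, 0.3467): 52 of 150 CSO channels fund exactly one health area
```

The same pipeline is available from the shell:

```sh
dahnet run-all --seed 1990 --outdir out/
```

which writes `flows.csv`, `actors.csv`, `landscape_summary.csv`,
`centrality.csv`, per-year ranking tables, `top_cso_closeness.csv`, GEXF
graph exports and a JSON run manifest, all byte-identical across runs with
the same seed.

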