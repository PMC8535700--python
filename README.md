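# aqnet — spatial association networks of multi-city air pollution

`aqnet` turns a daily multi-city pollutant panel (AQI plus PM2.5, PM10,
SO2, CO, NO2, O3) into a **directed spatial association network** and
characterizes how pollution is transmitted between cities:

1. **Network inference.** For every ordered city pair (x, y) and every
   lag order p in a configured range (default 1–10 days), the pairwise
   Granger-causality F test compares

   `y_t = α + Σ γ_i y_{t−i} + ε_t`  (restricted)

   against the regression that adds `Σ β_i x_{t−i}` (unrestricted), via

   `F = [(SSR_r − SSR_u)/p] / [SSR_u/(T − 2p − 1)]`.

   An edge x → y is drawn when the per-lag rejections at the 10% level
   satisfy the aggregation rule (majority of lags, by default). Series
   are ADF-screened first and differenced until stationary; missing
   days are filled with the mean of the nearest observations on either
   side.
2. **Network statistics** (binary directed graphs, the standard
   Krackhardt/Freeman conventions): density, efficiency, connectedness,
   average geodesic distance, cohesion index; per-city out/in degree,
   degree and betweenness centrality, and the spillover / receiver /
   equivalent role given by the sign of out-degree − in-degree.
3. **Cohesive subgroups** via CONCOR (convergence of iterated
   correlations), recursively bisecting cities by the correlation
   structure of their adjacency row‖column profiles (depth 2 → up to
   four subgroups), each subgroup labelled spillover / intermediary /
   receiver by its aggregate flow balance.
4. **QAP regression**: the AQI network regressed on the six pollutant
   networks cell-by-cell (diagonal dropped), with permutation p-values
   obtained by jointly permuting rows and columns of the dependent
   matrix (default 5000 draws) — the appropriate inference for
   relational data, where ordinary standard errors are invalid.

Because real monitoring extracts are rarely shareable, the package
ships a **synthetic panel generator** with a planted directed causal
network, winter-peaked seasonality, cross-pollutant structure and
injectable missingness, so every stage can be validated against known
ground truth. It is aimed at environmental statisticians and
epidemiologists studying regional transmission of air pollution.

## Worked example

```python
import aqnet

spec = aqnet.PanelSpec(n_cities=10, n_periods=400, seed=1)
truth = aqnet.planted_matching(10, 4, seed=2, coupling=0.8)
panel = aqnet.simulate_panel(spec, truth, aqnet.SeasonalProfile(amplitude=0.0),
                             missing_rate=0.01)

stat = aqnet.ensure_stationary(aqnet.impute_missing(panel))
net, evidence = aqnet.build_network(stat, "AQI",
                                    aqnet.GrangerConfig(lag_min=1, lag_max=5))
print("edges:", net.n_edges, "planted:", truth.adjacency.sum())
print(aqnet.summarize(net))

fit = aqnet.qap_regression(
    net.adjacency,
    [aqnet.build_network(stat, p, aqnet.GrangerConfig(lag_max=5))[0].adjacency
     for p in ("PM2.5", "PM10", "SO2")],
    aqnet.QAPConfig(n_permutations=1999, seed=0),
    predictor_names=["PM2.5", "PM10", "SO2"],
)
for name, c in fit.coefficients.items():
    print(f"{name:6s} coef={c['estimate']:+.3f}  p={c['p_value']:.4f}")
print(f"R2={fit.r_squared:.3f}  adj R2={fit.adj_r_squared:.3f}  "
      f"p(R2)={fit.r_squared_p:.4f}")
```

prints

```
edges: 7 planted: 4
NetworkSummary(density=0.07777777777777778, efficiency=1.0,
connectedness=0.2222222222222222, average_distance=1.2222222222222223,
cohesion_index=0.08888888888888889, n_components=4)
PM2.5  coef=+0.235  p=0.0515
PM10   coef=+0.402  p=0.0080
SO2    coef=+0.064  p=0.1530
R2=0.348  adj R2=0.326  p(R2)=0.0020
```

All four planted edges are recovered (7 observed edges = 4 true + 3
false positives, consistent with the 10% per-pair level); the network
is sparse, so density is low and efficiency is 1 (no redundant link).
The QAP fit attributes the AQI network chiefly to the particulate
networks — their pollutant series track the AQI anomaly most tightly
in the generator — while the weakly-coupled SO2 network is not
significant; R² carries a permutation p-value of 0.002.

The same pipeline is scriptable from the shell:

```
aqnet simulate --cities 35 --periods 879 --edges 16 --seed 1 --out panel/
aqnet run-all --input panel/panel.csv --lags 1:10 --alpha 0.10 \
      --aggregation majority --permutations 5000 --seed 1 --out run/
```

`run/` then contains the panel, stationarity ledger, one adjacency
matrix / GraphML / UCINET DL file per pollutant, the pair-level test
evidence, the network and node summary tables, the CONCOR partition
with roles, the QAP table, and a `report.json` tying it together.

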