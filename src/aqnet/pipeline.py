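"""End-to-end orchestration: simulate/load -> preprocess -> networks ->
metrics -> blockmodel -> QAP, with every intermediate persisted.

A single global seed drives all randomness: stage seeds are derived
deterministically with ``numpy.random.SeedSequence(seed).spawn``, so a
rerun with the same configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata as importlib_metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as net_io
from .blockmodel import BlockPartition, ConcorConfig, concor, partition_table, subgroup_roles
from .granger import GrangerConfig, build_network, pair_results_frame
from .metrics import node_summaries, node_table, summarize, summary_table
from .preprocess import ensure_stationary, half_year_means, impute_missing
from .qap import QAPConfig, qap_regression
from .synthetic import (
    PanelSpec,
    PlantedNetwork,
    SeasonalProfile,
    planted_matching,
    simulate_panel,
    write_ground_truth,
)

__all__ = ["RunConfig", "RunReport", "run"]

log = logging.getLogger("aqnet")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` (panel CSV) or ``simulation``
    (keyword arguments understood by the synthetic generator) must be
    given.  ``dependent`` and ``predictors`` fix the QAP design: the
    composite-index network regressed on the individual pollutant
    networks.
    """

    output_dir: str | Path = "aqnet_run"
    input_path: str | Path | None = None
    simulation: dict | None = None
    pollutants: list[str] | None = None
    dependent: str = "AQI"
    predictors: list[str] | None = None
    granger: GrangerConfig = field(default_factory=GrangerConfig)
    concor: ConcorConfig = field(default_factory=ConcorConfig)
    qap: QAPConfig = field(default_factory=QAPConfig)
    stationarity_alpha: float = 0.05
    max_diffs: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, ctor in (("granger", GrangerConfig), ("concor", ConcorConfig),
                          ("qap", QAPConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = ctor(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        if self.input_path is not None:
            d["input_path"] = str(self.input_path)
        return d


@dataclass
class RunReport:
    """Everything a run computed, with provenance; the same content is
    persisted as ``report.json`` in the output directory."""

    summaries: pd.DataFrame
    nodes: pd.DataFrame
    partition: BlockPartition
    subgroup_roles: dict[int, str]
    qap: dict
    provenance: dict
    output_dir: Path


def _stage_seed(root: int, index: int) -> int:
    return int(
        np.random.SeedSequence(root).spawn(index + 1)[index].generate_state(1)[0]
        % (2**31)
    )


def _simulate_from_config(cfg: RunConfig, out: Path) -> pd.DataFrame:
    sim = dict(cfg.simulation or {})
    spec = PanelSpec(
        n_cities=sim.get("n_cities", 35),
        n_periods=sim.get("n_periods", 879),
        pollutants=tuple(sim.get("pollutants", PanelSpec.pollutants)),
        seed=_stage_seed(cfg.seed, 0),
    )
    if "adjacency" in sim:
        net = PlantedNetwork(
            np.asarray(sim["adjacency"]),
            lag=sim.get("lag", 1),
            coupling=sim.get("coupling", 0.8),
        )
    else:
        net = planted_matching(
            spec.n_cities,
            sim.get("n_edges", spec.n_cities // 2 - 1),
            seed=_stage_seed(cfg.seed, 1),
            lag=sim.get("lag", 1),
            coupling=sim.get("coupling", 0.8),
        )
    season = SeasonalProfile(
        amplitude=sim.get("amplitude", 20.0),
        phase=sim.get("phase", 15),
        baseline=sim.get("baseline", 80.0),
    )
    panel = simulate_panel(
        spec,
        net,
        season,
        noise_sd=sim.get("noise_sd", 1.0),
        missing_rate=sim.get("missing_rate", 0.0),
    )
    write_ground_truth(out / "ground_truth", spec, net, season)
    return panel


def run(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and persist every artifact.

    Stages: obtain panel (simulate or load) -> impute -> half-year
    summary -> stationarity screen -> one Granger network per pollutant
    -> whole-network and node statistics -> CONCOR subgroups on the
    dependent network -> QAP regression of the dependent network on the
    predictor networks.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/6: panel")
    if cfg.simulation is not None:
        panel = _simulate_from_config(cfg, out)
    else:
        panel = net_io.read_panel_csv(cfg.input_path)
    available = sorted(panel["pollutant"].unique())
    pollutants = cfg.pollutants or available
    missing = set(pollutants) - set(available)
    if missing:
        raise ValueError(f"pollutants absent from input: {sorted(missing)}")
    if cfg.dependent not in pollutants:
        raise ValueError(f"dependent pollutant {cfg.dependent!r} not analyzed")
    predictors = cfg.predictors or [p for p in pollutants if p != cfg.dependent]
    net_io.write_panel_csv(panel, out / "panel.csv")

    log.info("stage 2/6: preprocess")
    panel = impute_missing(panel)
    half_year_means(panel, cfg.dependent).to_csv(
        out / f"half_year_means_{cfg.dependent}.csv", index=False
    )
    stat = ensure_stationary(panel, alpha=cfg.stationarity_alpha,
                             max_diffs=cfg.max_diffs)
    stat.ledger.to_csv(out / "stationarity_ledger.csv", index=False)

    log.info("stage 3/6: Granger networks (%d pollutants)", len(pollutants))
    networks = {}
    for pol in pollutants:
        net, results = build_network(stat, pol, cfg.granger)
        networks[pol] = net
        safe = pol.replace(".", "")
        net_io.export_network(net, out / f"network_{safe}.csv", "csv_matrix")
        net_io.export_network(net, out / f"network_{safe}.graphml", "graphml")
        net_io.export_network(net, out / f"network_{safe}.dl", "dl")
        pair_results_frame(results).to_csv(
            out / f"pair_tests_{safe}.csv", index=False
        )
        log.debug("network %s: %d edges", pol, net.n_edges)

    log.info("stage 4/6: network statistics")
    summaries = summary_table({p: summarize(n) for p, n in networks.items()})
    summaries.to_csv(out / "network_summary.csv")
    dep_nodes = node_summaries(networks[cfg.dependent])
    nodes_df = node_table(dep_nodes)
    nodes_df.to_csv(out / f"node_summary_{cfg.dependent}.csv", index=False)

    log.info("stage 5/6: CONCOR blockmodel")
    partition = concor(networks[cfg.dependent], cfg.concor)
    roles = subgroup_roles(partition, dep_nodes)
    partition_table(partition, roles).to_csv(out / "partition.csv", index=False)
    (out / "split_tree.json").write_text(json.dumps(partition.tree, indent=2))

    log.info("stage 6/6: QAP regression (%s ~ %s)", cfg.dependent, predictors)
    qap_cfg = dataclasses.replace(cfg.qap, seed=_stage_seed(cfg.seed, 2))
    fit = qap_regression(
        networks[cfg.dependent].adjacency,
        [networks[p].adjacency for p in predictors],
        qap_cfg,
        predictor_names=predictors,
    )
    qap_rows = [
        {"variable": nm, "coefficient": fit.coefficients[nm]["estimate"],
         "p_value": fit.coefficients[nm]["p_value"]}
        for nm in fit.predictors
    ]
    qap_rows.append({"variable": "Intercept",
                     "coefficient": fit.intercept["estimate"],
                     "p_value": fit.intercept["p_value"]})
    qap_rows.append({"variable": "R2", "coefficient": fit.r_squared,
                     "p_value": fit.r_squared_p})
    qap_rows.append({"variable": "Adj-R2", "coefficient": fit.adj_r_squared,
                     "p_value": ""})
    pd.DataFrame(qap_rows).to_csv(out / "qap_regression.csv", index=False)

    qap_dict = dataclasses.asdict(fit)
    provenance = _provenance(cfg)
    report = {
        "provenance": provenance,
        "network_summary": json.loads(summaries.to_json()),
        "node_summary": json.loads(nodes_df.to_json(orient="records")),
        "partition": {"assignment": partition.assignment,
                      "roles": {str(k): v for k, v in roles.items()},
                      "converged": partition.converged},
        "qap": qap_dict,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("run complete: %s", out)
    return RunReport(
        summaries=summaries,
        nodes=nodes_df,
        partition=partition,
        subgroup_roles=roles,
        qap=qap_dict,
        provenance=provenance,
        output_dir=out,
    )


def _provenance(cfg: RunConfig) -> dict:
    # output_dir is where the run lands, not what it computes: leaving it
    # out keeps reports byte-identical across reruns into fresh directories
    cfg_dict = {k: v for k, v in cfg.to_dict().items() if k != "output_dir"}
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    versions = {}
    for pkg in ("aqnet", "numpy", "scipy", "pandas", "statsmodels", "networkx"):
        try:
            versions[pkg] = importlib_metadata.version(pkg)
        except importlib_metadata.PackageNotFoundError:
            versions[pkg] = "unknown"
    return {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": versions,
        "seed": cfg.seed,
    }
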