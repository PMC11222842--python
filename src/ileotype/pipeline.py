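"""End-to-end orchestration: simulate/load -> enterotype -> diversity ->
associations -> differential abundance -> report bundle.

A run is described by a :class:`RunConfig` (loadable from a YAML file,
overridable by CLI flags).  Outputs are plain TSV/JSON files in the
output directory; every file-writing stage logs the thresholds it used
and the JSON summary echoes the full configuration plus its hash, so a
re-run with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (AbundanceTable, read_abundance_table,
                        read_phenotype_table, to_relative,
                        write_abundance_table, write_phenotype_table)
from .diversity import alpha_diversity_table
from .enterotyping import fit_enterotypes
from .lefse import export_lefse, run_lefse
from .simulate import EffectConfig, build_default_template, simulate_cohort
from .stats import (correlation_network, genus_trait_correlations,
                    kruskal_wallis, pairwise_trait_tests)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("ileotype")


@dataclass
class RunConfig:
    """Inputs, thresholds and seed for one pipeline run.

    Either ``abundance_path`` (plus optionally ``phenotype_path``) is
    given, or ``simulate=True`` generates the default synthetic cohort.
    """

    out_dir: str = "ileotype_run"
    seed: int = 0
    # input mode
    simulate: bool = True
    abundance_path: str | None = None
    abundance_orientation: str = "taxa_rows"
    abundance_mode: str = "counts"
    phenotype_path: str | None = None
    # simulation parameters
    component_sizes: tuple[int, ...] = (76, 67, 57)
    theta: float = 60.0
    depth_range: tuple[int, int] = (21243, 59481)
    n_filler: int = 100
    richness_boost: int = 30
    effects: dict = field(default_factory=dict)
    # analysis parameters
    k_min: int = 2
    k_max: int = 10
    rho_min: float = 0.6
    p_max: float = 0.01
    network_top_n: int = 15
    alpha: float = 0.05
    lda_threshold: float = 4.0
    n_boot: int = 30

    def __post_init__(self) -> None:
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        for name, v, lo, hi in (("rho_min", self.rho_min, 0, 1),
                                ("p_max", self.p_max, 0, 1),
                                ("alpha", self.alpha, 0, 1)):
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.lda_threshold < 0:
            raise ValueError("lda_threshold must be >= 0")

    # -- (de)serialisation -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["component_sizes"] = list(self.component_sizes)
        d["depth_range"] = list(self.depth_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "component_sizes" in d:
            d["component_sizes"] = tuple(d["component_sizes"])
        if "depth_range" in d:
            d["depth_range"] = tuple(d["depth_range"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns the JSON summary as a dict.  A failing stage raises with the
    stage name; outputs written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = {"config_hash": chash, "seed": config.seed, "version": __version__}
    log.info("run %s: seed=%d k=[%d,%d] rho_min=%.3g p_max=%.3g alpha=%.3g "
             "lda_threshold=%.3g", chash, config.seed, config.k_min,
             config.k_max, config.rho_min, config.p_max, config.alpha,
             config.lda_threshold)

    stage = "input"
    try:
        if config.simulate:
            template = build_default_template(
                component_sizes=tuple(config.component_sizes),
                theta=config.theta, depth_range=tuple(config.depth_range),
                n_filler=config.n_filler, richness_boost=config.richness_boost)
            effects = EffectConfig(**config.effects) if config.effects else EffectConfig()
            cohort = simulate_cohort(template, effects, config.seed)
            table, phenotypes = cohort.abundance, cohort.phenotypes
            write_abundance_table(table, out / "abundance.tsv")
            write_phenotype_table(phenotypes, out / "phenotypes.tsv")
            _write_tsv(pd.DataFrame({"true_label": cohort.true_labels},
                                    index=table.sample_ids),
                       out / "true_labels.tsv", index_label="sample_id")
        else:
            if not config.abundance_path:
                raise ValueError("abundance_path required when simulate=False")
            table = read_abundance_table(config.abundance_path,
                                         orientation=config.abundance_orientation,
                                         mode=config.abundance_mode)
            phenotypes = (read_phenotype_table(config.phenotype_path)
                          if config.phenotype_path else None)

        stage = "enterotyping"
        rel = to_relative(table)
        res = fit_enterotypes(rel, range(config.k_min, config.k_max + 1))
        warning = None
        if config.k_min == config.k_max:
            warning = f"k selection constrained to k={config.k_min}"
            log.warning(warning)
        _write_tsv(res.assignments(), out / "enterotypes.tsv", index_label="sample_id")
        _write_tsv(pd.DataFrame({"k": list(res.ch_by_k),
                                 "ch": list(res.ch_by_k.values())}),
                   out / "ch_by_k.tsv")
        _write_tsv(res.mds_coordinates(), out / "mds_coordinates.tsv",
                   index_label="sample_id")

        stage = "diversity"
        diversity_summary = None
        if table.mode == "counts":
            div = alpha_diversity_table(table)
            ddf = div.data.copy()
            ddf["enterotype"] = res.labels
            _write_tsv(ddf, out / "diversity.tsv", index_label="sample_id")
            kw = {}
            for idx in ("chao1", "shannon"):
                groups = [ddf.loc[ddf["enterotype"] == c, idx].to_numpy()
                          for c in range(1, res.k_selected + 1)]
                h, p = kruskal_wallis(groups)
                kw[idx] = {"H": h, "p": p}
            diversity_summary = {"kruskal_wallis": kw, **div.meta}

        stage = "associations"
        net = correlation_network(rel, config.rho_min, config.p_max,
                                  config.network_top_n)
        net.to_edge_list(out / "network_edges.tsv")
        net.to_graphml(out / "network.graphml")
        trait_summary = None
        if phenotypes is not None:
            tt = pairwise_trait_tests(phenotypes, res.labels)
            _write_tsv(tt, out / "trait_tests.tsv")
            gc = genus_trait_correlations(rel, phenotypes)
            _write_tsv(gc, out / "genus_trait_correlations.tsv")
            trait_summary = {
                "n_significant_pairs": int((tt["p"] < config.alpha).sum()),
                "multiple_testing_corrected": False,
            }

        stage = "lefse"
        lef = run_lefse(table, res.labels, alpha=config.alpha,
                        lda_threshold=config.lda_threshold,
                        n_boot=config.n_boot, seed=config.seed)
        export_lefse(lef, out / "lefse.tsv", only_passed=False)

        stage = "summary"
        drivers = res.driver_genus_per_cluster
        summary = {
            **stamp,
            "config": config.to_dict(),
            "k_selected": res.k_selected,
            "cluster_sizes": res.cluster_sizes,
            "driver_genus_per_cluster": drivers,
            "dominant_mean_abundance_pct": {
                f"ET{c}": round(res.mean_abundance(drivers[c - 1], c) * 100, 4)
                for c in range(1, res.k_selected + 1)},
            "silhouette_mean": round(res.silhouette_mean, 6),
            "diversity": diversity_summary,
            "traits": trait_summary,
            "lefse_passed": sorted(lef.passed["taxon"].tolist()),
            "warning": warning,
        }
        with open(out / "summary.json", "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
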