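"""End-to-end orchestration: map -> prep -> trials -> consensus -> report.

A :class:`PipelineConfig` (YAML-serializable) fully determines a run; given
the same config — master seed included — two runs write byte-identical
tabular outputs.  In synthetic mode the observational table is simulated
from a ground-truth DAG; in real mode the genomic tracks are read from
disk, mapped onto eG4 regions and discretized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .association import assignments_frame, spearman_matrix, \
    tss_proximal_assignments
from .citest import CITestConfig
from .consensus import RobustnessRecord, common_network, resolve_directions, \
    run_trials, select_n
from .graphs import PDAG
from .mapping import build_region_table
from .prep import SamplingConfig, discretize
from .synthetic import GroundTruthSpec, default_spec, simulate_observations, \
    DEFAULT_STRATUM_SIZES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; see the YAML schema in docs/methods.md.

    mode
        ``"synthetic"`` (simulate from a ground-truth spec) or ``"real"``
        (read tracks from ``inputs`` paths: regions, pg4s, mm_plus,
        mm_minus, phylop, segmentation, atac, tf_peaks, tss).
    """

    mode: str = "synthetic"
    outdir: str = "g4causal_run"
    master_seed: int = 0
    # synthetic mode
    spec_yaml: str | None = None          # None -> shipped default network
    n_per_stratum: dict | int | None = None
    # real mode
    inputs: dict = field(default_factory=dict)
    recruitment: str = "total"
    stability_cutoff: float = 25.0
    median_ties: str = "low"
    # learning
    sampling_strategy: str = "equal"
    k_grid: tuple = (7000,)
    n_grid: tuple = tuple(range(1, 11))
    n_sample_sets: int = 10
    n_trials: int = 50
    alpha: float = 0.05
    n_permutations: int = 1000
    select_n_value: int | None = None     # None -> closest to (1, 1)
    protected_sinkless_nodes: tuple = ("Stability",)
    tss_window_bp: int = 200

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            required = ["regions", "pg4s", "mm_plus", "mm_minus", "phylop",
                        "segmentation", "atac"]
            for key in required:
                if key not in self.inputs:
                    raise ValueError(f"real mode requires inputs.{key}")
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(self.inputs[key])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("k_grid", "n_grid", "protected_sinkless_nodes"):
            if key in doc:
                doc[key] = tuple(doc[key])
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        doc = asdict(self)
        for key in ("k_grid", "n_grid", "protected_sinkless_nodes"):
            doc[key] = list(doc[key])
        return yaml.safe_dump(doc, sort_keys=False)


@dataclass
class PipelineResult:
    outdir: Path
    discrete_table: pd.DataFrame
    robustness: pd.DataFrame
    resolved_network: PDAG
    selected_n: int


class _RealInputs:
    """Adapter presenting on-disk tracks with the GenomeFixture interface."""

    def __init__(self, inputs: dict):
        regions = gio.read_bed(inputs["regions"])
        regions = regions.rename(columns={"name": "region_id",
                                          "score": "eg4_signal"})
        if "region_id" not in regions.columns:
            regions["region_id"] = [f"eG4_{i:05d}" for i in range(len(regions))]
        if "eg4_signal" not in regions.columns:
            raise ValueError("region BED needs a score column (eG4 signal)")
        regions["stratum"] = inputs.get("stratum", "NA")
        self.regions = regions
        self.pg4s = gio.read_gff3(inputs["pg4s"])
        self.mm_track = gio.read_stranded_bedgraph_pair(inputs["mm_plus"],
                                                        inputs["mm_minus"])
        self.phylop_track = gio.read_bedgraph(inputs["phylop"])
        seg = gio.read_bed(inputs["segmentation"])
        self.segmentation = seg.rename(columns={"name": "state"})
        self.atac_fragments = gio.read_bed(inputs["atac"])
        if "tf_peaks" in inputs:
            peaks = gio.read_bed(inputs["tf_peaks"])
            self.tf_peaks = peaks.rename(columns={"name": "tf"})
        else:
            self.tf_peaks = pd.DataFrame(columns=["chrom", "start", "end",
                                                  "tf"])
        if "chrom_sizes" in inputs:
            sizes = pd.read_csv(inputs["chrom_sizes"], sep="\t", header=None,
                                index_col=0).iloc[:, 0]
            self.chrom_sizes = {str(k): int(v) for k, v in sizes.items()}
        else:
            track_max = pd.concat([self.regions, self.segmentation])
            self.chrom_sizes = {c: int(g.end.max())
                                for c, g in track_max.groupby("chrom")}
        self.tss = gio.read_tss(inputs["tss"]) if "tss" in inputs else \
            pd.DataFrame(columns=["chrom", "pos", "gene_id", "strand"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write every artifact under ``outdir``.

    Artifacts: config.yaml, region_table.tsv (real mode), discrete_table.tsv,
    correlations.tsv (real mode), robustness.tsv, common-network edge list
    and adjacency matrix, resolved_network.{tsv,dot}, tss_assignments.tsv
    (when TSSs are available) and run.log.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("g4causal")
    root.addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> PipelineResult:
    (outdir / "config.yaml").write_text(config.to_yaml())

    if config.mode == "synthetic":
        spec = GroundTruthSpec.from_yaml(Path(config.spec_yaml).read_text()) \
            if config.spec_yaml else default_spec()
        sizes = config.n_per_stratum or dict(DEFAULT_STRATUM_SIZES)
        discrete = simulate_observations(spec, sizes, seed=config.master_seed)
        logger.info("simulated %d rows in %d strata", len(discrete),
                    discrete.stratum.nunique())
    else:
        fixture = _RealInputs(config.inputs)
        region_table = build_region_table(fixture,
                                          recruitment=config.recruitment)
        gio.write_table(region_table, outdir / "region_table.tsv")
        corr = spearman_matrix(region_table)
        corr.rho.to_csv(outdir / "correlations.tsv", sep="\t")
        if len(fixture.tss):
            assigns = tss_proximal_assignments(
                region_table, fixture.tss, window_bp=config.tss_window_bp,
                stability_cutoff=config.stability_cutoff)
            gio.write_table(assignments_frame(assigns),
                            outdir / "tss_assignments.tsv")
        discrete = discretize(region_table,
                              stability_cutoff=config.stability_cutoff,
                              median_ties=config.median_ties)
    gio.write_table(discrete, outdir / "discrete_table.tsv")

    ci_cfg = CITestConfig(alpha=config.alpha,
                          n_permutations=config.n_permutations,
                          seed=config.master_seed)
    records = []
    models_by_key = {}
    for k in config.k_grid:
        samp = SamplingConfig(strategy=config.sampling_strategy, k=k,
                              seed=config.master_seed)
        record, models_by_n = run_trials(
            discrete, samp, ci_config=ci_cfg,
            n_sample_sets=config.n_sample_sets, n_trials=config.n_trials,
            n_grid=list(config.n_grid), master_seed=config.master_seed)
        records.append(record.frame)
        models_by_key[k] = (record, models_by_n)
    robustness = pd.concat(records, ignore_index=True)
    gio.write_table(robustness, outdir / "robustness.tsv")

    # consensus at the best (strategy, k) by AUC, N by upper-right distance
    best_k = max(config.k_grid,
                 key=lambda k: models_by_key[k][0].frame.auc.iloc[0])
    record, models_by_n = models_by_key[best_k]
    if config.select_n_value is not None:
        n_sel = config.select_n_value
    else:
        pts = {int(r.N): (r.acc_mean, r.cov_mean)
               for r in record.frame.itertuples()}
        n_sel = select_n(pts)
    net = common_network(models_by_n[n_sel])
    net.to_edge_frame().to_csv(outdir / "common_network_edges.tsv",
                               sep="\t", index=False)
    resolved = resolve_directions(
        net, protected_sinkless_nodes=config.protected_sinkless_nodes)
    resolved.to_adjacency_frame().to_csv(
        outdir / "resolved_network_adjacency.tsv", sep="\t")
    resolved.to_edge_frame().to_csv(outdir / "resolved_network_edges.tsv",
                                    sep="\t", index=False)
    (outdir / "resolved_network.dot").write_text(resolved.to_dot())
    logger.info("selected k=%s N=%d; resolved network: %d directed, "
                "%d undirected edges", best_k, n_sel,
                len(resolved.directed_edges), len(resolved.undirected_edges))
    return PipelineResult(outdir=outdir, discrete_table=discrete,
                          robustness=robustness, resolved_network=resolved,
                          selected_n=n_sel)
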