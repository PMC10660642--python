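"""Configuration-driven end-to-end pipeline.

Runs synthetic-data generation (or loads user data), normalization,
per-cell-type differential expression, TF activity, per-(cell type,
condition) network inference, differential targeting, community and
differential-community analysis with focal-TF Jaccard comparison, and
rewiring classification, serializing every stage to TSV/JSON with a
manifest of parameters, seeds, and output checksums. A rerun with the same
configuration and seed reproduces every output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from . import synth as gsynth
from .activity import activity_per_cell, build_design, summarize_activity
from .communities import (
    alpaca_differential,
    condor_partition,
    focal_community_similarity,
    positive_projection,
)
from .grn import Grn, PandaConfig, coexpression_network, panda_infer
from .preprocess import log_normalize, wilcoxon_de
from .rewiring import REPORTED_CATEGORIES, extract_focal_subnetwork, rewiring_summary
from .targeting import differential_targeting, hypergeometric_enrichment, targeting_summary

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("grnrewire")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run. Paper-derived defaults: log2FC gate
    0.1, adjusted-p gate 0.05, minimum 5 regulon targets per TF."""

    # synthetic study (ignored when input_dir is given)
    n_tfs: int = 12
    n_genes: int = 80
    cell_types: tuple[str, ...] = ("excitatory", "astrocyte", "microglia")
    conditions: tuple[str, str] = ("mutant", "wt")
    cells_per_type_per_condition: int = 150
    depth: float = 2000.0
    motif_density: float = 0.2
    ppi_density: float = 0.3
    de_lfc: float = 1.0
    module_boost: float = 1.0
    n_de_per_type: int = 8
    # user data (optional): directory with MTX triplet + priors
    input_dir: str | None = None
    # focal analysis
    focal_tf: str = "TF01"
    focal_gene_set: tuple[str, ...] = ()
    mechanism_proteins: tuple[str, ...] = ()
    # thresholds
    lfc_min: float = 0.1
    alpha: float = 0.05
    min_targets: int = 5
    # network inference
    panda: PandaConfig = field(default_factory=PandaConfig)
    # seeds
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.panda, dict):
            self.panda = PandaConfig(**self.panda)
        self.cell_types = tuple(self.cell_types)
        self.conditions = tuple(self.conditions)
        self.focal_gene_set = tuple(self.focal_gene_set)
        self.mechanism_proteins = tuple(self.mechanism_proteins)
        self.validate()

    def validate(self) -> None:
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValueError("conditions must be two distinct labels (case, control)")
        if not self.focal_tf:
            raise ValueError("a focal TF must be configured")
        for name in ("lfc_min", "alpha", "min_targets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panda"] = asdict(self.panda) if not isinstance(self.panda, dict) else self.panda
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: gsynth.SyntheticTruth | None
    adata: object
    de_tables: dict[str, pd.DataFrame]
    activity_profile: pd.DataFrame
    activity_change: pd.DataFrame
    grns: dict[tuple[str, str], Grn]
    targeting_tables: dict[str, pd.DataFrame]
    enrichment: dict[str, tuple[int, float]]
    partitions: dict[tuple[str, str], object]
    differential: dict[str, object]
    ji_matrix: pd.DataFrame | None
    rewiring_records: dict[str, list]
    manifest: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every stage and serialize a result bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage: %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # ------------------------------------------------------------------ data
    stage("data")
    case, control = config.conditions
    if config.input_dir is None:
        truth0 = gsynth.default_truth(
            n_tfs=config.n_tfs,
            n_genes=config.n_genes,
            cell_types=config.cell_types,
            conditions=config.conditions,
            seed=config.seed,
        )
        motif, ppi, regulon = gsynth.generate_priors(
            config.n_tfs,
            config.n_genes,
            config.motif_density,
            config.ppi_density,
            seed=config.seed,
        )
        truth = gsynth.plant_perturbation(
            truth0,
            de_lfc=config.de_lfc,
            module_boost=config.module_boost,
            n_de_per_type=config.n_de_per_type,
            regulon=regulon,
        )
        cond_priors = gsynth.condition_priors(truth, motif, ppi)
        adata = gsynth.simulate_counts(
            truth,
            cells_per_type_per_condition=config.cells_per_type_per_condition,
            depth=config.depth,
            seed=config.seed,
            regulon=regulon,
        )
        focal_tf = truth.focal_tf
        focal_set = set(config.focal_gene_set) or {
            rw.target for rw in truth.planted_rewired
        }
        mech = list(config.mechanism_proteins) or sorted(
            {rw.mechanism for rw in truth.planted_rewired}
        )
    else:
        indir = Path(config.input_dir)
        adata = gio.read_matrix(indir)
        motif = gio.edges_to_frame(gio.read_edges(indir / "motif_prior.tsv"))
        ppi = gio.edges_to_frame(gio.read_edges(indir / "ppi_prior.tsv"))
        reg_edges = gio.read_edges(indir / "regulon.tsv")
        regulon = reg_edges.rename(
            columns={"source": "tf", "target": "target", "weight": "mode"}
        )
        ppi = ppi.reindex(index=motif.index, columns=motif.index).fillna(0.0)
        np.fill_diagonal(ppi.values, 1.0)
        truth = None
        cond_priors = {c: (motif, ppi) for c in config.conditions}
        focal_tf = config.focal_tf
        focal_set = set(config.focal_gene_set)
        mech = list(config.mechanism_proteins)
    if focal_tf not in motif.index:
        raise ValueError(f"focal TF {focal_tf!r} absent from the motif prior")
    done("data")

    # ------------------------------------------------------- preprocess + DE
    stage("de")
    log_normalize(adata)
    de_tables = {}
    for ct in pd.unique(adata.obs["cell_type"]):
        de_tables[ct] = wilcoxon_de(
            adata, ct, case, control, lfc_min=config.lfc_min, alpha=config.alpha
        )
    done("de")

    # --------------------------------------------------------------- activity
    stage("activity")
    design, dropped = build_design(
        regulon, list(adata.var_names), min_targets=config.min_targets
    )
    acts = activity_per_cell(adata, design)
    activity_profile, activity_change = summarize_activity(
        acts, adata.obs[["cell_type", "condition"]], case, control
    )
    done("activity")

    # ------------------------------------------------------------------ grns
    stage("grn")
    L = np.asarray(adata.layers["lognorm"])
    genes = list(adata.var_names)
    grns: dict[tuple[str, str], Grn] = {}
    for ct in pd.unique(adata.obs["cell_type"]):
        for cond in config.conditions:
            mask = (
                (adata.obs["cell_type"] == ct) & (adata.obs["condition"] == cond)
            ).values
            coexpr = coexpression_network(L[mask], genes)
            m, p = cond_priors[cond]
            grns[(ct, cond)] = panda_infer(
                m, p, coexpr, config.panda, cell_type=ct, condition=cond
            )
    done("grn")

    # ------------------------------------------------------------- targeting
    stage("targeting")
    targeting_tables = {}
    enrichment = {}
    for ct in pd.unique(adata.obs["cell_type"]):
        table = differential_targeting(
            grns[(ct, case)], grns[(ct, control)], focal_set=focal_set
        )
        targeting_tables[ct] = table
        if focal_set:
            sel = set(table.loc[table["selected"], "gene"])
            universe = set(table["gene"])
            enrichment[ct] = hypergeometric_enrichment(
                sel, focal_set & universe, universe
            )
    done("targeting")

    # ----------------------------------------------------------- communities
    stage("communities")
    partitions = {}
    differential = {}
    for ct in pd.unique(adata.obs["cell_type"]):
        case_edges = positive_projection(grns[(ct, case)])
        ctrl_edges = positive_projection(grns[(ct, control)])
        partitions[(ct, case)] = condor_partition(case_edges, seed=config.seed)
        partitions[(ct, control)] = condor_partition(ctrl_edges, seed=config.seed)
        differential[ct] = alpaca_differential(
            case_edges, ctrl_edges, focal_tf, seed=config.seed, baseline=False
        )
        differential[ct].baseline = partitions[(ct, control)]
    ji = (
        focal_community_similarity(differential)
        if len(differential) >= 2
        else None
    )
    done("communities")

    # -------------------------------------------------------------- rewiring
    stage("rewiring")
    rewiring_records = {}
    for ct in pd.unique(adata.obs["cell_type"]):
        g_case, g_ctrl = grns[(ct, case)], grns[(ct, control)]
        rewiring_records[ct] = extract_focal_subnetwork(
            g_case,
            g_ctrl,
            g_case.ppi_out,
            g_ctrl.ppi_out,
            focal_tf,
            focal_set,
            mech,
        )
    done("rewiring")

    # ------------------------------------------------------------- serialize
    stage("write")
    outputs: dict[str, Path] = {}
    if truth is not None:
        (outdir / "truth.json").write_text(truth.to_json())
        outputs["truth"] = outdir / "truth.json"
    de_all = pd.concat(de_tables.values(), ignore_index=True)
    de_all.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    outputs["de_table"] = outdir / "de_table.tsv"
    activity_profile.to_csv(outdir / "activity_profile.tsv", sep="\t", index=False)
    activity_change.to_csv(outdir / "activity_change.tsv", sep="\t", index=False)
    outputs["activity_profile"] = outdir / "activity_profile.tsv"
    outputs["activity_change"] = outdir / "activity_change.tsv"
    for (ct, cond), grn in grns.items():
        p = outdir / f"grn_{ct}_{cond}.tsv"
        grn.to_frame().to_csv(p, sep="\t", index=False)
        outputs[f"grn_{ct}_{cond}"] = p
    tg_all = pd.concat(targeting_tables.values(), ignore_index=True)
    tg_all.to_csv(outdir / "targeting.tsv", sep="\t", index=False)
    outputs["targeting"] = outdir / "targeting.tsv"
    targeting_summary(list(targeting_tables.values())).to_csv(
        outdir / "targeting_summary.tsv", sep="\t", index=False
    )
    outputs["targeting_summary"] = outdir / "targeting_summary.tsv"
    part_frames = []
    for (ct, cond), part in partitions.items():
        f = part.to_frame()
        f.insert(0, "cell_type", ct)
        f.insert(1, "condition", cond)
        part_frames.append(f)
    pd.concat(part_frames, ignore_index=True).to_csv(
        outdir / "partitions.tsv", sep="\t", index=False
    )
    outputs["partitions"] = outdir / "partitions.tsv"
    diff_frames = []
    for ct, res in differential.items():
        f = res.to_frame()
        f.insert(0, "cell_type", ct)
        diff_frames.append(f)
    pd.concat(diff_frames, ignore_index=True).to_csv(
        outdir / "differential_communities.tsv", sep="\t", index=False
    )
    outputs["differential_communities"] = outdir / "differential_communities.tsv"
    if ji is not None:
        ji.to_csv(outdir / "jaccard_matrix.tsv", sep="\t")
        outputs["jaccard_matrix"] = outdir / "jaccard_matrix.tsv"
    sign_frames, mag_frames = [], []
    for ct, recs in rewiring_records.items():
        if recs:
            s, m = rewiring_summary(recs)
            sign_frames.append(s)
            mag_frames.append(m)
    if sign_frames:
        pd.concat(sign_frames, ignore_index=True).to_csv(
            outdir / "rewiring_sign.tsv", sep="\t", index=False
        )
        pd.concat(mag_frames, ignore_index=True).to_csv(
            outdir / "rewiring_magnitude.tsv", sep="\t", index=False
        )
        outputs["rewiring_sign"] = outdir / "rewiring_sign.tsv"
        outputs["rewiring_magnitude"] = outdir / "rewiring_magnitude.tsv"

    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "dropped_tfs": dropped,
        "enrichment": {ct: {"overlap": k, "p": p} for ct, (k, p) in enrichment.items()},
        "checksums": {name: _checksum(p) for name, p in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    done("write")
    for name, t in timings.items():
        log.info("stage %s took %.2fs", name, t)

    return PipelineResult(
        config=config,
        truth=truth,
        adata=adata,
        de_tables=de_tables,
        activity_profile=activity_profile,
        activity_change=activity_change,
        grns=grns,
        targeting_tables=targeting_tables,
        enrichment=enrichment,
        partitions=partitions,
        differential=differential,
        ji_matrix=ji,
        rewiring_records=rewiring_records,
        manifest=manifest,
    )
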