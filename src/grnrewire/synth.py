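"""Synthetic single-nucleus expression data with planted regulatory structure.

Emulates the statistical shape of a two-condition (mutant vs. wild-type),
multi-cell-type snRNA-seq study together with the prior-knowledge inputs the
network analysis consumes: a TF-gene motif prior, a symmetric TF-TF
protein-interaction prior, and a signed regulon table. Every perturbation is
planted with full ground truth so each downstream stage (differential
expression, TF activity, network inference, differential targeting,
differential communities, rewiring classification) can be scored against
what was actually put in.

Counts are negative binomial with per-gene dispersion; cell identity is a
sparse marker program; biological replicates are mimicked by jittering
baseline means; library sizes are lognormal. Rewired regulatory/cooperative
edges are realized as per-condition edits to the motif and PPI priors (the
regulation axis lives in the motif layer, the cooperation axis in the PPI
layer), combined with coexpression support, so the intended presence/absence
pattern survives message-passing network inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad

__all__ = [
    "SyntheticTruth",
    "PlantedActivity",
    "PlantedModule",
    "PlantedRewiring",
    "default_truth",
    "generate_priors",
    "plant_perturbation",
    "simulate_counts",
    "condition_priors",
    "write_synthetic_bundle",
]

# The four reported rewiring categories (see grnrewire.rewiring).
REWIRING_CATEGORIES = (
    "cooperation_gained",
    "cooperation_lost",
    "regulation_change_cooperation_gained",
    "regulation_change_cooperation_lost",
)


@dataclass
class PlantedActivity:
    tf: str
    cell_types: tuple[str, ...]
    direction: int  # +1: targets shifted up (per mode) in case cells


@dataclass
class PlantedModule:
    tfs: tuple[str, ...]
    genes: tuple[str, ...]
    cell_type: str
    boost: float = 0.0

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(t, g) for t in self.tfs for g in self.genes}


@dataclass
class PlantedRewiring:
    target: str  # gene that is also a protein in the cooperativity layer
    mechanism: str  # mechanism protein (a TF node of the PPI layer)
    category: str  # intended 4-way category
    # dedicated motif targets the pair shares when (and only when) it
    # cooperates; cooperation in the converged model is regulatory-profile
    # similarity, so shared targets are how cooperation is made real
    support_genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in REWIRING_CATEGORIES:
            raise ValueError(f"unknown rewiring category: {self.category!r}")


@dataclass
class SyntheticTruth:
    """Complete ground truth for one synthetic study.

    The gene universe contains the TF genes as its first entries (targets of
    rewiring must be proteins of the cooperativity layer, i.e. TFs, and they
    are expressed genes at the same time -- as the real mechanism proteins
    are)."""

    tf_names: list[str]
    gene_names: list[str]
    cell_types: list[str]
    conditions: tuple[str, str]  # (case, control)
    baseline_means: np.ndarray  # per gene, > 0
    dispersion: np.ndarray  # per gene NB size parameter, > 0
    seed: int
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    planted_de: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_active_tf: PlantedActivity | None = None
    planted_module: PlantedModule | None = None
    planted_rewired: list[PlantedRewiring] = field(default_factory=list)
    mechanism_support: dict[str, tuple[str, ...]] = field(default_factory=dict)
    focal_signature: tuple[str, ...] = ()
    focal_tf: str = ""

    def __post_init__(self):
        self.baseline_means = np.asarray(self.baseline_means, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValueError("exactly two distinct conditions are required")
        if self.baseline_means.shape != (len(self.gene_names),):
            raise ValueError("baseline_means must align with gene_names")
        if np.any(self.baseline_means <= 0):
            raise ValueError("all baseline means must be > 0")
        if self.dispersion.shape != (len(self.gene_names),):
            raise ValueError("dispersion must align with gene_names")
        if np.any(self.dispersion <= 0):
            raise ValueError("all dispersions must be > 0")
        genes = set(self.gene_names)
        tfs = set(self.tf_names)
        for ct, de in self.planted_de.items():
            if ct not in self.cell_types:
                raise ValueError(f"planted DE references unknown cell type {ct!r}")
            missing = set(de) - genes
            if missing:
                raise ValueError(f"planted DE references unknown genes {sorted(missing)}")
        if self.planted_active_tf and self.planted_active_tf.tf not in tfs:
            raise ValueError("planted active TF not in tf_names")
        if self.planted_module:
            if not set(self.planted_module.tfs) <= tfs:
                raise ValueError("planted module TFs not in tf_names")
            if not set(self.planted_module.genes) <= genes:
                raise ValueError("planted module genes not in gene_names")
        for rw in self.planted_rewired:
            if rw.target not in genes:
                raise ValueError(f"rewired target {rw.target!r} not in gene_names")
            if rw.mechanism not in tfs:
                raise ValueError(f"mechanism protein {rw.mechanism!r} not in tf_names")

    @property
    def case(self) -> str:
        return self.conditions[0]

    @property
    def control(self) -> str:
        return self.conditions[1]

    def to_json(self) -> str:
        d = asdict(self)
        d["baseline_means"] = self.baseline_means.tolist()
        d["dispersion"] = self.dispersion.tolist()
        return json.dumps(d, indent=1)


def default_truth(
    n_tfs: int = 12,
    n_genes: int = 80,
    cell_types: tuple[str, ...] = ("excitatory", "astrocyte", "microglia"),
    conditions: tuple[str, str] = ("mutant", "wt"),
    mean_log_loc: float = 1.0,
    mean_log_scale: float = 1.0,
    dispersion_value: float = 2.0,
    marker_fraction: float = 0.05,
    seed: int = 0,
) -> SyntheticTruth:
    """Baseline (unperturbed) truth with lognormal gene means and sparse
    cell-type marker programs. TF genes are the first ``n_tfs`` genes."""
    if n_tfs < 2:
        raise ValueError("n_tfs must be >= 2")
    if n_genes < n_tfs:
        raise ValueError("n_genes must be >= n_tfs")
    rng = np.random.default_rng(seed)
    tf_names = [f"TF{i:02d}" for i in range(1, n_tfs + 1)]
    gene_names = tf_names + [f"G{j:04d}" for j in range(1, n_genes - n_tfs + 1)]
    baseline = rng.lognormal(mean_log_loc, mean_log_scale, size=n_genes)
    dispersion = np.full(n_genes, float(dispersion_value))
    n_mark = max(1, int(round(marker_fraction * n_genes)))
    markers: dict[str, list[str]] = {}
    # markers drawn from the non-TF tail so regulatory structure stays clean
    pool = np.array(gene_names[n_tfs:] if n_genes > n_tfs else gene_names)
    for ct in cell_types:
        markers[ct] = list(rng.choice(pool, size=min(n_mark, len(pool)), replace=False))
    return SyntheticTruth(
        tf_names=tf_names,
        gene_names=gene_names,
        cell_types=list(cell_types),
        conditions=tuple(conditions),
        baseline_means=baseline,
        dispersion=dispersion,
        seed=int(seed),
        marker_genes=markers,
        focal_tf=tf_names[0],
    )


def generate_priors(
    n_tfs: int,
    n_genes: int,
    motif_density: float,
    ppi_density: float,
    seed: int,
    positive_mode_prob: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Motif, PPI, and signed-regulon priors for a synthetic TF/gene universe.

    Returns
    -------
    motif : DataFrame, TF x gene, entries in {0, 1}; every TF has >= 1 target
    ppi : DataFrame, TF x TF, symmetric, nonnegative, unit diagonal
    regulon : DataFrame with columns (tf, target, mode), modes in {-1, +1}
    """
    if n_tfs < 2:
        raise ValueError("n_tfs must be >= 2")
    if n_genes < n_tfs:
        raise ValueError("n_genes must be >= n_tfs")
    for name, d in (("motif_density", motif_density), ("ppi_density", ppi_density)):
        if not (0.0 < d < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {d}")
    rng = np.random.default_rng(seed)
    tf_names = [f"TF{i:02d}" for i in range(1, n_tfs + 1)]
    gene_names = tf_names + [f"G{j:04d}" for j in range(1, n_genes - n_tfs + 1)]

    motif = (rng.random((n_tfs, n_genes)) < motif_density).astype(float)
    for i in range(n_tfs):  # every TF regulates something
        if motif[i].sum() == 0:
            motif[i, rng.integers(n_genes)] = 1.0

    upper = np.triu((rng.random((n_tfs, n_tfs)) < ppi_density).astype(float), k=1)
    ppi = upper + upper.T + np.eye(n_tfs)

    tf_idx, gene_idx = np.nonzero(motif)
    modes = np.where(rng.random(tf_idx.size) < positive_mode_prob, 1, -1)
    regulon = pd.DataFrame(
        {
            "tf": [tf_names[i] for i in tf_idx],
            "target": [gene_names[j] for j in gene_idx],
            "mode": modes,
        }
    )
    motif_df = pd.DataFrame(motif, index=tf_names, columns=gene_names)
    ppi_df = pd.DataFrame(ppi, index=tf_names, columns=tf_names)
    return motif_df, ppi_df, regulon


ALL_COMPONENTS = frozenset({"de", "activity", "module", "rewiring"})


def plant_perturbation(
    truth: SyntheticTruth,
    de_lfc: float = 1.0,
    module_boost: float = 1.0,
    n_de_per_type: int = 10,
    activity_shift: float = 0.5,
    regulon: pd.DataFrame | None = None,
    components: frozenset[str] | set[str] = ALL_COMPONENTS,
) -> SyntheticTruth:
    """Plant recoverable perturbations into a baseline truth.

    Fills: ``planted_de`` (n_de_per_type genes per cell type, alternating
    sign, |log2FC| = |de_lfc|), one active TF (its regulon targets shifted by
    ``activity_shift`` log2-units times their mode in case cells of the
    affected cell types), one strengthened network module in the first cell
    type, and four rewired (target, mechanism) pairs covering all four
    regulation x cooperation categories. ``components`` restricts which
    perturbations are planted (e.g. ``{"de"}`` for a pure differential-
    expression study with no other effects in the data).
    """
    components = set(components)
    if not components <= ALL_COMPONENTS:
        raise ValueError(f"unknown components: {components - ALL_COMPONENTS}")
    if de_lfc == 0:
        raise ValueError("de_lfc must be nonzero")
    if module_boost <= 0:
        raise ValueError("module_boost must be > 0")
    if n_de_per_type > len(truth.gene_names):
        raise ValueError("n_de_per_type exceeds the gene universe")
    rng = np.random.default_rng(truth.seed + 1)
    n_tfs = len(truth.tf_names)
    non_tf_genes = [g for g in truth.gene_names[n_tfs:]]
    marker_union = set().union(*truth.marker_genes.values()) if truth.marker_genes else set()
    de_pool = [g for g in non_tf_genes if g not in marker_union]

    planted_de: dict[str, dict[str, float]] = {}
    used: set[str] = set()
    for ct in truth.cell_types if "de" in components else []:
        avail = [g for g in de_pool if g not in used]
        if len(avail) < n_de_per_type:
            raise ValueError("not enough free genes to plant DE in every cell type")
        chosen = list(rng.choice(avail, size=n_de_per_type, replace=False))
        used.update(chosen)
        planted_de[ct] = {
            g: (de_lfc if k % 2 == 0 else -de_lfc) for k, g in enumerate(chosen)
        }

    # active TF: the non-focal TF with the most regulon targets (robust
    # activity signal after the min-targets filter)
    focal = truth.focal_tf or truth.tf_names[0]
    if regulon is not None and len(regulon):
        counts = regulon[regulon["tf"] != focal].groupby("tf").size()
        active_tf = str(counts.idxmax())
    else:
        active_tf = next(t for t in truth.tf_names if t != focal)
    planted_active = None
    if "activity" in components:
        planted_active = PlantedActivity(
            tf=active_tf,
            cell_types=tuple(truth.cell_types[: max(1, len(truth.cell_types) - 1)]),
            direction=+1,
        )

    # network module: a TF-set x gene-block whose edges are strengthened in
    # case networks of one cell type (a single-TF edit would be cancelled by
    # the column-wise prior normalization when in-degrees are summed)
    planted_module = None
    module_tfs: tuple[str, ...] = ()
    module_genes: tuple[str, ...] = ()
    if "module" in components:
        module_pool = [g for g in de_pool if g not in used]
        n_module = min(8, len(module_pool))
        module_genes = tuple(rng.choice(module_pool, size=n_module, replace=False))
        used.update(module_genes)
        module_tfs = tuple(
            t for t in truth.tf_names if t not in {focal, active_tf}
        )[:3]
        planted_module = PlantedModule(
            tfs=module_tfs,
            genes=module_genes,
            cell_type=truth.cell_types[0],
            boost=module_boost,
        )

    # rewired pairs: targets are TF genes (proteins in the PPI layer), one per
    # category; two designated mechanism proteins, as in the paper's
    # DNA-damage / cell-cycle mechanism pair
    planted_rewired: list[PlantedRewiring] = []
    mechanism_support: dict[str, tuple[str, ...]] = {}
    focal_signature: tuple[str, ...] = ()
    if "rewiring" in components:
        excluded = {focal, active_tf} | set(module_tfs)
        candidates = [t for t in truth.tf_names if t not in excluded]
        if len(candidates) < 6:
            raise ValueError("need at least 11 TFs to plant all rewiring categories")
        mechanisms = candidates[:2]
        targets = candidates[2:6]
        support_pool = [g for g in de_pool if g not in used]
        block = min(4, (len(support_pool) - 8) // 4)
        if block < 2:
            raise ValueError("not enough free genes to plant rewiring support blocks")
        for k, cat in enumerate(REWIRING_CATEGORIES):
            sup = tuple(support_pool[k * block : (k + 1) * block])
            used.update(sup)
            planted_rewired.append(
                PlantedRewiring(
                    target=targets[k],
                    mechanism=mechanisms[k % 2],
                    category=cat,
                    support_genes=sup,
                )
            )
        # always-on private programs: genes only the mechanism regulates, so
        # a non-cooperating pair has actively dissimilar regulatory profiles
        # (and each mechanism TF stays non-degenerate when it cooperates
        # with nobody)
        filler = support_pool[4 * block :]
        mechanism_support = {
            mechanisms[0]: tuple(filler[:4]),
            mechanisms[1]: tuple(filler[4:8]),
        }
        used.update(filler[:8])
        # focal-TF expression program: baseline regulon targets of the focal
        # TF; a rewired target gene is co-expressed with it exactly when
        # regulated
        if regulon is not None and len(regulon):
            # genes already carrying a correlation factor are off limits;
            # planted DE genes are fine (a mean shift is orthogonal to
            # coexpression)
            factor_genes = set(module_genes) | set(filler[:8])
            for rw in planted_rewired:
                factor_genes.update(rw.support_genes)
            sig_pool = [
                t
                for t in regulon.loc[regulon["tf"] == focal, "target"]
                if t in set(de_pool) and t not in factor_genes
            ]
            focal_signature = tuple(sig_pool[:6])

    return SyntheticTruth(
        tf_names=truth.tf_names,
        gene_names=truth.gene_names,
        cell_types=truth.cell_types,
        conditions=truth.conditions,
        baseline_means=truth.baseline_means.copy(),
        dispersion=truth.dispersion.copy(),
        seed=truth.seed,
        marker_genes=truth.marker_genes,
        planted_de=planted_de,
        planted_active_tf=planted_active,
        planted_module=planted_module,
        planted_rewired=planted_rewired,
        mechanism_support=mechanism_support,
        focal_signature=focal_signature,
        focal_tf=focal,
    )


# -- per-condition realization of the planted rewiring -----------------------
#
# Category-to-edit mapping (the regulation axis is the focal-TF -> target
# motif edge; the cooperation axis is the target <-> mechanism PPI edge;
# "presence" downstream means a positive inferred edge weight, which the
# normalized priors deliver for 1-entries and deny for 0-entries):
#
#   cooperation_gained                   reg 1/1   coop ctrl 0 -> case 1
#   cooperation_lost                     reg 1/1   coop ctrl 1 -> case 0
#   regulation_change_cooperation_gained reg 0->1  coop ctrl 0 -> case 1
#   regulation_change_cooperation_lost   reg 0->1  coop ctrl 1 -> case 0


def rewiring_state(rw: PlantedRewiring, is_case: bool) -> tuple[bool, bool]:
    """(regulation present, cooperation present) for one condition."""
    reg_changes = rw.category.startswith("regulation_change")
    coop_gained = rw.category.endswith("gained")
    reg_present = True if not reg_changes else is_case
    coop_present = is_case if coop_gained else (not is_case)
    return reg_present, coop_present


def condition_priors(
    truth: SyntheticTruth,
    motif: pd.DataFrame,
    ppi: pd.DataFrame,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-condition (motif, ppi) priors realizing the planted module and the
    planted rewiring edits on top of the shared baseline priors."""
    out = {}
    for cond in truth.conditions:
        m = motif.copy()
        p = ppi.copy()
        is_case = cond == truth.case
        if truth.planted_module is not None:
            mod = truth.planted_module
            for t in mod.tfs:
                for g in mod.genes:
                    m.loc[t, g] = 1.0 + (mod.boost if is_case else 0.0)
        focal = truth.focal_tf
        # rewiring rows are fully specified by the planted design: the
        # converged cooperativity layer reflects regulatory-profile
        # similarity, so random baseline overlap would drown the signal
        involved = {rw.target for rw in truth.planted_rewired} | {
            rw.mechanism for rw in truth.planted_rewired
        }
        for node in involved:
            m.loc[node, :] = 0.0
        for mech, fillers in truth.mechanism_support.items():
            for g in fillers:
                m.loc[mech, g] = 1.0
        for rw in truth.planted_rewired:
            reg_present, coop_present = rewiring_state(rw, is_case)
            m.loc[focal, rw.target] = 1.0 if reg_present else 0.0
            w = 1.0 if coop_present else 0.0
            p.loc[rw.target, rw.mechanism] = w
            p.loc[rw.mechanism, rw.target] = w
            # the pair shares the support targets only when it cooperates
            for g in rw.support_genes:
                m.loc[rw.target, g] = 1.0
                if coop_present:
                    m.loc[rw.mechanism, g] = 1.0
        out[cond] = (m, p)
    return out


def _condition_multipliers(truth: SyntheticTruth, regulon: pd.DataFrame | None) -> dict[str, np.ndarray]:
    """Per-cell-type case-condition mean multipliers (control is all ones)."""
    gene_index = {g: j for j, g in enumerate(truth.gene_names)}
    mult = {ct: np.ones(len(truth.gene_names)) for ct in truth.cell_types}
    for ct, de in truth.planted_de.items():
        for g, lfc in de.items():
            mult[ct][gene_index[g]] *= 2.0 ** lfc
    pa = truth.planted_active_tf
    if pa is not None and regulon is not None:
        sub = regulon[regulon["tf"] == pa.tf]
        for _, row in sub.iterrows():
            j = gene_index.get(row["target"])
            if j is None:
                continue
            shift = 0.5 * pa.direction * float(row["mode"])
            for ct in pa.cell_types:
                mult[ct][j] *= 2.0 ** shift
    return mult


def simulate_counts(
    truth: SyntheticTruth,
    cells_per_type_per_condition: int = 150,
    depth: float = 2000.0,
    seed: int = 0,
    regulon: pd.DataFrame | None = None,
    n_replicates: int = 3,
    replicate_sigma: float = 0.1,
    libsize_sigma: float = 0.3,
    module_sigma: float = 0.6,
    marker_multiplier: float = 5.0,
) -> ad.AnnData:
    """Draw NB counts for every (cell type, condition) block.

    Mean model per cell: baseline x marker program x condition multiplier x
    replicate jitter x shared module factor (case cells of the module cell
    type only), rescaled so the expected cell total equals ``depth`` times a
    lognormal library-size factor. Dispersion is the per-gene NB size.
    """
    if cells_per_type_per_condition < 2:
        raise ValueError("cells_per_type_per_condition must be >= 2")
    rng = np.random.default_rng(seed)
    genes = truth.gene_names
    n_genes = len(genes)
    gene_index = {g: j for j, g in enumerate(genes)}
    mult = _condition_multipliers(truth, regulon)

    # replicate jitter: per (condition, replicate, gene), mimics 3 animals
    jitter = {
        (cond, r): rng.lognormal(0.0, replicate_sigma, size=n_genes)
        for cond in truth.conditions
        for r in range(n_replicates)
    }

    blocks, obs_rows = [], []
    for ct in truth.cell_types:
        marker = np.ones(n_genes)
        for g in truth.marker_genes.get(ct, []):
            marker[gene_index[g]] = marker_multiplier
        module_idx = None
        if (
            truth.planted_module is not None
            and truth.planted_module.cell_type == ct
        ):
            module_idx = [gene_index[g] for g in truth.planted_module.genes]
            module_idx += [gene_index[t] for t in truth.planted_module.tfs]
        for cond in truth.conditions:
            base = truth.baseline_means * marker
            if cond == truth.case:
                base = base * mult[ct]
            reps = np.array(
                [r % n_replicates for r in range(cells_per_type_per_condition)]
            )
            mean_mat = np.empty((cells_per_type_per_condition, n_genes))
            for r in range(n_replicates):
                rows = reps == r
                mean_mat[rows] = base * jitter[(cond, r)]
            if module_idx is not None and cond == truth.case:
                factor = rng.lognormal(0.0, module_sigma, size=cells_per_type_per_condition)
                mean_mat[:, module_idx] *= factor[:, None]
            # rewired pairs: the target's support program and the mechanism's
            # private program are co-activated when the pair cooperates and
            # anti-regulated when it does not, so the coexpression evidence
            # carries the cooperation state into the inferred networks
            is_case = cond == truth.case
            z_focal = rng.normal(0.0, module_sigma, size=cells_per_type_per_condition)
            sig_idx = [gene_index[g] for g in truth.focal_signature]
            if sig_idx:
                mean_mat[:, sig_idx] *= np.exp(z_focal)[:, None]
            for rw in truth.planted_rewired:
                reg_present, coop_present = rewiring_state(rw, is_case)
                z = rng.normal(0.0, module_sigma, size=cells_per_type_per_condition)
                sup_idx = [gene_index[g] for g in rw.support_genes]
                mech_idx = [
                    gene_index[g]
                    for g in truth.mechanism_support.get(rw.mechanism, ())
                ]
                if sup_idx:
                    mean_mat[:, sup_idx] *= np.exp(z)[:, None]
                if mech_idx:
                    sign = 1.0 if coop_present else -1.0
                    mean_mat[:, mech_idx] *= np.exp(sign * z)[:, None]
                # the target gene rides the focal TF's program only while
                # the focal TF actually regulates it
                if sig_idx:
                    sign = 1.0 if reg_present else -1.0
                    mean_mat[:, gene_index[rw.target]] *= np.exp(sign * z_focal)
            lib = depth * rng.lognormal(0.0, libsize_sigma, size=cells_per_type_per_condition)
            mean_mat *= (lib / mean_mat.sum(axis=1))[:, None]
            r_disp = truth.dispersion[None, :]
            p = r_disp / (r_disp + mean_mat)
            counts = rng.negative_binomial(r_disp, p)
            blocks.append(counts)
            for k in range(cells_per_type_per_condition):
                obs_rows.append(
                    {
                        "cell_type": ct,
                        "condition": cond,
                        "sample_id": f"{cond}_rep{reps[k] + 1}",
                    }
                )
    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{k:06d}" for k in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["conditions"] = list(truth.conditions)
    return adata


def write_synthetic_bundle(
    outdir: str | Path,
    truth: SyntheticTruth,
    adata: ad.AnnData,
    motif: pd.DataFrame,
    ppi: pd.DataFrame,
    regulon: pd.DataFrame,
) -> dict[str, Path]:
    """Serialize the synthetic study: MTX + barcodes/features/metadata TSVs,
    3-column prior edge lists, and the ground truth as JSON."""
    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = gio.write_matrix(outdir, adata)
    paths["motif"] = gio.write_edges(outdir / "motif_prior.tsv", _frame_to_edges(motif))
    paths["ppi"] = gio.write_edges(outdir / "ppi_prior.tsv", _frame_to_edges(ppi))
    reg = regulon.rename(columns={"tf": "source", "target": "target", "mode": "weight"})
    paths["regulon"] = gio.write_edges(outdir / "regulon.tsv", reg)
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    return paths


def _frame_to_edges(mat: pd.DataFrame) -> pd.DataFrame:
    src, tgt = np.nonzero(mat.values)
    return pd.DataFrame(
        {
            "source": mat.index.values[src],
            "target": mat.columns.values[tgt],
            "weight": mat.values[src, tgt],
        }
    )
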