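"""Synthetic interactomes, expression cohorts, and survival tables.

The generator emulates the structure of a pan-cancer study cohort so that
every pipeline stage is testable without external downloads: a random
signed interactome (gene products, metabolites, process nodes with ≥ 2
participants each), multi-cancer-type cohorts of tumor samples with matched
normals, log-normal per-gene expression with Poisson sampling noise and
per-sample sequencing-depth factors, and right-censored survival times
whose hazard depends on chosen analytes.

Effects are *planted* and therefore recoverable ground truth:

* a gene-level plant shifts one gene's tumor log-mean by a stated effect
  (log10 units) in a stated contrast (one cancer type vs rest, or tumor vs
  normal);
* a pathway-level plant shifts every nonzero-ARR member of a pathway
  coherently, with the sign of each member's shift matching its
  activator/repressor role — so the pathway's activation level moves in a
  known direction while each individual member moves only weakly;
* a survival plant ties the event hazard to an analyte's standardized
  level via a stated log hazard ratio.

All three generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .expression import ClinicalTable, ExpressionMatrix, MODE_PROTEOMIC, MODE_RNA
from .interactome import Interaction, Interactome, NodeKind
from .pathways import Pathway

__all__ = ["PlantedMarker", "PlantedHazard", "SyntheticConfig", "generate_interactome",
           "generate_cohort", "generate_survival", "generate_proteomic_cohort"]

CONTRAST_TYPE = "cancer_type_one_vs_rest"
CONTRAST_TUMOR = "tumor_vs_normal"


@dataclass(frozen=True)
class PlantedMarker:
    """A planted differential effect: gene or pathway, contrast, log10 effect."""

    target: str                      # gene id, or pathway id for coherent plants
    contrast: str = CONTRAST_TYPE    # which comparison carries the effect
    cancer_type: str | None = None   # required for the one-vs-rest contrast
    effect: float = 1.0              # shift of the tumor log10-mean
    kind: str = "gene"               # "gene" | "pathway"


@dataclass(frozen=True)
class PlantedHazard:
    """A survival plant: per-1-SD log hazard ratio on an analyte's level.

    ``endpoint`` names the survival process the analyte drives ("os" or
    "pfs"); overall and progression-free survival are distinct clinical
    processes, so a prognostic analyte is planted into one of them.
    """

    analyte: str
    log_hr: float
    endpoint: str = "os"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohorts.

    Defaults describe a three-cancer-type study with per-type sample counts
    in the range of a large public pan-cancer cohort (about 130 tumors and
    about 33 site-matched normals per type, roughly a 4:1 tumor:normal
    ratio), moderate biological noise, and 30% independent censoring —
    enough samples per stratum for rank statistics and Cox fits to be well
    conditioned.
    """

    seed: int = 0
    # interactome shape
    n_genes: int = 60
    n_metabolites: int = 15
    n_processes: int = 10
    edge_density: float = 3.0        # mean out-degree per node
    interaction_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # activation/inhibition/other
    # cohort shape
    n_cancer_types: int = 3
    tumors_per_type: int = 134
    normals_per_type: int = 33
    base_log_mean: float = math.log(500.0)   # natural-log scale of baseline counts
    gene_sd: float = 1.0                     # spread of per-gene baseline means
    biological_sd: float = 0.35              # per-sample log-normal noise
    depth_sd: float = 0.15                   # per-sample library-size log-sd
    planted_markers: tuple[PlantedMarker, ...] = ()
    # survival
    baseline_hazard: float = 1.0 / 500.0     # events per day
    censoring_rate: float = 0.3
    planted_hazards: tuple[PlantedHazard, ...] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.interaction_mix) - 1.0) > 1e-12:
            raise ConfigError("interaction_mix must sum to 1")
        if min(self.interaction_mix) < 0:
            raise ConfigError("interaction_mix probabilities must be non-negative")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigError("censoring_rate must be in [0, 1)")
        for name in ("n_genes", "n_metabolites", "n_processes",
                     "n_cancer_types", "tumors_per_type", "normals_per_type"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def cancer_type_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_cancer_types)]

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["planted_markers"] = [asdict(m) for m in self.planted_markers]
        payload["planted_hazards"] = [asdict(h) for h in self.planted_hazards]
        payload["interaction_mix"] = list(self.interaction_mix)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        payload["planted_markers"] = tuple(
            PlantedMarker(**m) for m in payload.get("planted_markers", [])
        )
        payload["planted_hazards"] = tuple(
            PlantedHazard(**h) for h in payload.get("planted_hazards", [])
        )
        payload["interaction_mix"] = tuple(payload["interaction_mix"])
        return cls(**payload)


def _gene_ids(config: SyntheticConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, config.n_genes + 1)]


def generate_interactome(config: SyntheticConfig) -> Interactome:
    """Random signed interactome with the configured node-kind counts.

    Out-degrees are Poisson with mean ``edge_density``; edge labels are
    drawn from ``interaction_mix``; every process node is guaranteed at
    least two participants (adjacent non-process nodes).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config)
    metabolites = [f"M{i:04d}" for i in range(1, config.n_metabolites + 1)]
    processes = [f"P{i:04d}" for i in range(1, config.n_processes + 1)]
    substrates = genes + metabolites
    if config.n_processes > 0 and len(substrates) < 2:
        raise ConfigError("process nodes need at least 2 non-process nodes as participants")

    graph = Interactome()
    for g in genes:
        graph.add_node(g, NodeKind.GENE_PRODUCT)
    for m in metabolites:
        graph.add_node(m, NodeKind.METABOLITE)
    for p in processes:
        graph.add_node(p, NodeKind.PROCESS)

    labels = [Interaction.ACTIVATION, Interaction.INHIBITION, Interaction.OTHER]
    all_nodes = substrates + processes
    for source in all_nodes:
        k = rng.poisson(config.edge_density)
        if k == 0:
            continue
        targets = rng.choice(len(all_nodes), size=min(k, len(all_nodes) - 1), replace=False)
        for ti in targets:
            target = all_nodes[ti]
            if target == source:
                continue
            label = labels[rng.choice(3, p=config.interaction_mix)]
            graph.add_edge(source, target, label)
    # every process gets >= 2 participants
    for p in processes:
        participants = {
            n for n in graph.direct_neighbors(p, "both")
            if graph.node_kind(n) is not NodeKind.PROCESS
        }
        while len(participants) < 2:
            cand = substrates[rng.choice(len(substrates))]
            if cand in participants:
                continue
            label = labels[rng.choice(3, p=config.interaction_mix)]
            graph.add_edge(p, cand, label)
            participants.add(cand)
    return graph


def _sample_frame(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for ct in config.cancer_type_names():
        for i in range(1, config.tumors_per_type + 1):
            rows.append((f"{ct}_T{i:03d}", ct, "tumor"))
        for i in range(1, config.normals_per_type + 1):
            rows.append((f"{ct}_N{i:03d}", ct, "normal"))
    frame = pd.DataFrame(rows, columns=["sample_id", "cancer_type", "tissue"])
    return frame.set_index("sample_id")


def _effect_matrix(
    config: SyntheticConfig,
    genes: list[str],
    meta: pd.DataFrame,
    pathways: Sequence[Pathway],
) -> np.ndarray:
    """Per-(gene, sample) shift of the natural-log mean implied by the plants."""
    pw_by_id = {pw.id: pw for pw in pathways}
    gene_pos = {g: i for i, g in enumerate(genes)}
    shift = np.zeros((len(genes), len(meta)))
    ln10 = math.log(10.0)
    for plant in config.planted_markers:
        if plant.contrast == CONTRAST_TYPE:
            if plant.cancer_type is None:
                raise ConfigError(f"plant {plant.target}: one-vs-rest contrast needs a cancer_type")
            if plant.cancer_type not in set(meta["cancer_type"]):
                raise ConfigError(f"plant {plant.target}: unknown cancer type {plant.cancer_type}")
            cols = ((meta["cancer_type"] == plant.cancer_type) & (meta["tissue"] == "tumor")).to_numpy()
        elif plant.contrast == CONTRAST_TUMOR:
            cols = (meta["tissue"] == "tumor").to_numpy()
            if plant.cancer_type is not None:
                cols &= (meta["cancer_type"] == plant.cancer_type).to_numpy()
        else:
            raise ConfigError(f"plant {plant.target}: unknown contrast {plant.contrast!r}")
        if plant.kind == "gene":
            if plant.target not in gene_pos:
                raise ConfigError(f"planted gene {plant.target!r} not in the gene universe")
            shift[gene_pos[plant.target], cols] += plant.effect * ln10
        elif plant.kind == "pathway":
            pw = pw_by_id.get(plant.target)
            if pw is None:
                raise ConfigError(f"planted pathway {plant.target!r} not in the supplied pathway set")
            if pw.arr is None:
                raise ConfigError(f"planted pathway {plant.target!r} must be ARR-annotated")
            hit = [m for m in pw.members if m in gene_pos and pw.arr[m] != 0.0]
            if not hit:
                raise ConfigError(f"planted pathway {plant.target!r} has no nonzero-ARR gene member")
            for m in hit:
                shift[gene_pos[m], cols] += plant.effect * ln10 * math.copysign(1.0, pw.arr[m])
        else:
            raise ConfigError(f"plant {plant.target}: unknown kind {plant.kind!r}")
    return shift


def generate_cohort(
    config: SyntheticConfig,
    graph: Interactome,
    pathways: Sequence[Pathway] = (),
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Raw-count expression cohort with matched normals and planted effects.

    Counts are Poisson draws around a log-normal mean: per-gene baseline,
    per-sample biological noise, per-sample depth factor, plus any planted
    shifts.  ``pathways`` must contain every pathway referenced by a
    pathway-level plant (annotated, so shifts can follow member ARR signs).
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(set(_gene_ids(config)) | set(graph.nodes(NodeKind.GENE_PRODUCT)))
    meta = _sample_frame(config)
    n_g, n_s = len(genes), len(meta)

    base = config.base_log_mean + config.gene_sd * rng.standard_normal(n_g)
    noise = config.biological_sd * rng.standard_normal((n_g, n_s))
    depth = config.depth_sd * rng.standard_normal(n_s)
    shift = _effect_matrix(config, genes, meta, pathways)
    lam = np.exp(base[:, None] + noise + depth[None, :] + shift)
    counts = rng.poisson(lam).astype(float)

    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=meta.index)
    clinical = ClinicalTable(
        meta.assign(os_time=np.nan, os_event=np.nan, pfs_time=np.nan, pfs_event=np.nan)
    )
    return ExpressionMatrix(values, MODE_RNA), clinical


def generate_proteomic_cohort(
    config: SyntheticConfig,
    graph: Interactome,
    pathways: Sequence[Pathway] = (),
    missing_rate: float = 0.0,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Gene-level log2-ratio cohort emulating label-based proteomic output.

    Values are log2 ratios to a common reference channel: per-sample noise
    plus planted shifts (converted to log2), with optional missingness.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = sorted(set(_gene_ids(config)) | set(graph.nodes(NodeKind.GENE_PRODUCT)))
    meta = _sample_frame(config)
    n_g, n_s = len(genes), len(meta)
    ln2 = math.log(2.0)
    noise = config.biological_sd * rng.standard_normal((n_g, n_s)) / ln2
    shift = _effect_matrix(config, genes, meta, pathways) / ln2
    values = noise + shift
    if missing_rate > 0:
        mask = rng.random((n_g, n_s)) < missing_rate
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=meta.index)
    clinical = ClinicalTable(
        meta.assign(os_time=np.nan, os_event=np.nan, pfs_time=np.nan, pfs_event=np.nan)
    )
    return ExpressionMatrix(frame, MODE_PROTEOMIC), clinical


def generate_survival(
    config: SyntheticConfig,
    analyte_matrix: pd.DataFrame,
    clinical: ClinicalTable,
    endpoints: tuple[str, ...] = ("os", "pfs"),
    log_scale_levels: bool = True,
) -> ClinicalTable:
    """Fill survival endpoints with proportional-hazards event times.

    Each tumor subject's event time is exponential with
    ``log hazard = log(baseline) + Σ log_hr × standardized analyte level``;
    a fraction ``censoring_rate`` of subjects is censored at a uniform
    point before their event time.  Normal-tissue samples keep missing
    endpoints.  OS and PFS draws are independent given the analyte levels.

    Expression influences hazard multiplicatively, so for count-scale
    matrices the standardized level is computed on the log(1 + x) scale
    (``log_scale_levels=True``); pass ``False`` for matrices already on a
    log or signed scale (proteomic ratios, activation levels).
    """
    rng = np.random.default_rng(config.seed + 3)
    for plant in config.planted_hazards:
        if plant.analyte not in analyte_matrix.index:
            raise ConfigError(f"planted hazard analyte {plant.analyte!r} not in matrix")
    subjects = [s for s in analyte_matrix.columns if s in clinical.samples
                and clinical.data.loc[s, "tissue"] == "tumor"]

    data = clinical.data.copy()
    for endpoint in endpoints:
        log_hazard = np.full(len(subjects), math.log(config.baseline_hazard))
        for plant in config.planted_hazards:
            if plant.endpoint != endpoint:
                continue
            level = analyte_matrix.loc[plant.analyte, subjects].to_numpy(dtype=float)
            if log_scale_levels:
                level = np.log1p(level)
            sd = level.std()
            z = (level - level.mean()) / sd if sd > 0 else np.zeros_like(level)
            log_hazard = log_hazard + plant.log_hr * z
        rates = np.exp(log_hazard)
        c_max = _uniform_censoring_horizon(rates, config.censoring_rate)
        t_event = rng.exponential(1.0 / rates)
        if c_max is None:  # censoring rate 0: follow everyone to the event
            t_obs, event = t_event, np.ones(len(subjects))
        else:
            t_cens = rng.uniform(0.0, c_max, len(subjects))
            event = (t_event <= t_cens).astype(float)
            t_obs = np.minimum(t_event, t_cens)
        data.loc[subjects, f"{endpoint}_time"] = t_obs
        data.loc[subjects, f"{endpoint}_event"] = event
    return ClinicalTable(data)


def _uniform_censoring_horizon(rates: np.ndarray, censoring_rate: float) -> float | None:
    """Horizon c such that C ~ U(0, c), independent of T, censors the requested
    fraction: solves mean_i P(C < T_i) = rate, with P(C < T) = (1-e^{-lam c})/(lam c)."""
    if censoring_rate <= 0.0:
        return None
    from scipy.optimize import brentq

    def censored_fraction(c: float) -> float:
        x = rates * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0 / rates.min()
    while censored_fraction(hi) > censoring_rate:
        hi *= 2.0
    return float(brentq(lambda c: censored_fraction(c) - censoring_rate, lo, hi, xtol=1e-10))
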