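"""End-to-end orchestration: data → pathways → ARR → PAL → screens → report.

The full screen runs, for each cancer type and each analyte category (gene
expression, classical pathway PAL, gene-centric pathway PAL):

* a cancer-type-specific screen (one type vs the rest of the pooled tumors),
* a tumor-vs-normal screen where matched normals exist,
* overall-survival and progression-free-survival screens where endpoints
  exist,

and writes per-contrast detail tables plus a summary of significant-analyte
counts and percentage shares per stratum.  Case-to-normal ratios for
pathway scoring always use the normal samples of the same cancer type as
the control group; cancer types without normals are skipped for pathway
analytes (logged, not fatal).  The pipeline contains no randomness: rerun
with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import arr as arr_mod
from .errors import PalscreenError, StratumError
from .expression import (
    ClinicalTable,
    ExpressionMatrix,
    MODE_PROTEOMIC,
    case_to_normal_ratios,
    median_of_ratios_normalize,
    proteomic_ratios_to_cnr,
    read_expression_table,
)
from .interactome import parse_interactome_table
from .pal import compute_pal_matrix, write_pal_table
from .pathways import (
    build_all_gene_centric,
    filter_uninformative,
    read_classical_pathways,
    write_pathways_table,
)
from .screen import AUC_THRESHOLD, Q_THRESHOLD, screen_cancer_types, screen_tumor_vs_normal
from .survival import screen_survival

__all__ = ["RunConfig", "run_full_screen", "run_study", "summarize"]

logger = logging.getLogger("palscreen")

CATEGORY_GENE = "gene"
CATEGORY_CLASSICAL = "classical_pathway"
CATEGORY_GENE_CENTRIC = "gene_centric_pathway"


@dataclass
class RunConfig:
    """Resolved configuration of one full screening run."""

    interactome: str
    expression: str
    clinical: str
    out_dir: str
    classical_gmt: str | None = None
    classical_arr: str | None = None
    mode: str = "rna"                    # "rna" | "proteomic"
    direction: str = "both"
    radius: int = 1
    log_base: float = 10.0
    pseudocount: float = 1.0
    proteomic_log_base: float = 2.0
    paired: bool = False
    auc_threshold: float = AUC_THRESHOLD
    q_threshold: float = Q_THRESHOLD
    adjust_on: str = "logrank"
    seed: int = 0


@dataclass
class StudyResult:
    """In-memory result bundle of one full screen."""

    pathways: list = field(default_factory=list)
    excluded_pathways: list = field(default_factory=list)
    pal_gene_centric: pd.DataFrame | None = None
    pal_classical: pd.DataFrame | None = None
    gene_matrix: pd.DataFrame | None = None
    screens: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)


def _per_type_cnr(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    mode: str,
    pseudocount: float,
    proteomic_log_base: float,
    notes: list[str],
) -> pd.DataFrame | None:
    """Case-to-normal ratios for every sample, controls = same-type normals.

    Normal samples are ratioed against their own control group so that
    pathway activation is defined for them too (needed by the
    tumor-vs-normal contrast).  Returns genes × samples, or None when no
    cancer type has normals.
    """
    blocks = []
    for ct in clinical.cancer_types():
        normals = [s for s in clinical.normal_samples(ct) if s in expr.samples]
        type_samples = [
            s for s in expr.samples
            if s in clinical.samples and clinical.data.loc[s, "cancer_type"] == ct
        ]
        if not normals:
            notes.append(f"skip pathway scoring for {ct}: no normal samples (no CNR reference)")
            continue
        if mode == "proteomic":
            cnr, dropped = proteomic_ratios_to_cnr(
                expr.subset_samples(type_samples), normals, log_base=proteomic_log_base
            )
            if dropped:
                notes.append(f"{ct}: {len(dropped)} genes dropped (insufficient normal coverage)")
            blocks.append(cnr.values)
        else:
            sub = expr.subset_samples(type_samples)
            controls = expr.subset_samples(normals)
            cnr = case_to_normal_ratios(sub, controls, pseudocount=pseudocount)
            blocks.append(cnr.values)
    if not blocks:
        return None
    return pd.concat(blocks, axis=1)


def run_study(
    graph,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    classical_pathways=(),
    config: RunConfig | None = None,
) -> StudyResult:
    """Run the full screen on in-memory inputs; see :func:`run_full_screen`."""
    cfg = config or RunConfig("", "", "", "")
    result = StudyResult()
    notes = result.log

    # 1. pathways
    gene_centric = arr_mod.annotate_all(
        build_all_gene_centric(graph, direction=cfg.direction, radius=cfg.radius), graph
    )
    if cfg.mode == "rna":
        expr_norm, size_factors = median_of_ratios_normalize(expr)
        notes.append(f"size factors: {len(size_factors)} samples normalized")
    else:
        expr_norm = expr
    assay_universe = set(expr.genes)
    gene_centric, excluded = filter_uninformative(gene_centric, assay_universe)
    classical, excluded_classical = (
        filter_uninformative(list(classical_pathways), assay_universe)
        if classical_pathways
        else ([], [])
    )
    result.pathways = gene_centric + classical
    result.excluded_pathways = excluded + excluded_classical
    for pw, reason in result.excluded_pathways:
        notes.append(f"excluded pathway {pw.id}: {reason}")

    # 2. per-type CNR and PAL
    cnr = _per_type_cnr(expr_norm, clinical, cfg.mode, cfg.pseudocount,
                        cfg.proteomic_log_base, notes)
    pal_gc = pal_cl = None
    if cnr is not None:
        from .expression import CNRMatrix

        cnr_m = CNRMatrix(cnr)
        pal = compute_pal_matrix(cnr_m, gene_centric, log_base=cfg.log_base,
                                 pathway_set_id="gene_centric")
        pal_gc = pal.values
        for pid, reason in pal.excluded:
            notes.append(f"PAL undefined for {pid}: {reason}")
        if classical:
            palc = compute_pal_matrix(cnr_m, classical, log_base=cfg.log_base,
                                      pathway_set_id="classical")
            pal_cl = palc.values
            for pid, reason in palc.excluded:
                notes.append(f"PAL undefined for {pid}: {reason}")
    result.pal_gene_centric = pal_gc
    result.pal_classical = pal_cl
    result.gene_matrix = expr_norm.values

    # 3. screens per category
    categories: list[tuple[str, pd.DataFrame | None]] = [
        (CATEGORY_GENE, expr_norm.values),
        (CATEGORY_CLASSICAL, pal_cl),
        (CATEGORY_GENE_CENTRIC, pal_gc),
    ]
    type_frames, tumor_frames, os_frames, pfs_frames = [], [], [], []
    has_normals = len(clinical.normal_samples()) > 0
    if not has_normals:
        notes.append("skip tumor-vs-normal screen: cohort has no normal samples")
    for category, matrix in categories:
        if matrix is None or matrix.shape[0] == 0:
            notes.append(f"skip category {category}: no analytes")
            continue
        try:
            type_frames.append(
                screen_cancer_types(matrix, clinical, category,
                                    auc_threshold=cfg.auc_threshold,
                                    q_threshold=cfg.q_threshold, paired=cfg.paired)
            )
        except StratumError as exc:
            notes.append(f"skip cancer-type screen for {category}: {exc}")
        if has_normals:
            for ct in clinical.cancer_types():
                try:
                    tumor_frames.append(
                        screen_tumor_vs_normal(matrix, clinical, category, cancer_types=[ct],
                                               auc_threshold=cfg.auc_threshold,
                                               q_threshold=cfg.q_threshold, paired=cfg.paired)
                    )
                except StratumError as exc:
                    notes.append(f"skip tumor-vs-normal for {category}/{ct}: {exc}")
        for endpoint, frames in (("os", os_frames), ("pfs", pfs_frames)):
            tcol = f"{endpoint}_time"
            if clinical.data[tcol].notna().sum() == 0:
                continue
            for ct in clinical.cancer_types():
                tumor_cols = [s for s in matrix.columns if s in set(clinical.tumor_samples(ct))]
                if len(tumor_cols) < 4:
                    continue
                try:
                    frames.append(
                        screen_survival(matrix[tumor_cols], clinical, endpoint=endpoint,
                                        category=category, cancer_type=ct,
                                        q_threshold=cfg.q_threshold, adjust_on=cfg.adjust_on)
                    )
                except (StratumError, PalscreenError) as exc:
                    notes.append(f"skip survival {endpoint} for {category}/{ct}: {exc}")

    def _concat(frames):
        frames = [f for f in frames if f is not None and len(f)]
        return pd.concat(frames, ignore_index=True) if frames else None

    result.screens = {
        k: v
        for k, v in {
            "cancer_type": _concat(type_frames),
            "tumor_vs_normal": _concat(tumor_frames),
            "survival_os": _concat(os_frames),
            "survival_pfs": _concat(pfs_frames),
        }.items()
        if v is not None
    }
    result.summary = summarize(result.screens)
    return result


def summarize(screens: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts and percentage shares of significant analytes per stratum.

    Mirrors the shape of a per-cancer-type biomarker count table: one row
    per (screen, cancer type, category) with ``n_tested``, ``n_significant``
    and ``percent`` = 100 · n_significant / n_tested.
    """
    rows = []
    for screen_name, frame in screens.items():
        if frame is None or not len(frame):
            continue
        tested = frame if "status" not in frame.columns else frame[frame["status"] == "ok"]
        for (ct, cat), grp in tested.groupby(["cancer_type", "category"], sort=True):
            n = len(grp)
            k = int(grp["significant"].sum())
            rows.append(
                {
                    "screen": screen_name,
                    "cancer_type": ct,
                    "category": cat,
                    "n_tested": n,
                    "n_significant": k,
                    "percent": 100.0 * k / n if n else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["screen", "cancer_type", "category", "n_tested", "n_significant", "percent"]
    )


def run_full_screen(config: RunConfig) -> StudyResult:
    """File-based entry point: read inputs, run the study, write the report bundle.

    Writes into ``config.out_dir``: the gene-centric pathway table, PAL
    matrices, one detail TSV per screen, ``summary.tsv`` and ``run_log.txt``
    (every resolved config value and every skip/exclusion with its reason).
    Missing input files are reported all at once as a startup error.
    """
    problems = [
        f"missing input file: {p}"
        for p in (config.interactome, config.expression, config.clinical,
                  config.classical_gmt, config.classical_arr)
        if p and not Path(p).exists()
    ]
    if problems:
        raise FileNotFoundError("; ".join(problems))

    graph = parse_interactome_table(config.interactome)
    mode = MODE_PROTEOMIC if config.mode == "proteomic" else "rna_counts"
    expr = read_expression_table(config.expression, mode=mode)
    clinical = ClinicalTable.from_tsv(config.clinical)
    classical = (
        read_classical_pathways(config.classical_gmt, config.classical_arr)
        if config.classical_gmt and config.classical_arr
        else ()
    )

    result = run_study(graph, expr, clinical, classical_pathways=classical, config=config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pathways_table(result.pathways, out / "pathways.tsv")
    if result.pal_gene_centric is not None:
        from .pal import PALMatrix

        write_pal_table(
            PALMatrix(result.pal_gene_centric, log_base=config.log_base,
                      pathway_set_id="gene_centric", cnr_source_id=config.expression),
            out / "pal_gene_centric.tsv",
        )
    if result.pal_classical is not None:
        from .pal import PALMatrix

        write_pal_table(
            PALMatrix(result.pal_classical, log_base=config.log_base,
                      pathway_set_id="classical", cnr_source_id=config.expression),
            out / "pal_classical.tsv",
        )
    for name, frame in result.screens.items():
        frame.to_csv(out / f"screen_{name}.tsv", sep="\t", index=False, float_format="%.10g")
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.10g")

    buf = io.StringIO()
    buf.write("# palscreen run log\n## resolved configuration\n")
    for key, value in asdict(config).items():
        buf.write(f"{key} = {value}\n")
    buf.write("## events\n")
    for line in result.log:
        buf.write(line + "\n")
    (out / "run_log.txt").write_text(buf.getvalue(), encoding="utf-8")
    logger.info("report bundle written to %s", out)
    return result
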