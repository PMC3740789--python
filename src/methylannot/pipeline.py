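"""End-to-end probe annotation: merge all per-module annotations."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import genes as genes_mod
from . import islands as islands_mod
from . import snps as snps_mod
from . import specificity as spec_mod
from .core import ProbeRecord, compute_probe_intervals, validate_probe_against_genome
from .io import GeneModel, SnpRecord

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    sex_chroms: frozenset[str] = frozenset({"chrX", "chrY", "X", "Y"})
    hc_params: islands_mod.IslandParams = islands_mod.HC_PARAMS
    ic_params: islands_mod.IslandParams = islands_mod.IC_PARAMS
    ucsc_params: islands_mod.IslandParams = islands_mod.UCSC_PARAMS
    icshore_gap_tolerance: int = 0
    search: spec_mod.SearchParams = field(default_factory=spec_mod.SearchParams)
    validate_probes: bool = True


@dataclass
class AnnotationResult:
    table: pd.DataFrame
    summary: dict
    merged_islands: list
    ucsc_islands: list
    specificity: dict
    validation: dict


def annotate_all(
    genome: Mapping[str, str],
    probes: Sequence[ProbeRecord],
    snps: Sequence[SnpRecord] | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    config: RunConfig | None = None,
) -> AnnotationResult:
    """Run every annotation stage and merge per-probe records.

    rs-category probes are parsed but excluded from annotation.  SNP and
    gene-feature columns are emitted only when the corresponding inputs
    are supplied; their absence is recorded in the summary.
    """
    cfg = config or RunConfig()
    summary: dict = {"partial": []}

    annotatable = [p for p in probes if p.category != "rs"]
    summary["n_probes_input"] = len(probes)
    summary["n_rs_excluded"] = len(probes) - len(annotatable)
    intervals = {p.probe_id: compute_probe_intervals(p) for p in annotatable}

    validation: dict = {}
    if cfg.validate_probes:
        for p in annotatable:
            validation[p.probe_id] = validate_probe_against_genome(p, genome)
        summary["n_validated"] = sum(1 for v in validation.values() if v.valid)

    hc = islands_mod.find_islands(genome, cfg.hc_params, "HC")
    ic = islands_mod.find_islands(genome, cfg.ic_params, "IC")
    merged, adjacency = islands_mod.merge_hil(hc, ic, cfg.icshore_gap_tolerance)
    ucsc = islands_mod.find_islands(genome, cfg.ucsc_params, "UCSC")
    summary["n_hc_islands"] = len(hc)
    summary["n_ic_islands"] = len(ic)
    summary["n_ucsc_islands"] = len(ucsc)

    specificity = spec_mod.run_specificity_screen(
        annotatable, genome, cfg.sex_chroms, cfg.search
    )

    snp_ann: dict[str, snps_mod.SnpAnnotation] = {}
    if snps is not None:
        snp_ann = snps_mod.annotate_target_cpg_snps(annotatable, snps)
        snps_mod.classify_snp_proximity(annotatable, snps, snp_ann)
    else:
        summary["partial"].append("snp")

    if gene_models is None:
        summary["partial"].append("genes")

    rows = []
    for p in annotatable:
        iv = intervals[p.probe_id]
        hil = islands_mod.classify_probe_hil(iv, merged)
        ucsc_cls = islands_mod.classify_probe_ucsc(iv, ucsc)
        ss = specificity[p.probe_id]
        n_rep = spec_mod.count_repetitive_bp(iv.footprint, genome)
        row = {
            "probe_id": p.probe_id,
            "AlleleA_Hits": ss.allele_a_hits,
            "AlleleB_Hits": ss.allele_b_hits,
            "XY_Hits": ss.xy_hits,
            "Autosomal_Hits": ss.autosomal_hits,
            "Non_specific": int(ss.non_specific),
            "n_bp_repetitive": n_rep,
            "HIL_CpG_class": hil.label,
            "HIL_CpG_Island_Name": hil.island_name or "",
            "UCSC_CpG_class": ucsc_cls,
        }
        if snps is not None:
            ann = snp_ann.get(p.probe_id)
            if ann is not None:
                row["target CpG SNP"] = ";".join(ann.target_cpg_snps)
                row["n_target CpG SNP"] = ann.n_target_cpg_snp
            else:  # ch probes carry no SNP annotation
                row["target CpG SNP"] = ""
                row["n_target CpG SNP"] = 0
        if gene_models is not None:
            c0 = iv.target_cpg.start
            fs = genes_mod.annotate_position_features(
                p.probe_id, p.chrom, c0, gene_models
            )
            row.update(genes_mod.feature_indicator_row(fs))
            tss = genes_mod.closest_tss(p.probe_id, p.chrom, c0, gene_models)
            row["Closest_TSS"] = tss.closest_tss if not tss.missing else ""
            row["Distance_closest_TSS"] = tss.distance if not tss.missing else ""
            row["Closest_TSS_gene_name"] = tss.gene_name or ""
            row["Closest_TSS_Transcript"] = tss.transcript_id or ""
        rows.append(row)

    table = pd.DataFrame(rows)
    summary["hil_counts"] = table["HIL_CpG_class"].value_counts().to_dict()
    summary["ucsc_counts"] = table["UCSC_CpG_class"].value_counts().to_dict()
    summary["hil_x_ucsc"] = {
        f"{h}|{u}": int(n)
        for (h, u), n in table.groupby(
            ["HIL_CpG_class", "UCSC_CpG_class"]
        ).size().items()
    }
    summary["n_non_specific"] = int(table["Non_specific"].sum())
    summary["cross_hyb_table"] = spec_mod.cross_hyb_table(specificity.values())
    summary["icshore_adjacency"] = adjacency
    return AnnotationResult(
        table=table,
        summary=summary,
        merged_islands=merged,
        ucsc_islands=ucsc,
        specificity=specificity,
        validation=validation,
    )
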