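"""Target-CpG SNP annotation and SNP-proximity classes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import ProbeRecord, compute_probe_intervals
from .io import SnpRecord


@dataclass
class SnpAnnotation:
    probe_id: str
    target_cpg_snps: list[str] = field(default_factory=list)
    snp_lt10bp: bool = False
    snp_gt10bp: bool = False
    max_het: float | None = None

    @property
    def n_target_cpg_snp(self) -> int:
        return len(self.target_cpg_snps)

    @property
    def has_target_snp(self) -> bool:
        return bool(self.target_cpg_snps)


def _snp_lookup(snps: Iterable[SnpRecord]) -> dict[tuple[str, int], list[SnpRecord]]:
    table: dict[tuple[str, int], list[SnpRecord]] = {}
    for s in snps:
        table.setdefault((s.chrom, s.pos), []).append(s)
    return table


def annotate_target_cpg_snps(
    probes: Sequence[ProbeRecord], snps: Sequence[SnpRecord]
) -> dict[str, SnpAnnotation]:
    """Annotate cg probes whose target C or G coincides with a SNP.

    A SNP annotates a probe iff its 1-based position equals MAPINFO (the C)
    or MAPINFO+1 (the G), regardless of whether the G falls inside the
    probe footprint.  rs- and ch-category probes are skipped.
    """
    lookup = _snp_lookup(snps)
    out: dict[str, SnpAnnotation] = {}
    for probe in probes:
        if probe.category != "cg":
            continue
        ann = SnpAnnotation(probe_id=probe.probe_id)
        found: list[SnpRecord] = []
        for pos in (probe.mapinfo, probe.mapinfo + 1):
            found.extend(lookup.get((probe.chrom, pos), ()))
        seen = set()
        for s in found:
            if s.rs_id in seen:
                continue
            seen.add(s.rs_id)
            ann.target_cpg_snps.append(s.rs_id)
            if s.heterozygosity is not None:
                ann.max_het = (
                    s.heterozygosity
                    if ann.max_het is None
                    else max(ann.max_het, s.heterozygosity)
                )
        ann.target_cpg_snps.sort()
        out[probe.probe_id] = ann
    return out


def classify_snp_proximity(
    probes: Sequence[ProbeRecord],
    snps: Sequence[SnpRecord],
    annotations: Mapping[str, SnpAnnotation],
) -> dict[str, SnpAnnotation]:
    """Fill the <10 bp / >10 bp proximity flags.

    Distance is measured from the nearest base of the target CpG,
    inclusive; only SNPs under the probe footprint count.  The target-CpG
    positions themselves are handled by annotate_target_cpg_snps and do not
    set either proximity flag.
    """
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for probe in probes:
        ann = annotations.get(probe.probe_id)
        if ann is None:
            continue
        fp = compute_probe_intervals(probe).footprint
        c_pos, g_pos = probe.mapinfo, probe.mapinfo + 1
        for s in by_chrom.get(probe.chrom, ()):
            if not (fp.start + 1 <= s.pos <= fp.end):  # 1-based footprint span
                continue
            if s.pos in (c_pos, g_pos):
                continue
            dist = min(abs(s.pos - c_pos), abs(s.pos - g_pos))
            if dist <= 10:
                ann.snp_lt10bp = True
            else:
                ann.snp_gt10bp = True
    return dict(annotations)


def analysis_groups(annotations: Mapping[str, SnpAnnotation]) -> dict[str, set[str]]:
    """Probe groups for the variability analyses.

    Probes with a target-CpG SNP are removed from the <10 bp group.
    """
    target = {p for p, a in annotations.items() if a.has_target_snp}
    lt10 = {p for p, a in annotations.items() if a.snp_lt10bp} - target
    gt10 = {p for p, a in annotations.items() if a.snp_gt10bp}
    return {
        "all": set(annotations),
        "target_cpg_snp": target,
        "snp_lt10bp": lt10,
        "snp_gt10bp": gt10,
    }


def heterozygosity_summary(
    annotations: Mapping[str, SnpAnnotation]
) -> dict[str, float]:
    """Fractions of target-SNP probes by documented heterozygosity.

    Bins: not documented as variable (no value or 0), (0, 0.1], and >0.1.
    Fractions are over probes with at least one target-CpG SNP.
    """
    annotated = [a for a in annotations.values() if a.has_target_snp]
    if not annotated:
        return {"not_documented": 0.0, "le_0.1": 0.0, "gt_0.1": 0.0}
    n = len(annotated)
    not_doc = sum(1 for a in annotated if a.max_het is None or a.max_het == 0)
    high = sum(1 for a in annotated if a.max_het is not None and a.max_het > 0.1)
    low = n - not_doc - high
    return {
        "not_documented": not_doc / n,
        "le_0.1": low / n,
        "gt_0.1": high / n,
    }
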