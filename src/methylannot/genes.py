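"""Nine-way gene-feature classification and closest-TSS annotation.

Each transcript is decomposed into three gene regions (5'UTR, body and
3'UTR, strand-aware from the cds boundaries) and three components (first
exon = the most upstream exon in transcription direction, other exons and
introns).  The pairwise intersections give nine feature classes; a probe
collects one label per overlapping transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import GenomicInterval
from .io import GeneModel

REGIONS = ("5'UTR", "body", "3'UTR")
COMPONENTS = ("first exon", "exon", "intron")
FEATURE_LABELS = tuple(f"{r} {c}" for r in REGIONS for c in COMPONENTS)


@dataclass
class FeatureSet:
    probe_id: str
    #: one (label, transcript_id, gene_name) per overlapping transcript
    transcript_labels: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [lbl for lbl, _, _ in self.transcript_labels]

    @property
    def gene_labels(self) -> dict[str, set[str]]:
        """Collapsed view: unique labels per gene name."""
        out: dict[str, set[str]] = {}
        for lbl, _, gene in self.transcript_labels:
            out.setdefault(gene, set()).add(lbl)
        return out

    @property
    def unique_labels(self) -> set[str]:
        return set(self.labels)


@dataclass
class TssAnnotation:
    probe_id: str
    closest_tss: int | None  # 1-based position
    distance: int | None  # unsigned bp
    signed_distance: int | None  # negative = probe upstream of the TSS
    gene_name: str | None
    transcript_id: str | None
    tie: bool = False
    missing: bool = False


def _regions(model: GeneModel) -> list[tuple[str, int, int]]:
    """(region label, start, end) pieces of the transcript span."""
    if not model.is_coding:
        return [("body", model.tx_start, model.tx_end)]
    if model.strand == "+":
        pieces = [
            ("5'UTR", model.tx_start, model.cds_start),
            ("body", model.cds_start, model.cds_end),
            ("3'UTR", model.cds_end, model.tx_end),
        ]
    else:
        pieces = [
            ("3'UTR", model.tx_start, model.cds_start),
            ("body", model.cds_start, model.cds_end),
            ("5'UTR", model.cds_end, model.tx_end),
        ]
    return [(lbl, s, e) for lbl, s, e in pieces if e > s]


def _components(model: GeneModel) -> list[tuple[str, int, int]]:
    first_idx = 0 if model.strand == "+" else len(model.exon_starts) - 1
    pieces = []
    for i, (s, e) in enumerate(zip(model.exon_starts, model.exon_ends)):
        pieces.append(("first exon" if i == first_idx else "exon", s, e))
    for iv in model.introns():
        pieces.append(("intron", iv.start, iv.end))
    # transcript span outside the exon range (degenerate models) is intronic
    if model.exon_starts and model.tx_start < model.exon_starts[0]:
        pieces.append(("intron", model.tx_start, model.exon_starts[0]))
    if model.exon_ends and model.exon_ends[-1] < model.tx_end:
        pieces.append(("intron", model.exon_ends[-1], model.tx_end))
    return pieces


def build_feature_intervals(model: GeneModel) -> dict[str, list[GenomicInterval]]:
    """Nine labeled interval lists as region x component intersections."""
    out: dict[str, list[GenomicInterval]] = {lbl: [] for lbl in FEATURE_LABELS}
    for r_lbl, r_s, r_e in _regions(model):
        for c_lbl, c_s, c_e in _components(model):
            s, e = max(r_s, c_s), min(r_e, c_e)
            if e > s:
                out[f"{r_lbl} {c_lbl}"].append(
                    GenomicInterval(model.chrom, s, e, model.strand)
                )
    return out


def feature_label_at(model: GeneModel, pos: int) -> str | None:
    """Feature label of a single base within one transcript, or None outside it."""
    if not (model.tx_start <= pos < model.tx_end):
        return None
    component = "intron"
    first_idx = 0 if model.strand == "+" else len(model.exon_starts) - 1
    for i, (s, e) in enumerate(zip(model.exon_starts, model.exon_ends)):
        if s <= pos < e:
            component = "first exon" if i == first_idx else "exon"
            break
    for r_lbl, r_s, r_e in _regions(model):
        if r_s <= pos < r_e:
            return f"{r_lbl} {component}"
    return None  # base falls before first region piece (degenerate model)


def annotate_position_features(
    probe_id: str, chrom: str, pos: int, models: Sequence[GeneModel]
) -> FeatureSet:
    """Feature labels of a genomic base across all overlapping transcripts."""
    fs = FeatureSet(probe_id=probe_id)
    seen: set[tuple[str, str]] = set()
    for model in models:
        if model.chrom != chrom:
            continue
        label = feature_label_at(model, pos)
        if label is None:
            continue
        key = (label, model.transcript_id)
        if key in seen:
            continue
        seen.add(key)
        fs.transcript_labels.append((label, model.transcript_id, model.gene_name))
    return fs


def annotate_probe_features(probe_intervals, models: Sequence[GeneModel],
                            probe_id: str = "?") -> FeatureSet:
    t = probe_intervals.target_cpg
    return annotate_position_features(probe_id, t.chrom, t.start, models)


def closest_tss(
    probe_id: str, chrom: str, pos: int, models: Sequence[GeneModel]
) -> TssAnnotation:
    """Closest strand-aware TSS to the target C, over all transcripts.

    ``pos`` is the 0-based C position.  Ties are broken towards the
    lexicographically smallest transcript id and flagged.
    """
    candidates = [m for m in models if m.chrom == chrom]
    if not candidates:
        return TssAnnotation(probe_id, None, None, None, None, None, missing=True)
    best: GeneModel | None = None
    best_dist: int | None = None
    tie = False
    for m in sorted(candidates, key=lambda m: m.transcript_id):
        dist = abs(pos - m.tss)
        if best_dist is None or dist < best_dist:
            best, best_dist, tie = m, dist, False
        elif dist == best_dist:
            tie = True
    assert best is not None and best_dist is not None
    signed = pos - best.tss if best.strand == "+" else best.tss - pos
    return TssAnnotation(
        probe_id=probe_id,
        closest_tss=best.tss + 1,
        distance=best_dist,
        signed_distance=signed,
        gene_name=best.gene_name,
        transcript_id=best.transcript_id,
        tie=tie,
    )


def feature_indicator_row(fs: FeatureSet) -> dict[str, int]:
    """0/1 indicator per feature label for the merged annotation table."""
    present = fs.unique_labels
    return {lbl: int(lbl in present) for lbl in FEATURE_LABELS}
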