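"""In-silico bisulfite cross-hybridization screening.

Probes are matched against four bisulfite-converted genome variants:
fully unmethylated (all C->T) and fully methylated (only non-CpG C->T)
conversions of the forward sequence, and the same two conversions of the
reverse complement.  Candidate placements are generated by exact 12-mer
seeding and scored by ungapped comparison anchored at the probe's 3'
(50th) base, trimming only the 5' boundary; a hit is accepted
when identity over the aligned region is >=90%, at least 40 of 50 bases
match, there are no gaps and the probe's 50th (3'-terminal) base lies
inside the chromosome.  Accepted hits are collapsed to distinct genomic
loci by their genomic footprint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import (
    PROBE_LENGTH,
    ProbeRecord,
    compute_probe_intervals,
    reverse_complement,
)

VARIANTS = ("unmeth_fwd", "meth_fwd", "unmeth_rev", "meth_rev")

_NON_CPG_C = re.compile(r"C(?!(?:[Gg]))|c(?!(?:[Gg]))")


def _convert_unmeth(seq: str) -> str:
    return seq.translate(str.maketrans("Cc", "Tt"))


def _convert_meth(seq: str) -> str:
    return _NON_CPG_C.sub(lambda m: "T" if m.group(0) == "C" else "t", seq)


def bisulfite_convert(genome: Mapping[str, str], variant: str) -> dict[str, str]:
    """Build one of the four bisulfite genome variants (case preserved)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    conv = _convert_unmeth if variant.startswith("unmeth") else _convert_meth
    out = {}
    for chrom, seq in genome.items():
        if variant.endswith("_rev"):
            seq = reverse_complement(seq)
        out[chrom] = conv(seq)
    return out


def build_variants(genome: Mapping[str, str]) -> dict[str, dict[str, str]]:
    return {v: bisulfite_convert(genome, v) for v in VARIANTS}


def expand_degenerate(probe_seq: str, assay_type: str = "II") -> list[str]:
    """Concrete sequence versions of a possibly R-containing probe.

    R positions are jointly replaced: one all-A version and one all-G
    version (mixed substitutions are not enumerated).
    """
    if "R" not in probe_seq:
        return [probe_seq]
    if assay_type == "I":
        raise ValueError("R is not permitted in type I probe sequences")
    return [probe_seq.replace("R", "A"), probe_seq.replace("R", "G")]


@dataclass(frozen=True)
class AlignmentHit:
    probe_id: str
    allele: str  # "A" or "B"
    degenerate_version: str  # "R->A", "R->G" or "none"
    variant: str
    chrom: str
    start: int  # position in variant coordinates
    orientation: str  # "+" probe matched variant as-is; "-" via reverse complement
    matches: int
    aligned_length: int
    gaps: int
    pos50_aligned: bool
    genomic_start: int
    genomic_end: int
    is_intended_target: bool

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.chrom, self.genomic_start, self.genomic_end)


@dataclass(frozen=True)
class SearchParams:
    seed_length: int = 12
    max_candidates: int = 10_000
    min_identity: float = 0.90
    min_matches: int = 40


@dataclass
class SpecificitySummary:
    probe_id: str
    allele_a_hits: int
    allele_b_hits: int
    xy_hits: int
    autosomal_hits: int
    n_loci: int
    non_specific: bool
    no_hit: bool
    saturated: bool
    intended_chrom_class: str  # "auto" or "sex"
    cross_hyb_auto: bool
    cross_hyb_sex: bool
    loci: list[tuple[str, int, int]] = field(default_factory=list)


class SeedIndex:
    """Exact k-mer index over the four variant genomes (uppercase)."""

    def __init__(self, variants: Mapping[str, Mapping[str, str]], seed_length: int):
        self.seed_length = seed_length
        self.upper: dict[tuple[str, str], str] = {}
        self.index: dict[tuple[str, str], dict[str, list[int]]] = {}
        for vname, chroms in variants.items():
            for chrom, seq in chroms.items():
                key = (vname, chrom)
                s = seq.upper()
                self.upper[key] = s
                idx: dict[str, list[int]] = {}
                for i in range(len(s) - seed_length + 1):
                    idx.setdefault(s[i : i + seed_length], []).append(i)
                self.index[key] = idx

    def candidates(self, key: tuple[str, str], query: str) -> set[int]:
        """Placements sharing at least one exact seed with *query*."""
        idx = self.index[key]
        k = self.seed_length
        out: set[int] = set()
        for off in range(len(query) - k + 1):
            for pos in idx.get(query[off : off + k], ()):
                out.add(pos - off)
        return out


def best_anchored_extent(flags: Sequence[bool]) -> tuple[int, int]:
    """(matches, aligned_length) of the best 3'-anchored ungapped extent.

    *flags* are per-base match indicators in probe order (index 0 = 5' end).
    The aligned region must end at the probe's 3'-most aligned base; its 5'
    boundary is trimmed to maximize matches-minus-mismatches (ties resolved
    towards the longer extent), mirroring how a local aligner trims
    low-identity probe ends while keeping the 3' anchor.
    """
    best_score = None
    best = (0, 0)
    score = 0
    matches = 0
    n = len(flags)
    for k in range(n - 1, -1, -1):
        if flags[k]:
            score += 1
            matches += 1
        else:
            score -= 1
        if best_score is None or score >= best_score:
            best_score = score
            best = (matches, n - k)
    return best


def _score_placement(
    target: str,
    query: str,
    start: int,
    orientation: str,
) -> tuple[int, int, bool]:
    """(matches, aligned_length, pos50_aligned) for an ungapped placement.

    The probe's 50th base maps to query index 49 for "+" placements and to
    query index 0 (variant position *start*) for "-" placements, because a
    "-" hit is found through the reverse complement of the probe.
    pos50_aligned is true iff that base lies inside the chromosome.
    """
    length = len(target)
    lo = max(0, start)
    hi = min(length, start + len(query))
    if hi <= lo:
        return 0, 0, False
    flags = [target[i] == query[i - start] for i in range(lo, hi)]
    if orientation == "-":
        flags.reverse()  # query is revcomp(probe): probe order is reversed
        pos50 = start
    else:
        pos50 = start + len(query) - 1
    matches, aligned = best_anchored_extent(flags)
    return matches, aligned, 0 <= pos50 < length


def _genomic_footprint(
    variant: str, chrom_len: int, start: int, qlen: int
) -> tuple[int, int]:
    if variant.endswith("_rev"):
        return chrom_len - (start + qlen), chrom_len - start
    return start, start + qlen


def _probe_versions(probe: ProbeRecord) -> list[tuple[str, str, str]]:
    """(allele, degenerate label, concrete sequence) triples for one probe."""
    versions = []
    for allele, seq in (("A", probe.probe_seq_A), ("B", probe.probe_seq_B)):
        if seq is None:
            continue
        expanded = expand_degenerate(seq, probe.assay_type)
        if len(expanded) == 1:
            versions.append((allele, "none", expanded[0]))
        else:
            versions.append((allele, "R->A", expanded[0]))
            versions.append((allele, "R->G", expanded[1]))
    return versions


def find_candidate_hits(
    probe: ProbeRecord,
    seed_index: SeedIndex,
    params: SearchParams = SearchParams(),
) -> tuple[list[AlignmentHit], bool]:
    """Score every seeded placement of a probe across all variants.

    The intended-target placement (the probe footprint mapped into each
    variant) is always scored, even when no seed covers it.  Returns the
    hits plus a flag indicating candidate-set saturation.
    """
    fp = compute_probe_intervals(probe).footprint
    hits: list[AlignmentHit] = []
    saturated = False
    for allele, degen, seq in _probe_versions(probe):
        queries = (("-", reverse_complement(seq)), ("+", seq))
        for (vname, chrom), target in seed_index.upper.items():
            chrom_len = len(target)
            for orientation, query in queries:
                cand = seed_index.candidates((vname, chrom), query)
                if len(cand) > params.max_candidates:
                    saturated = True
                    cand = set(sorted(cand)[: params.max_candidates])
                if chrom == probe.chrom:
                    # intended placement in variant coordinates
                    if vname.endswith("_rev"):
                        cand.add(chrom_len - fp.end)
                    else:
                        cand.add(fp.start)
                for start in cand:
                    matches, aligned, pos50 = _score_placement(
                        target, query, start, orientation
                    )
                    if aligned == 0:
                        continue
                    g_start, g_end = _genomic_footprint(
                        vname, chrom_len, start, len(query)
                    )
                    hits.append(
                        AlignmentHit(
                            probe_id=probe.probe_id,
                            allele=allele,
                            degenerate_version=degen,
                            variant=vname,
                            chrom=chrom,
                            start=start,
                            orientation=orientation,
                            matches=matches,
                            aligned_length=aligned,
                            gaps=0,
                            pos50_aligned=pos50,
                            genomic_start=g_start,
                            genomic_end=g_end,
                            is_intended_target=(
                                chrom == probe.chrom
                                and g_start == fp.start
                                and g_end == fp.end
                            ),
                        )
                    )
    return hits, saturated


def filter_hits(
    hits: Iterable[AlignmentHit], params: SearchParams = SearchParams()
) -> list[AlignmentHit]:
    """Apply the hit-acceptance criteria."""
    out = []
    for h in hits:
        if h.aligned_length == 0:
            continue
        if h.matches / h.aligned_length < params.min_identity:
            continue
        if h.matches < params.min_matches:
            continue
        if h.gaps != 0:
            continue
        if not h.pos50_aligned:
            continue
        out.append(h)
    return out


def distinct_loci(accepted: Iterable[AlignmentHit]) -> list[tuple[str, int, int]]:
    """Collapse accepted hits across variants/versions to genomic loci."""
    return sorted({h.locus for h in accepted})


DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def summarize_specificity(
    probe: ProbeRecord,
    accepted: Sequence[AlignmentHit],
    sex_chroms: frozenset[str] | set[str] = DEFAULT_SEX_CHROMS,
    saturated: bool = False,
) -> SpecificitySummary:
    loci = distinct_loci(accepted)
    a_loci = {h.locus for h in accepted if h.allele == "A"}
    b_loci = {h.locus for h in accepted if h.allele == "B"}
    fp = compute_probe_intervals(probe).footprint
    intended_locus = (fp.chrom, fp.start, fp.end)
    cross = [l for l in loci if l != intended_locus]
    xy = [l for l in loci if l[0] in sex_chroms]
    auto = [l for l in loci if l[0] not in sex_chroms]
    intended_class = "sex" if probe.chrom in sex_chroms else "auto"
    return SpecificitySummary(
        probe_id=probe.probe_id,
        allele_a_hits=len(a_loci),
        allele_b_hits=len(b_loci),
        xy_hits=len(xy),
        autosomal_hits=len(auto),
        n_loci=len(loci),
        non_specific=len(loci) > 1,
        no_hit=len(loci) == 0,
        saturated=saturated,
        intended_chrom_class=intended_class,
        cross_hyb_auto=any(l[0] not in sex_chroms for l in cross),
        cross_hyb_sex=any(l[0] in sex_chroms for l in cross),
        loci=loci,
    )


def run_specificity_screen(
    probes: Sequence[ProbeRecord],
    genome: Mapping[str, str],
    sex_chroms: frozenset[str] | set[str] = DEFAULT_SEX_CHROMS,
    params: SearchParams = SearchParams(),
) -> dict[str, SpecificitySummary]:
    """Full screen: build variants, search, filter and summarize per probe."""
    variants = build_variants(genome)
    index = SeedIndex(variants, params.seed_length)
    summaries = {}
    for probe in probes:
        hits, saturated = find_candidate_hits(probe, index, params)
        accepted = filter_hits(hits, params)
        summaries[probe.probe_id] = summarize_specificity(
            probe, accepted, sex_chroms, saturated
        )
    return summaries


def cross_hyb_table(summaries: Iterable[SpecificitySummary]) -> dict[str, int]:
    """Cross-classification of non-specific probes by intended vs cross-hyb
    chromosome class (autosome / sex chromosome)."""
    table = {
        "intended_auto_cross_auto_only": 0,
        "intended_auto_cross_sex_only": 0,
        "intended_auto_cross_both": 0,
        "intended_sex_cross_auto_only": 0,
        "intended_sex_cross_sex_only": 0,
        "intended_sex_cross_both": 0,
    }
    for s in summaries:
        if not s.non_specific:
            continue
        side = "auto" if s.intended_chrom_class == "auto" else "sex"
        if s.cross_hyb_auto and s.cross_hyb_sex:
            table[f"intended_{side}_cross_both"] += 1
        elif s.cross_hyb_sex:
            table[f"intended_{side}_cross_sex_only"] += 1
        elif s.cross_hyb_auto:
            table[f"intended_{side}_cross_auto_only"] += 1
    return table


def count_repetitive_bp(footprint, genome: Mapping[str, str]) -> int:
    """Number of soft-masked (lowercase) bases under the intended footprint."""
    seq = genome[footprint.chrom][footprint.start : footprint.end]
    return sum(1 for b in seq if b.islower())


def repetitive_flags(n_bp: int, non_specific: bool) -> tuple[bool, bool]:
    """(mostly-repetitive, fully-repetitive-and-specific) flags."""
    return n_bp > 25, n_bp == PROBE_LENGTH and not non_specific
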