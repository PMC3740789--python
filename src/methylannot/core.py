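"""Domain types and probe-coordinate arithmetic.

Coordinates are 0-based half-open internally.  Manifest MAPINFO is the
1-based genomic position of the C of the interrogated CpG and is converted
on ingest.  The probe geometry (where the 50-mer footprint sits relative to
the target C for each assay type x design strand combination) is fixed by
the requirement that :func:`validate_probe_against_genome` round-trips on
sequences derived from the genome itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

PROBE_LENGTH = 50

_COMPLEMENT = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")
_ALLOWED_RC = set("ACGTNRYacgtnry")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside the supported alphabet."""


class ProbeDefinitionError(ValueError):
    """Raised for probes with unknown assay type / design strand codes."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement *seq*, preserving case.

    Accepts A/C/G/T/N plus the purine code R (complemented to Y) and Y
    (complemented to R); anything else is rejected.
    """
    bad = set(seq) - _ALLOWED_RC
    if bad:
        raise SequenceAlphabetError(
            f"unsupported characters in sequence: {sorted(bad)!r}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class ProbeRecord:
    """One manifest row.

    ``mapinfo`` is the 1-based position of the C of the target CpG.
    Type I probes carry two allele sequences (A = unmethylated design,
    B = methylated design); type II probes carry a single sequence in
    which C/T-degenerate positions appear as ``R``.
    """

    probe_id: str
    assay_type: str  # "I" or "II"
    design_strand: str  # "F" or "R"
    chrom: str
    mapinfo: int
    probe_seq_A: str
    probe_seq_B: str | None = None

    def __post_init__(self) -> None:
        if self.assay_type not in ("I", "II"):
            raise ProbeDefinitionError(
                f"probe {self.probe_id}: unknown assay type {self.assay_type!r}"
            )
        if self.design_strand not in ("F", "R"):
            raise ProbeDefinitionError(
                f"probe {self.probe_id}: unknown design strand {self.design_strand!r}"
            )
        if self.mapinfo < 1:
            raise ProbeDefinitionError(
                f"probe {self.probe_id}: MAPINFO must be >= 1, got {self.mapinfo}"
            )
        if len(self.probe_seq_A) != PROBE_LENGTH:
            raise ProbeDefinitionError(
                f"probe {self.probe_id}: allele A sequence must be "
                f"{PROBE_LENGTH} nt, got {len(self.probe_seq_A)}"
            )
        if self.assay_type == "I":
            if self.probe_seq_B is None or len(self.probe_seq_B) != PROBE_LENGTH:
                raise ProbeDefinitionError(
                    f"probe {self.probe_id}: type I probes need a 50 nt allele B sequence"
                )
            if "R" in self.probe_seq_A or "R" in self.probe_seq_B:
                raise ProbeDefinitionError(
                    f"probe {self.probe_id}: R is only valid in type II sequences"
                )
        else:
            if self.probe_seq_B is not None:
                raise ProbeDefinitionError(
                    f"probe {self.probe_id}: type II probes carry a single sequence"
                )

    @property
    def category(self) -> str:
        """Probe category by id prefix: cg, ch or rs."""
        for prefix in ("cg", "ch", "rs"):
            if self.probe_id.startswith(prefix):
                return prefix
        return "other"


@dataclass(frozen=True)
class ProbeIntervals:
    """The three derived genomic intervals of a probe.

    ``footprint`` is the exact 50-base genomic placement of the synthesized
    probe; ``entire_probe`` equals the footprint except for type I R-design
    probes, where the adjacent target C extends it to 51 bp.
    """

    target_cpg: GenomicInterval
    probe_wo_cpg: GenomicInterval
    entire_probe: GenomicInterval
    footprint: GenomicInterval


def compute_probe_intervals(probe: ProbeRecord) -> ProbeIntervals:
    """Derive target-CpG / probe-without-CpG / entire-probe intervals.

    Geometry (0-based; ``c0`` = MAPINFO-1 is the C, ``g0`` = c0+1 the G):

    ========  ======  =====================  =====================
    type      strand  footprint (50 bp)      entire_probe
    ========  ======  =====================  =====================
    I         F       [c0-49, c0+1)          = footprint (has C)
    I         R       [g0, g0+50)            [c0, g0+50)  (51 bp)
    II        F       [c0-50, c0)            = footprint
    II        R       [g0+1, g0+51)          = footprint
    ========  ======  =====================  =====================
    """
    c0 = probe.mapinfo - 1
    g0 = c0 + 1
    chrom = probe.chrom
    if probe.assay_type == "I" and probe.design_strand == "F":
        leftmost = c0 - PROBE_LENGTH + 1
    elif probe.assay_type == "II" and probe.design_strand == "F":
        leftmost = c0 - PROBE_LENGTH
    else:
        leftmost = c0
    if leftmost < 0:
        raise ProbeDefinitionError(
            f"probe {probe.probe_id}: footprint extends past chromosome start"
        )
    target = GenomicInterval(chrom, c0, g0 + 1)

    if probe.assay_type == "I":
        if probe.design_strand == "F":
            fp = GenomicInterval(chrom, c0 - PROBE_LENGTH + 1, c0 + 1)
            entire = fp
            wo = GenomicInterval(chrom, fp.start, c0)
        else:
            fp = GenomicInterval(chrom, g0, g0 + PROBE_LENGTH)
            entire = GenomicInterval(chrom, c0, g0 + PROBE_LENGTH)
            wo = GenomicInterval(chrom, g0 + 1, g0 + PROBE_LENGTH)
    else:
        if probe.design_strand == "F":
            fp = GenomicInterval(chrom, c0 - PROBE_LENGTH, c0)
            entire = fp
            wo = fp
        else:
            fp = GenomicInterval(chrom, g0 + 1, g0 + 1 + PROBE_LENGTH)
            entire = fp
            wo = fp

    if fp.start < 0:
        raise ProbeDefinitionError(
            f"probe {probe.probe_id}: footprint extends past chromosome start"
        )
    return ProbeIntervals(target_cpg=target, probe_wo_cpg=wo, entire_probe=entire, footprint=fp)


# ---------------------------------------------------------------------------
# in-silico bisulfite sequence derivation
# ---------------------------------------------------------------------------

def bisulfite_convert_seq(seq: str, mode: str, next_base: str = "N") -> str:
    """Bisulfite-convert a (sense-strand) sequence, preserving case.

    mode="unmeth": every C becomes T.  mode="meth": Cs in CpG context are
    retained, all other Cs become T.  mode="degenerate": Cs in CpG context
    become Y (C-or-T), all other Cs become T.  ``next_base`` supplies the
    base following the sequence so that a terminal C gets correct context.
    """
    if mode not in ("unmeth", "meth", "degenerate"):
        raise ValueError(f"unknown conversion mode {mode!r}")
    out = []
    n = len(seq)
    for i, b in enumerate(seq):
        if b in "Cc":
            follower = seq[i + 1] if i + 1 < n else next_base
            in_cpg = follower in "Gg"
            if mode == "unmeth" or not in_cpg:
                repl = "T" if b == "C" else "t"
            elif mode == "meth":
                repl = b
            else:
                repl = "Y" if b == "C" else "y"
            out.append(repl)
        else:
            out.append(b)
    return "".join(out)


def _plus_strand_template(chrom_seq: str, fp: GenomicInterval) -> tuple[str, str]:
    """Footprint sequence on the plus strand plus its 3'-context base."""
    seg = chrom_seq[fp.start:fp.end].upper()
    nxt = chrom_seq[fp.end].upper() if fp.end < len(chrom_seq) else "N"
    return seg, nxt


def _minus_strand_template(chrom_seq: str, fp: GenomicInterval) -> tuple[str, str]:
    """Footprint sequence read on the minus strand plus its 3'-context base."""
    seg = reverse_complement(chrom_seq[fp.start:fp.end].upper())
    nxt = (
        reverse_complement(chrom_seq[fp.start - 1].upper())
        if fp.start > 0
        else "N"
    )
    return seg, nxt


def expected_probe_sequences(
    chrom_seq: str,
    assay_type: str,
    design_strand: str,
    mapinfo: int,
    chrom: str = "chr?",
) -> tuple[str, str | None]:
    """Derive the manifest probe sequence(s) implied by the genome.

    The probe is the reverse complement of the bisulfite-converted target
    strand under its footprint (plus strand for F designs, minus strand for
    R designs).  Type I returns (allele A, allele B) built against the
    fully-unmethylated and fully-methylated conversions; type II returns a
    single sequence with CpG-degenerate positions encoded as R.
    """
    dummy = ProbeRecord(
        probe_id="cg_tmp",
        assay_type=assay_type,
        design_strand=design_strand,
        chrom=chrom,
        mapinfo=mapinfo,
        probe_seq_A="A" * PROBE_LENGTH,
        probe_seq_B="A" * PROBE_LENGTH if assay_type == "I" else None,
    )
    fp = compute_probe_intervals(dummy).footprint
    if fp.end > len(chrom_seq):
        raise ValueError("probe footprint extends past chromosome end")
    if design_strand == "F":
        template, nxt = _plus_strand_template(chrom_seq, fp)
    else:
        template, nxt = _minus_strand_template(chrom_seq, fp)

    if assay_type == "I":
        seq_a = reverse_complement(bisulfite_convert_seq(template, "unmeth", nxt))
        seq_b = reverse_complement(bisulfite_convert_seq(template, "meth", nxt))
        return seq_a, seq_b
    seq = reverse_complement(bisulfite_convert_seq(template, "degenerate", nxt))
    return seq, None


def degenerate_match(expected: str, observed: str) -> list[int]:
    """Positions where two probe sequences disagree, treating R as A-or-G."""
    if len(expected) != len(observed):
        raise ValueError("sequences must have equal length")
    mismatches = []
    for i, (e, o) in enumerate(zip(expected.upper(), observed.upper())):
        if e == o:
            continue
        if e == "R" and o in "AG":
            continue
        if o == "R" and e in "AG":
            continue
        mismatches.append(i)
    return mismatches


@dataclass
class ValidationReport:
    probe_id: str
    valid: bool
    unvalidatable: bool = False
    mismatch_positions: list[int] = field(default_factory=list)
    message: str = ""


def validate_probe_against_genome(
    probe: ProbeRecord, genome: Mapping[str, str]
) -> ValidationReport:
    """Check that the stored allele A sequence round-trips from the genome."""
    if probe.chrom not in genome:
        return ValidationReport(
            probe.probe_id, False, unvalidatable=True,
            message=f"chromosome {probe.chrom} absent from genome",
        )
    chrom_seq = genome[probe.chrom]
    try:
        ivals = compute_probe_intervals(probe)
        if ivals.footprint.end > len(chrom_seq):
            raise ValueError("footprint out of chromosome bounds")
        expected_a, _ = expected_probe_sequences(
            chrom_seq, probe.assay_type, probe.design_strand, probe.mapinfo,
            chrom=probe.chrom,
        )
    except (ValueError, ProbeDefinitionError) as exc:
        return ValidationReport(
            probe.probe_id, False, unvalidatable=True, message=str(exc)
        )
    mismatches = degenerate_match(expected_a, probe.probe_seq_A)
    return ValidationReport(
        probe.probe_id,
        valid=not mismatches,
        mismatch_positions=mismatches,
        message="" if not mismatches else f"{len(mismatches)} mismatching positions",
    )
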