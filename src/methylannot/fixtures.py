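"""Deterministic generators for every input the pipeline consumes.

Each generated artifact carries machine-readable planted truth so that
downstream tests never have to re-derive expectations with the code under
test.  All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    PROBE_LENGTH,
    GenomicInterval,
    ProbeRecord,
    compute_probe_intervals,
    expected_probe_sequences,
)
from .io import GeneModel, SnpRecord
from .islands import HC_PARAMS, IC_PARAMS, IslandParams, gc_content, obs_exp_cpg
from .stats import BetaMatrix


# ---------------------------------------------------------------------------
# genome + probe fixture
# ---------------------------------------------------------------------------

@dataclass
class IslandSpec:
    """A planted CpG-dense block.

    Blocks are delimited by a masked (N) base on each side: windows
    containing N never qualify, so the scanner cannot blend a planted
    block with its flanks and recovery is exact.  An IC block that should
    read as "bordering" an HC block therefore sits 1 masked base away,
    which the merge step bridges with its gap-tolerance knob.
    """

    chrom: str
    start: int
    length: int
    density_class: str  # "HC" or "IC"
    gc: float


@dataclass
class RepeatSpec:
    chrom: str
    start: int
    length: int


@dataclass
class ProbeSpec:
    probe_id: str
    assay_type: str
    design_strand: str
    chrom: str
    mapinfo: int
    plant_internal_cpg: bool = False
    #: when False the builder does not write a CG at the target position and
    #: instead requires the genome to already carry one there
    plant_target_cpg: bool = True


@dataclass
class DuplicationSpec:
    """Copy a host probe's footprint elsewhere with controlled identity.

    ``n_mismatches`` bases are swapped A<->T on the copy; with
    ``protect_3prime`` the mismatches are confined to a contiguous block at
    the probe's 5' end (probe indices 2 .. 1+n), leaving the 3' terminus
    intact so the decoy survives 3'-anchored alignment trimming.
    """

    host_probe_id: str
    dest_chrom: str
    dest_start: int
    n_mismatches: int = 0
    protect_3prime: bool = True


@dataclass
class FixtureSpec:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000, "chrX": 8_000}
    )
    gc_background: float = 0.30
    islands: list[IslandSpec] = field(default_factory=list)
    repeats: list[RepeatSpec] = field(default_factory=list)
    probes: list[ProbeSpec] = field(default_factory=list)
    duplications: list[DuplicationSpec] = field(default_factory=list)
    #: gap (bp) bridged when deciding IC-borders-HC; 1 bridges the masked
    #: separator bases between planted blocks
    icshore_gap_tolerance: int = 1


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: dict[str, str]
    probes: list[ProbeRecord]
    truth: dict


class UnsatisfiableSpecError(ValueError):
    pass


def _probe_index_to_genomic(fp: GenomicInterval, design_strand: str, i: int) -> int:
    """Genomic position of probe-space index *i* (0 = 5' end) of a footprint."""
    if design_strand == "F":
        return fp.start + (PROBE_LENGTH - 1 - i)
    return fp.start + i


def _sample_block(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


_ISLAND_PARAMS = {"HC": HC_PARAMS, "IC": IC_PARAMS}


def _plant_island(
    rng: np.random.Generator, arr: np.ndarray, spec: IslandSpec, max_tries: int = 100
) -> None:
    params: IslandParams = _ISLAND_PARAMS[spec.density_class]
    if spec.length <= params.min_len:
        raise UnsatisfiableSpecError(
            f"island of class {spec.density_class} needs length > {params.min_len}"
        )
    # an IC block longer than the HC minimum must keep its GC below the HC
    # threshold or it would qualify as HC as well
    if spec.density_class == "IC" and spec.length > HC_PARAMS.min_len:
        upper = HC_PARAMS.min_gc
    else:
        upper = 1.0
    for _ in range(max_tries):
        block = _sample_block(rng, spec.length, spec.gc)
        gc = gc_content(block)
        oe = obs_exp_cpg(block)
        if gc is None or not (params.min_gc < gc <= upper) or oe <= params.min_oe:
            continue
        arr[spec.start : spec.start + spec.length] = list(block)
        # masked separators pin the block boundaries for the scanner
        if spec.start > 0:
            arr[spec.start - 1] = "N"
        if spec.start + spec.length < len(arr):
            arr[spec.start + spec.length] = "N"
        return
    raise UnsatisfiableSpecError(
        f"could not satisfy island spec {spec} after {max_tries} tries"
    )


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Construct a genome, probes and planted truth from a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    arrays: dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        arrays[chrom] = np.array(list(_sample_block(rng, length, spec.gc_background)))

    for isl in spec.islands:
        _plant_island(rng, arrays[isl.chrom], isl)

    # plant target CpGs (and optional internal CpGs) for every probe
    for p in spec.probes:
        arr = arrays[p.chrom]
        c0 = p.mapinfo - 1
        if p.plant_target_cpg:
            arr[c0] = "C"
            arr[c0 + 1] = "G"
        if p.plant_internal_cpg:
            if p.assay_type != "II":
                raise UnsatisfiableSpecError(
                    "internal degenerate CpGs are a type II construct"
                )
            pos = c0 - 20 if p.design_strand == "F" else c0 + 22
            arr[pos] = "C"
            arr[pos + 1] = "G"

    # re-verify islands after CpG planting
    for isl in spec.islands:
        block = "".join(arrays[isl.chrom][isl.start : isl.start + isl.length])
        params = _ISLAND_PARAMS[isl.density_class]
        gc = gc_content(block)
        if gc is None or gc <= params.min_gc or obs_exp_cpg(block) <= params.min_oe:
            raise UnsatisfiableSpecError(
                f"island at {isl.chrom}:{isl.start} no longer satisfies its "
                "thresholds after CpG planting"
            )

    # duplication hosts: force the designated mismatch positions to A/T so
    # that A<->T swaps on the copy control identity in every bisulfite variant
    probe_by_id = {p.probe_id: p for p in spec.probes}
    dup_truth: dict[str, list[dict]] = {}
    for dup in spec.duplications:
        host = probe_by_id[dup.host_probe_id]
        fp = compute_probe_intervals(
            ProbeRecord(
                probe_id=host.probe_id,
                assay_type=host.assay_type,
                design_strand=host.design_strand,
                chrom=host.chrom,
                mapinfo=host.mapinfo,
                probe_seq_A="A" * PROBE_LENGTH,
                probe_seq_B="A" * PROBE_LENGTH if host.assay_type == "I" else None,
            )
        ).footprint
        arr = arrays[host.chrom]
        mism_offsets = []
        for i in range(2, 2 + dup.n_mismatches):
            g = _probe_index_to_genomic(fp, host.design_strand, i)
            off = g - fp.start
            if arr[g] in ("C", "G"):
                arr[g] = rng.choice(["A", "T"])
            mism_offsets.append(off)
        dup_truth.setdefault(dup.host_probe_id, []).append(
            {
                "chrom": dup.dest_chrom,
                "start": dup.dest_start,
                "end": dup.dest_start + PROBE_LENGTH,
                "n_mismatches": dup.n_mismatches,
                "source": (host.chrom, fp.start, fp.end),
                "offsets": mism_offsets,
            }
        )

    # copy footprints to their duplication destinations, applying A<->T swaps
    swap = {"A": "T", "T": "A"}
    for dup in spec.duplications:
        host = probe_by_id[dup.host_probe_id]
        rec = [d for d in dup_truth[dup.host_probe_id]
               if d["start"] == dup.dest_start and d["chrom"] == dup.dest_chrom][0]
        s_chrom, s_start, s_end = rec["source"]
        copy = arrays[s_chrom][s_start:s_end].copy()
        for off in rec["offsets"]:
            if copy[off] not in swap:
                raise UnsatisfiableSpecError(
                    f"duplication host {dup.host_probe_id}: mismatch base not A/T"
                )
            copy[off] = swap[copy[off]]
        arrays[dup.dest_chrom][dup.dest_start : dup.dest_start + PROBE_LENGTH] = copy

    # soft-mask repeats last so planted letters keep their identity
    for rep in spec.repeats:
        arr = arrays[rep.chrom]
        seg = arr[rep.start : rep.start + rep.length]
        arr[rep.start : rep.start + rep.length] = np.char.lower(seg)

    genome = {chrom: "".join(arr) for chrom, arr in arrays.items()}

    probes = []
    for p in spec.probes:
        chrom_seq = genome[p.chrom]
        c0 = p.mapinfo - 1
        if chrom_seq[c0 : c0 + 2].upper() != "CG":
            raise UnsatisfiableSpecError(
                f"probe {p.probe_id}: target position is not a CpG"
            )
        seq_a, seq_b = expected_probe_sequences(
            chrom_seq, p.assay_type, p.design_strand, p.mapinfo, chrom=p.chrom
        )
        probes.append(
            ProbeRecord(
                probe_id=p.probe_id,
                assay_type=p.assay_type,
                design_strand=p.design_strand,
                chrom=p.chrom,
                mapinfo=p.mapinfo,
                probe_seq_A=seq_a,
                probe_seq_B=seq_b,
            )
        )

    truth = {
        "islands": [
            (i.chrom, i.start, i.start + i.length, i.density_class)
            for i in spec.islands
        ],
        "repeats": [(r.chrom, r.start, r.start + r.length) for r in spec.repeats],
        "duplications": dup_truth,
    }
    return Fixture(spec=spec, genome=genome, probes=probes, truth=truth)


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The standard desk-scale fixture.

    chr1 (60 kb) carries: an HC island with an abutting IC tail (expected
    ICshore), an isolated IC island, a soft-masked repeat tract, twenty
    validation probes covering all four type x strand combinations, probes
    pinned to each HIL and UCSC class, duplication decoys at 42/50 and
    39/50 identity, and an exact cross-chromosome copy in each direction
    between chr1 and chrX.
    """
    probes: list[ProbeSpec] = []
    # 20 validation probes: 10 type I then 10 type II, alternating F/R
    for i in range(20):
        assay = "I" if i < 10 else "II"
        strand = "F" if i % 2 == 0 else "R"
        probes.append(
            ProbeSpec(
                probe_id=f"cg2{i:06d}",
                assay_type=assay,
                design_strand=strand,
                chrom="chr1",
                mapinfo=1001 + 120 * i,
                plant_internal_cpg=(assay == "II" and i in (12, 15)),
            )
        )
    # CpG-class probes
    probes += [
        ProbeSpec("cg3000001", "II", "F", "chr1", 5301),   # inside HC
        ProbeSpec("cg3000002", "II", "F", "chr1", 5751),   # inside IC tail -> ICshore
        ProbeSpec("cg3000003", "II", "F", "chr1", 20151),  # isolated IC
        ProbeSpec("cg3000004", "II", "F", "chr1", 21300),  # ~1 kb off island -> shore
        ProbeSpec("cg3000005", "II", "F", "chr1", 22801),  # ~2.5 kb -> shelf
        ProbeSpec("cg3000006", "II", "F", "chr1", 27001),  # far -> sea / LC
    ]
    # specificity probes
    probes += [
        ProbeSpec("cg4000001", "I", "F", "chr1", 10001),   # 42/50 decoy host
        ProbeSpec("cg4000002", "I", "F", "chr1", 12001),   # 39/50 decoy host
        ProbeSpec("cg4000003", "II", "F", "chr1", 13001),  # exact copy on chrX
        ProbeSpec("cg4000004", "II", "F", "chr1", 14001, plant_internal_cpg=True),
        ProbeSpec("cg4100001", "II", "F", "chrX", 5001),   # exact copy on chr1
        ProbeSpec("cg4100002", "II", "F", "chrX", 4001),   # plain sex-chrom probe
    ]
    # repeat probes: footprint fully / partially inside the masked tract
    probes += [
        ProbeSpec("cg5000001", "II", "F", "chr1", 30055),
        ProbeSpec("cg5000002", "II", "F", "chr1", 30081),
    ]
    # gene-demo probes (target Cs at gene-space positions 1000/5000/9000)
    probes += [
        ProbeSpec("cg6000001", "II", "F", "chr1", 41001),
        ProbeSpec("cg6000002", "II", "F", "chr1", 45001),
        ProbeSpec("cg6000003", "II", "F", "chr1", 49001),
    ]
    return FixtureSpec(
        seed=seed,
        islands=[
            IslandSpec("chr1", 5000, 600, "HC", gc=0.62),
            IslandSpec("chr1", 5601, 300, "IC", gc=0.60),
            IslandSpec("chr1", 20000, 300, "IC", gc=0.60),
        ],
        repeats=[RepeatSpec("chr1", 30000, 60)],
        probes=probes,
        duplications=[
            DuplicationSpec("cg4000001", "chr1", 15000, n_mismatches=8),
            DuplicationSpec("cg4000002", "chr1", 16000, n_mismatches=11),
            DuplicationSpec("cg4000003", "chrX", 2000, n_mismatches=0),
            DuplicationSpec("cg4100001", "chr1", 55000, n_mismatches=0),
        ],
    )


#: expected classifications for the pinned class probes of the default fixture
DEFAULT_EXPECTED_CLASSES = {
    "cg3000001": {"hil": "HC", "ucsc": "island"},
    "cg3000002": {"hil": "ICshore", "ucsc": "island"},
    "cg3000003": {"hil": "IC", "ucsc": "island"},
    "cg3000004": {"hil": "LC", "ucsc": "shore"},
    "cg3000005": {"hil": "LC", "ucsc": "shelf"},
    "cg3000006": {"hil": "LC", "ucsc": "sea"},
}


# ---------------------------------------------------------------------------
# gene model fixture (five-transcript demo gene)
# ---------------------------------------------------------------------------

def demo_gene_models(
    chrom: str = "chr1", offset: int = 40_000
) -> tuple[list[GeneModel], dict[str, int]]:
    """A five-transcript plus-strand gene exercising all nine features.

    Returns the transcript models and the three canonical probe positions
    (0-based target-C coordinates) named "i", "ii" and "iii".
    """

    def gm(tx_id, tx, cds, exons):
        starts, ends = zip(*exons)
        return GeneModel(
            gene_name="DEMO1",
            transcript_id=tx_id,
            chrom=chrom,
            strand="+",
            tx_start=offset + tx[0],
            tx_end=offset + tx[1],
            cds_start=offset + cds[0],
            cds_end=offset + cds[1],
            exon_starts=tuple(offset + s for s in starts),
            exon_ends=tuple(offset + e for e in ends),
        )

    models = [
        gm("TX_A", (200, 9300), (4000, 8000),
           [(200, 400), (900, 1200), (4800, 5200), (8800, 9300)]),
        gm("TX_B", (900, 9500), (6600, 8500),
           [(900, 1200), (5500, 5800), (6500, 8700), (9200, 9500)]),
        gm("TX_C", (300, 9500), (2550, 5650),
           [(300, 600), (2500, 2700), (5500, 5700), (8800, 9500)]),
        gm("TX_D", (4500, 9300), (4600, 8000),
           [(4500, 5200), (8800, 9300)]),
        gm("TX_E", (8600, 9500), (8650, 8900),
           [(8600, 9100), (9200, 9500)]),
    ]
    positions = {"i": offset + 1000, "ii": offset + 5000, "iii": offset + 9000}
    return models, positions


#: transcript-level labels the demo gene must yield at each probe position
DEMO_GENE_EXPECTED = {
    "i": ["5'UTR exon", "5'UTR first exon", "5'UTR intron"],
    "ii": ["body exon", "5'UTR intron", "body intron", "body first exon"],
    "iii": ["3'UTR exon", "3'UTR intron", "3'UTR exon", "3'UTR exon",
            "3'UTR first exon"],
}


def mirror_gene_model(model: GeneModel, pivot: int) -> GeneModel:
    """Reflect a gene model through *pivot* and flip its strand."""
    def refl(x: int) -> int:
        return 2 * pivot - x

    exon_pairs = sorted(
        (refl(e), refl(s)) for s, e in zip(model.exon_starts, model.exon_ends)
    )
    return GeneModel(
        gene_name=model.gene_name,
        transcript_id=model.transcript_id + "_mirror",
        chrom=model.chrom,
        strand="-" if model.strand == "+" else "+",
        tx_start=refl(model.tx_end),
        tx_end=refl(model.tx_start),
        cds_start=refl(model.cds_end),
        cds_end=refl(model.cds_start),
        exon_starts=tuple(s for s, _ in exon_pairs),
        exon_ends=tuple(e for _, e in exon_pairs),
    )


# ---------------------------------------------------------------------------
# SNP fixture
# ---------------------------------------------------------------------------

def gen_snps_for_probes(
    probes: Sequence[ProbeRecord], seed: int = 0
) -> tuple[list[SnpRecord], dict[str, dict]]:
    """Plant SNPs at known positions relative to each cg probe.

    Cycles through four scenarios: SNP at the target C, at the G, within
    10 bp of the CpG inside the footprint, and deeper inside the footprint.
    Returns the SNP list and per-probe truth.
    """
    rng = np.random.default_rng(seed)
    snps: list[SnpRecord] = []
    truth: dict[str, dict] = {}
    k = 0
    for probe in probes:
        if probe.category != "cg":
            continue
        fp = compute_probe_intervals(probe).footprint
        scenario = k % 5
        k += 1
        entry = {"target": [], "lt10": [], "gt10": []}
        if scenario in (0, 3):
            pos = probe.mapinfo
            het = float(rng.choice([0.0, 0.05, 0.3]))
            rs = f"rs{10_000 + k}"
            snps.append(SnpRecord(rs, probe.chrom, pos, 1, het if het > 0 else None))
            entry["target"].append(rs)
        if scenario in (1, 3):
            rs = f"rs{20_000 + k}"  # SNP at the G of the target CpG
            snps.append(SnpRecord(rs, probe.chrom, probe.mapinfo + 1, 1, 0.2))
            entry["target"].append(rs)
        if scenario == 2:
            # 5 bp from the CpG, inside the footprint
            if probe.design_strand == "F":
                pos = probe.mapinfo - 5
            else:
                pos = probe.mapinfo + 6
            rs = f"rs{30_000 + k}"
            snps.append(SnpRecord(rs, probe.chrom, pos, 1, 0.1))
            entry["lt10"].append(rs)
        if scenario == 4:
            # deep inside the footprint, far from the CpG
            if probe.design_strand == "F":
                pos = fp.start + 6
            else:
                pos = fp.end - 5
            rs = f"rs{40_000 + k}"
            snps.append(SnpRecord(rs, probe.chrom, pos, 1, 0.4))
            entry["gt10"].append(rs)
        truth[probe.probe_id] = entry
    return snps, truth


# ---------------------------------------------------------------------------
# beta-matrix fixture
# ---------------------------------------------------------------------------

@dataclass
class BetaProbeModel:
    probe_id: str
    kind: str = "null"  # null | trimodal | tissue_diff | sex_diff
    snp_class: str = "none"  # none | target | lt10 | gt10
    mean: float = 0.5
    noise_sd: float = 0.05
    tissue_means: dict[str, float] | None = None
    allele_freq: float = 0.5
    centers: tuple[float, float, float] = (0.05, 0.5, 0.95)
    sex_delta: float = 0.0


@dataclass
class BetaSpec:
    samples: list[tuple[str, str, str]]  # (sample_id, tissue, sex)
    probes: list[BetaProbeModel]


def gen_beta(spec: BetaSpec, seed: int = 0) -> tuple[BetaMatrix, pd.DataFrame]:
    """Simulate a beta matrix with planted truth labels.

    Noise is truncated-normal on [0, 1].  Trimodal probes draw genotypes
    under Hardy-Weinberg at the declared allele frequency and centre the
    three genotype groups at the declared levels.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [s for s, _, _ in spec.samples]
    tissues = pd.Series({s: t for s, t, _ in spec.samples})
    sexes = pd.Series({s: x for s, _, x in spec.samples})
    n = len(sample_ids)
    is_male = np.array([x == "M" for _, _, x in spec.samples])
    tissue_of = [t for _, t, _ in spec.samples]

    means = np.empty((len(spec.probes), n))
    sds = np.empty((len(spec.probes), 1))
    truth_rows = []
    for j, pm in enumerate(spec.probes):
        if pm.kind == "trimodal":
            q = 1.0 - pm.allele_freq
            geno = rng.choice(
                3, size=n, p=[q * q, 2 * pm.allele_freq * q,
                              pm.allele_freq * pm.allele_freq]
            )
            means[j] = np.asarray(pm.centers)[geno]
        elif pm.kind == "tissue_diff":
            assert pm.tissue_means is not None
            means[j] = [pm.tissue_means[t] for t in tissue_of]
        elif pm.kind == "sex_diff":
            means[j] = pm.mean + np.where(is_male, pm.sex_delta, 0.0)
        else:
            means[j] = pm.mean
        sds[j, 0] = pm.noise_sd
        truth_rows.append(
            {
                "probe_id": pm.probe_id,
                "kind": pm.kind,
                "snp_class": pm.snp_class,
                "noise_sd": pm.noise_sd,
            }
        )
    means = np.clip(means, 0.0, 1.0)
    scale = np.broadcast_to(sds, means.shape)
    a = (0.0 - means) / scale
    b = (1.0 - means) / scale
    rows = sps.truncnorm.rvs(a, b, loc=means, scale=scale, size=means.shape,
                             random_state=rng)
    values = pd.DataFrame(rows, index=[p.probe_id for p in spec.probes],
                          columns=sample_ids)
    truth = pd.DataFrame(truth_rows).set_index("probe_id")
    return BetaMatrix(values=values, tissue=tissues, sex=sexes), truth


def snp_demo_beta_spec(
    n_probes: int = 2000,
    n_samples: int = 24,
    frac_target: float = 0.20,
    frac_lt10: float = 0.10,
    frac_gt10: float = 0.10,
    seed: int = 0,
) -> BetaSpec:
    """Beta model mirroring the SNP-confound scenario.

    Target-CpG-SNP probes are genotype-trimodal; the proximity classes and
    the background draw per-probe noise SDs from a spread wide enough that
    a representative fraction survives the SD >= 0.10 screen.
    """
    rng = np.random.default_rng(seed)
    samples = [(f"s{i:03d}", "blood", "M" if i % 2 else "F")
               for i in range(n_samples)]
    n_target = int(n_probes * frac_target)
    n_lt10 = int(n_probes * frac_lt10)
    n_gt10 = int(n_probes * frac_gt10)
    probes = []
    for j in range(n_probes):
        pid = f"cg{j:07d}"
        if j < n_target:
            probes.append(
                BetaProbeModel(pid, kind="trimodal", snp_class="target",
                               noise_sd=0.02)
            )
        else:
            if j < n_target + n_lt10:
                snp_class = "lt10"
            elif j < n_target + n_lt10 + n_gt10:
                snp_class = "gt10"
            else:
                snp_class = "none"
            probes.append(
                BetaProbeModel(
                    pid,
                    kind="null",
                    snp_class=snp_class,
                    mean=float(rng.choice([0.1, 0.5, 0.9])),
                    noise_sd=float(rng.uniform(0.02, 0.18)),
                )
            )
    return BetaSpec(samples=samples, probes=probes)


def tdm_beta_spec(
    n_probes: int = 1000,
    n_planted: int = 50,
    n_per_tissue: int = 4,
    delta: float = 0.3,
    noise_sd: float = 0.05,
    base_mean: float = 0.3,
) -> BetaSpec:
    """Two-tissue beta model with planted between-tissue differences."""
    samples = [(f"b{i}", "blood", "F") for i in range(n_per_tissue)]
    samples += [(f"v{i}", "villi", "M") for i in range(n_per_tissue)]
    probes = []
    for j in range(n_probes):
        pid = f"cg{j:07d}"
        if j < n_planted:
            probes.append(
                BetaProbeModel(
                    pid, kind="tissue_diff", noise_sd=noise_sd,
                    tissue_means={"blood": base_mean, "villi": base_mean + delta},
                )
            )
        else:
            probes.append(BetaProbeModel(pid, kind="null", mean=base_mean,
                                         noise_sd=noise_sd))
    return BetaSpec(samples=samples, probes=probes)


def sex_beta_spec(
    n_probes: int = 1000,
    n_planted: int = 50,
    n_per_sex: int = 50,
    delta: float = 0.2,
    noise_sd: float = 0.03,
    base_mean: float = 0.4,
) -> BetaSpec:
    """Single-tissue beta model with planted sex differences."""
    samples = [(f"m{i}", "blood", "M") for i in range(n_per_sex)]
    samples += [(f"f{i}", "blood", "F") for i in range(n_per_sex)]
    probes = []
    for j in range(n_probes):
        pid = f"cg{j:07d}"
        if j < n_planted:
            probes.append(
                BetaProbeModel(pid, kind="sex_diff", mean=base_mean,
                               sex_delta=delta, noise_sd=noise_sd)
            )
        else:
            probes.append(BetaProbeModel(pid, kind="null", mean=base_mean,
                                         noise_sd=noise_sd))
    return BetaSpec(samples=samples, probes=probes)
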