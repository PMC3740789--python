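"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes results from first principles (exhaustive scans,
quadratic intersection, direct ECDF arithmetic) without going through the
code paths under test.
"""

from __future__ import annotations

import numpy as np

PROBE_LEN = 50

_RC = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _bisulfite(seq: str, meth: bool) -> str:
    out = []
    n = len(seq)
    for i, b in enumerate(seq):
        if b in "Cc":
            nxt = seq[i + 1] if i + 1 < n else "N"
            if meth and nxt in "Gg":
                out.append(b)
            else:
                out.append("T" if b == "C" else "t")
        else:
            out.append(b)
    return "".join(out)


def build_variants_oracle(genome: dict[str, str]) -> dict[str, dict[str, str]]:
    out = {}
    for name, meth, rev in (
        ("unmeth_fwd", False, False),
        ("meth_fwd", True, False),
        ("unmeth_rev", False, True),
        ("meth_rev", True, True),
    ):
        out[name] = {
            chrom: _bisulfite(_rc(seq) if rev else seq, meth)
            for chrom, seq in genome.items()
        }
    return out


def _version_seqs(probe) -> list[str]:
    seqs = []
    for s in (probe.probe_seq_A, probe.probe_seq_B):
        if s is None:
            continue
        if "R" in s:
            seqs.append(s.replace("R", "A"))
            seqs.append(s.replace("R", "G"))
        else:
            seqs.append(s)
    return seqs


def oracle_accepted_loci(
    probe,
    variants: dict[str, dict[str, str]],
    min_matches: int = 40,
    min_identity: float = 0.90,
) -> set[tuple[str, int, int]]:
    """Exhaustive all-offsets scan across variants and both orientations.

    Every full-length placement is scored with the 3'-anchored best-suffix
    extent (vectorized cumulative sums); accepted placements are mapped to
    genomic footprints and unioned.  Partial (contig-edge) placements are
    ignored: they cannot satisfy the match minimum on these fixtures.
    """
    loci: set[tuple[str, int, int]] = set()
    for vname, chroms in variants.items():
        for chrom, seq in chroms.items():
            t = np.frombuffer(seq.upper().encode(), np.uint8)
            length = len(t)
            n_off = length - PROBE_LEN + 1
            if n_off <= 0:
                continue
            for qseq in _version_seqs(probe):
                for orient in ("-", "+"):
                    q = _rc(qseq) if orient == "-" else qseq
                    qa = np.frombuffer(q.upper().encode(), np.uint8)
                    match = np.empty((n_off, PROBE_LEN), dtype=bool)
                    for i in range(PROBE_LEN):
                        match[:, i] = t[i : i + n_off] == qa[i]
                    if orient == "-":
                        match = match[:, ::-1]  # probe order
                    sgn = np.where(match, 1, -1)
                    suffix_score = np.cumsum(sgn[:, ::-1], axis=1)[:, ::-1]
                    suffix_match = np.cumsum(match[:, ::-1], axis=1)[:, ::-1]
                    t_best = np.argmax(suffix_score, axis=1)
                    rows = np.arange(n_off)
                    matches = suffix_match[rows, t_best]
                    aligned = PROBE_LEN - t_best
                    ok = (matches >= min_matches) & (
                        matches / aligned >= min_identity
                    )
                    for o in np.flatnonzero(ok):
                        o = int(o)
                        if vname.endswith("_rev"):
                            loci.add((chrom, length - (o + PROBE_LEN), length - o))
                        else:
                            loci.add((chrom, o, o + PROBE_LEN))
    return loci


def all_windows_island_bases(
    seq: str, min_gc: float, min_oe: float, min_len: int
) -> set[int]:
    """Union of bases of every window satisfying the island thresholds."""
    s = seq.upper()
    n = len(s)
    arr = np.frombuffer(s.encode(), np.uint8)
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_n = np.concatenate(
        [[0], np.cumsum(~np.isin(arr, np.frombuffer(b"ACGT", np.uint8)))]
    )
    cpg = np.zeros(n, dtype=np.int64)
    for i in range(n - 1):
        if s[i] == "C" and s[i + 1] == "G":
            cpg[i] = 1
    cum_cpg = np.concatenate([[0], np.cumsum(cpg)])
    bases: set[int] = set()
    for start in range(n):
        for end in range(start + min_len + 1, n + 1):
            if is_n[end] - is_n[start] > 0:
                break  # any longer window from this start also contains the N
            length = end - start
            n_c = is_c[end] - is_c[start]
            n_g = is_g[end] - is_g[start]
            if (n_c + n_g) / length <= min_gc:
                continue
            if n_c == 0 or n_g == 0:
                continue
            n_cpg = cum_cpg[start:end - 1].sum() if end - 1 > start else 0
            if n_cpg * length / (n_c * n_g) > min_oe:
                bases.update(range(start, end))
    return bases


def quadratic_target_snp_scan(probes, snps) -> dict[str, list[str]]:
    """O(probes x snps) scan for SNPs at the C or G of each cg probe."""
    out: dict[str, list[str]] = {}
    for p in probes:
        if not p.probe_id.startswith("cg"):
            continue
        found = []
        for s in snps:
            if s.chrom == p.chrom and s.pos in (p.mapinfo, p.mapinfo + 1):
                found.append(s.rs_id)
        out[p.probe_id] = sorted(set(found))
    return out


def vectorised_target_snp_scan(probes, snps) -> dict[str, list[str]]:
    """Brute-force scan at acceptance scale: per probe, test every SNP
    position directly (no hashing/indexing), vectorized over the SNP list."""
    chroms = sorted({s.chrom for s in snps})
    code = {c: i for i, c in enumerate(chroms)}
    snp_chrom = np.array([code[s.chrom] for s in snps])
    snp_pos = np.array([s.pos for s in snps])
    rs = np.array([s.rs_id for s in snps])
    out: dict[str, list[str]] = {}
    for p in probes:
        if not p.probe_id.startswith("cg"):
            continue
        if p.chrom not in code:
            out[p.probe_id] = []
            continue
        mask = (snp_chrom == code[p.chrom]) & (
            (snp_pos == p.mapinfo) | (snp_pos == p.mapinfo + 1)
        )
        out[p.probe_id] = sorted(set(rs[mask].tolist()))
    return out


def ks_two_sample_oracle(x, y) -> float:
    """Two-sample KS D from direct ECDF evaluation on the pooled support."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    support = np.concatenate([x, y])
    fx = np.searchsorted(x, support, side="right") / len(x)
    fy = np.searchsorted(y, support, side="right") / len(y)
    return float(np.abs(fx - fy).max())


def brute_force_feature_label(model, pos: int) -> str | None:
    """Independent per-base gene-feature labeling."""
    if not (model.tx_start <= pos < model.tx_end):
        return None
    exons = list(zip(model.exon_starts, model.exon_ends))
    in_exon = None
    for i, (s, e) in enumerate(exons):
        if s <= pos < e:
            in_exon = i
            break
    first = 0 if model.strand == "+" else len(exons) - 1
    if in_exon is None:
        comp = "intron"
    elif in_exon == first:
        comp = "first exon"
    else:
        comp = "exon"
    if model.cds_start == model.cds_end:
        region = "body"
    elif pos < model.cds_start:
        region = "5'UTR" if model.strand == "+" else "3'UTR"
    elif pos >= model.cds_end:
        region = "3'UTR" if model.strand == "+" else "5'UTR"
    else:
        region = "body"
    return f"{region} {comp}"
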