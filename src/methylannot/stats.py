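"""Methylation-matrix statistics.

Covers the downstream computations on probes-by-samples beta matrices:
beta/M transforms, within-group variability screening, methylation level
categories, distribution comparisons (two-sample KS), differential
methylation between tissues (z-score with Bonferroni control), class
enrichment of differential probes, and a sex-difference screen (moderated
two-sample test + Benjamini-Hochberg as a documented stand-in for SAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

BETA_CLAMP_EPS = float(np.finfo(float).eps)


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with sample metadata."""

    values: pd.DataFrame  # rows: probe ids, columns: sample ids
    tissue: pd.Series  # sample id -> tissue label
    sex: pd.Series | None = None  # sample id -> "M"/"F"

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if not set(self.values.columns) <= set(self.tissue.index):
            raise ValueError("every sample needs a tissue label")

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)], self.tissue, self.sex)

    def tissues(self) -> list[str]:
        return sorted(self.tissue.loc[self.values.columns].unique())

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.tissue[s] == tissue]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def m_from_intensities(intensity_m, intensity_u):
    """M = log2((methylated intensity + 1) / (unmethylated intensity + 1))."""
    m = np.asarray(intensity_m, dtype=float)
    u = np.asarray(intensity_u, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    return np.log2((m + 1.0) / (u + 1.0))


def beta_from_m(m):
    """beta = 2^M / (2^M + 1); strictly increasing with M."""
    m = np.asarray(m, dtype=float)
    # equivalent to the logistic of M*ln2, stable for large |M|
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    out[~pos] = np.exp2(m[~pos]) / (1.0 + np.exp2(m[~pos]))
    return out if out.ndim else float(out)


def m_from_beta(beta, clamp_eps: float = BETA_CLAMP_EPS):
    """M = log2(beta / (1 - beta)); beta in {0,1} is clamped by clamp_eps."""
    b = np.asarray(beta, dtype=float)
    if (b < 0).any() or (b > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, clamp_eps, 1.0 - clamp_eps)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# variability
# ---------------------------------------------------------------------------

def within_group_sd(matrix: BetaMatrix) -> pd.DataFrame:
    """Per-probe sample SD (n-1 denominator) within each tissue group.

    Groups with fewer than two samples yield NaN.
    """
    out = {}
    for tissue in matrix.tissues():
        cols = matrix.samples_of(tissue)
        if len(cols) < 2:
            out[tissue] = pd.Series(np.nan, index=matrix.values.index)
        else:
            out[tissue] = matrix.values[cols].std(axis=1, ddof=1)
    return pd.DataFrame(out)


def flag_highly_variable(sds: pd.Series, threshold: float = 0.25) -> pd.Series:
    """SD >= threshold (boundary inclusive)."""
    return sds >= threshold


SD_REMOVAL_CUTOFF = 0.10


def sd_distribution_compare(
    sds: pd.Series,
    probe_classes: Mapping[str, set[str]],
    removal_cutoff: float = SD_REMOVAL_CUTOFF,
) -> dict[str, tuple[float, float]]:
    """Two-sample KS of each class's SD distribution against all probes.

    Probes with SD below *removal_cutoff* are removed from every group
    first.  Returns {class: (D, p)}; empty classes are reported as NaN.
    """
    kept = sds[sds >= removal_cutoff].dropna()
    all_values = kept.to_numpy()
    results: dict[str, tuple[float, float]] = {}
    for cls, probe_ids in probe_classes.items():
        values = kept[kept.index.isin(probe_ids)].to_numpy()
        if values.size == 0 or all_values.size == 0:
            results[cls] = (float("nan"), float("nan"))
            continue
        res = sps.ks_2samp(values, all_values, method="asymp")
        results[cls] = (float(res.statistic), float(res.pvalue))
    return results


# ---------------------------------------------------------------------------
# methylation levels
# ---------------------------------------------------------------------------

def methylation_level(mean_beta: float) -> str:
    """hypo (<=0.2), hetero (0.2, 0.8) or hyper (>=0.8)."""
    if not 0 <= mean_beta <= 1:
        raise ValueError("mean beta outside [0, 1]")
    if mean_beta <= 0.2:
        return "hypo"
    if mean_beta >= 0.8:
        return "hyper"
    return "hetero"


def methylation_levels(mean_betas: pd.Series) -> pd.Series:
    bins = pd.Series("hetero", index=mean_betas.index)
    bins[mean_betas <= 0.2] = "hypo"
    bins[mean_betas >= 0.8] = "hyper"
    return bins


# ---------------------------------------------------------------------------
# tissue differential methylation
# ---------------------------------------------------------------------------

@dataclass
class TdmResult:
    probe_id: str
    delta_mean: float
    z: float
    p: float
    significant: bool


def select_tdm(
    matrix: BetaMatrix,
    tissue_a: str,
    tissue_b: str,
    alpha: float = 0.05,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-probe z-score between two tissues with Bonferroni control.

    z = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with a two-sided
    normal tail; the pooled-variance alternative uses a common variance
    estimate.  A probe is significant when p < alpha / n_probes.
    """
    cols_a = matrix.samples_of(tissue_a)
    cols_b = matrix.samples_of(tissue_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least two samples per tissue")
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if pooled:
        pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        se = np.sqrt(pooled_var * (1 / na + 1 / nb))
    else:
        se = np.sqrt(var_a / na + var_b / nb)
    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / np.where(se > 0, se, 1.0), np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    p = 2.0 * sps.norm.sf(np.abs(z))
    n_tests = len(matrix.values.index)
    significant = p < alpha / n_tests
    return pd.DataFrame(
        {
            "delta_mean": delta,
            "z": z,
            "p": p,
            "significant": significant,
        },
        index=matrix.values.index,
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    class_label: str
    pct_relative_enrichment: float
    p: float
    n_class: int
    n_class_tdm: int


def relative_enrichment(
    tdm_flags: pd.Series,
    class_labels: pd.Series,
    significance_threshold: float = 1.0e-7,
) -> list[EnrichmentResult]:
    """Signed percentage enrichment of differential probes per class.

    PRE(class) = 100 * (f_tdm(class) - f_all(class)) / f_all(class), where
    f is the fraction of probes carrying the class within the respective
    set.  The tail probability is hypergeometric (differential set vs class
    membership), taken in the direction of the observed effect.
    """
    common = tdm_flags.index.intersection(class_labels.index)
    flags = tdm_flags.loc[common].astype(bool)
    labels = class_labels.loc[common]
    n_total = len(common)
    n_tdm = int(flags.sum())
    results = []
    for cls in sorted(labels.unique()):
        in_class = labels == cls
        n_class = int(in_class.sum())
        k = int((in_class & flags).sum())
        f_all = n_class / n_total
        if n_tdm == 0 or f_all == 0:
            results.append(EnrichmentResult(cls, float("nan"), float("nan"), n_class, k))
            continue
        f_tdm = k / n_tdm
        pre = 100.0 * (f_tdm - f_all) / f_all
        hg = sps.hypergeom(n_total, n_class, n_tdm)
        if f_tdm >= f_all:
            p = float(hg.sf(k - 1))
        else:
            p = float(hg.cdf(k))
        results.append(EnrichmentResult(cls, pre, p, n_class, k))
    return results


# ---------------------------------------------------------------------------
# sex differences
# ---------------------------------------------------------------------------

def sex_differential(
    matrix: BetaMatrix,
    fdr: float = 0.01,
    min_delta: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Probes with sex-differential methylation.

    Welch's two-sample test on M values with Benjamini-Hochberg FDR,
    intersected with an absolute difference in mean beta >= min_delta.
    This is a stand-in for the published SAM-based screen and is tagged
    as such in the returned metadata.
    """
    if matrix.sex is None:
        raise ValueError("sample sex labels are required")
    sexes = matrix.sex.loc[matrix.values.columns]
    groups = sorted(sexes.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two sexes, got {groups}")
    cols_a = [s for s in matrix.values.columns if sexes[s] == groups[0]]
    cols_b = [s for s in matrix.values.columns if sexes[s] == groups[1]]
    beta = matrix.values.to_numpy(dtype=float)
    m_vals = m_from_beta(beta)
    a = m_vals[:, [matrix.values.columns.get_loc(c) for c in cols_a]]
    b = m_vals[:, [matrix.values.columns.get_loc(c) for c in cols_b]]
    t_res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.nan_to_num(t_res.pvalue, nan=1.0)
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    beta_a = matrix.values[cols_a].mean(axis=1)
    beta_b = matrix.values[cols_b].mean(axis=1)
    delta = (beta_a - beta_b).abs()
    table = pd.DataFrame(
        {
            "p": pvals,
            "q": qvals,
            "fdr_pass": reject,
            "delta_beta": delta,
            "selected": reject & (delta.to_numpy() >= min_delta),
        },
        index=matrix.values.index,
    )
    meta = {
        "method": "standin",
        "test": "welch-t-on-M",
        "fdr_method": "benjamini-hochberg",
        "fdr": fdr,
        "min_delta": min_delta,
        "groups": groups,
    }
    return table, meta


# ---------------------------------------------------------------------------
# probe prefilter
# ---------------------------------------------------------------------------

@dataclass
class PrefilterLog:
    removed_detection_p: int = 0
    removed_missing_beta: int = 0
    removed_rs_ch: int = 0
    removed_sex_chrom: int = 0
    removed_non_specific: int = 0
    kept: int = 0
    skipped_rules: list[str] = field(default_factory=list)


def prefilter_probes(
    matrix: BetaMatrix,
    detection_p: pd.DataFrame | None = None,
    probe_chrom: Mapping[str, str] | None = None,
    non_specific: Mapping[str, bool] | None = None,
    sex_chroms: set[str] = frozenset({"chrX", "chrY", "X", "Y"}),
    detection_cutoff: float = 0.01,
) -> tuple[BetaMatrix, PrefilterLog]:
    """Apply the standard probe-removal rules, logging counts per rule.

    Rules: detection p > cutoff in any sample; missing beta in any sample;
    rs/ch probes; sex-chromosome probes; non-specific probes.  Rules whose
    inputs are absent are skipped and noted in the log.
    """
    log_ = PrefilterLog()
    keep = pd.Series(True, index=matrix.values.index)

    if detection_p is not None:
        bad = (detection_p.loc[matrix.values.index] > detection_cutoff).any(axis=1)
        log_.removed_detection_p = int((keep & bad).sum())
        keep &= ~bad
    else:
        log_.skipped_rules.append("detection_p")

    missing = matrix.values.isna().any(axis=1)
    log_.removed_missing_beta = int((keep & missing).sum())
    keep &= ~missing

    is_rs_ch = matrix.values.index.to_series().str.startswith(("rs", "ch"))
    log_.removed_rs_ch = int((keep & is_rs_ch).sum())
    keep &= ~is_rs_ch

    if probe_chrom is not None:
        on_sex = matrix.values.index.to_series().map(
            lambda p: probe_chrom.get(p) in sex_chroms
        )
        log_.removed_sex_chrom = int((keep & on_sex).sum())
        keep &= ~on_sex
    else:
        log_.skipped_rules.append("sex_chrom")

    if non_specific is not None:
        ns = matrix.values.index.to_series().map(
            lambda p: bool(non_specific.get(p, False))
        )
        log_.removed_non_specific = int((keep & ns).sum())
        keep &= ~ns
    else:
        log_.skipped_rules.append("non_specific")

    log_.kept = int(keep.sum())
    filtered = BetaMatrix(matrix.values[keep], matrix.tissue, matrix.sex)
    return filtered, log_
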