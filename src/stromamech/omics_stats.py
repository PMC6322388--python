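"""Label-free proteomics statistics and the housekeeping-stability check.

The differential-abundance procedure works on LFQ (label-free
quantification) intensity matrices:

1. missing values of each protein are imputed with draws from
   Normal(m/100, (m/100)/100), where m is that protein's non-zero
   observed minimum — a low-abundance imputation reflecting that
   MS dropout is biased toward weak signals;
2. two-tailed unpaired t-tests per protein (equal-variance by default,
   Welch by flag) between the two sample groups;
3. Benjamini-Hochberg FDR adjustment;
4. regulation calls: up/down when significant and the group mean ratio
   exceeds +/-50% (ratio >= 1.5 or <= 1/1.5 by default).

Also provides RPKM normalization and an exact Mann-Whitney stability
check for a housekeeping gene set (e.g. tubulins), plus an LFQ matrix
simulator with MNAR (abundance-dependent) dropout for calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinMatrix",
    "ImputationRule",
    "DifferentialResult",
    "LfqSimParams",
    "impute_missing",
    "differential_abundance",
    "classify_regulation",
    "generate_lfq_matrix",
    "rpkm",
    "housekeeping_stability",
]


@dataclass
class ProteinMatrix:
    """Protein x sample intensities with explicit missingness.

    ``intensities`` is a DataFrame (proteins in rows, samples in columns)
    where missing entries are NaN — never zero. ``groups`` maps each
    sample to one of exactly two group labels.
    """

    intensities: pd.DataFrame
    groups: pd.Series  # indexed by sample id

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if list(self.intensities.columns) != list(self.groups.index):
            self.groups = self.groups.reindex(self.intensities.columns)
        if self.groups.isna().any():
            raise ValueError("every sample column needs a group label")
        observed = self.intensities.to_numpy()
        if np.nanmin(observed, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")

    @property
    def group_labels(self) -> list:
        return sorted(self.groups.unique())

    def samples_in(self, label) -> list:
        return list(self.groups.index[self.groups == label])

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()


@dataclass(frozen=True)
class ImputationRule:
    """Low-abundance imputation: Normal(m/mean_divisor, mean/sd_divisor).

    With the defaults, a protein whose non-zero observed minimum is m has
    its missing cells drawn from Normal(m/100, m/10000).
    """

    mean_divisor: float = 100.0
    sd_divisor: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_divisor <= 0 or self.sd_divisor <= 0:
            raise ValueError("divisors must be positive")


@dataclass
class ImputationReport:
    n_imputed: int
    n_clipped_negative: int
    dropped_proteins: list = field(default_factory=list)


def impute_missing(
    matrix: ProteinMatrix, rule: ImputationRule = ImputationRule()
) -> tuple[ProteinMatrix, ImputationReport]:
    """Fill missing cells per protein from Normal(m/100, m/10000).

    m is the protein's minimum over observed non-zero intensities, across
    all samples. Observed values are untouched; negative draws (rare at
    SD = mean/100) are clipped to zero and counted. Proteins with no
    observed non-zero value cannot be imputed and are dropped with a
    report entry, never silently.
    """
    rng = np.random.default_rng(rule.seed)
    data = matrix.intensities.copy()
    n_clipped = 0
    n_imputed = 0
    dropped = []
    for pid, row in data.iterrows():
        miss = row.isna()
        if not miss.any():
            continue
        observed = row[~miss]
        nonzero = observed[observed > 0]
        if nonzero.empty:
            dropped.append(pid)
            continue
        m = float(nonzero.min())
        mean = m / rule.mean_divisor
        sd = mean / rule.sd_divisor
        draws = rng.normal(mean, sd, int(miss.sum()))
        n_clipped += int((draws < 0).sum())
        draws = np.clip(draws, 0.0, None)
        n_imputed += draws.size
        data.loc[pid, miss] = draws
    if dropped:
        data = data.drop(index=dropped)
    return (
        ProteinMatrix(intensities=data, groups=matrix.groups),
        ImputationReport(n_imputed=n_imputed, n_clipped_negative=n_clipped,
                         dropped_proteins=dropped),
    )


@dataclass
class DifferentialResult:
    """Per-protein test results and regulation calls.

    ``table`` columns: mean_1, mean_2, fold_change (group2/group1),
    log2fc, t, p, q, call, flag. Calls default to the raw-p gate
    (p < p_threshold and fold change beyond +/-50%); ``call_on_q`` gives
    the same classification under the BH-adjusted q instead.
    """

    table: pd.DataFrame
    group_labels: tuple
    p_threshold: float
    fc_threshold: float
    used_q: bool


def differential_abundance(
    matrix: ProteinMatrix,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    welch: bool = False,
    use_q_for_calls: bool = False,
) -> DifferentialResult:
    """Two-tailed unpaired t-tests with BH FDR over a complete matrix.

    Requires an imputed (NaN-free) matrix and exactly two groups with at
    least two samples each. A protein with zero variance in both groups
    gets p = 1 if the group means are equal, else the smallest positive
    float, and is flagged.
    """
    if matrix.intensities.isna().any().any():
        raise ValueError("matrix contains missing values: impute first")
    labels = matrix.group_labels
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, found {labels}")
    g1_cols = matrix.samples_in(labels[0])
    g2_cols = matrix.samples_in(labels[1])
    if len(g1_cols) < 2 or len(g2_cols) < 2:
        raise ValueError("each group needs >= 2 samples")

    x1 = matrix.intensities[g1_cols].to_numpy(dtype=float)
    x2 = matrix.intensities[g2_cols].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pval = stats.ttest_ind(x2, x1, axis=1, equal_var=not welch)

    degenerate = (v1 == 0) & (v2 == 0)
    tiny = np.finfo(float).tiny
    pval = np.where(degenerate, np.where(m1 == m2, 1.0, tiny), pval)
    tstat = np.where(degenerate & (m1 == m2), 0.0, tstat)
    pval = np.nan_to_num(pval, nan=1.0)

    _, qval, _, _ = multipletests(pval, method="fdr_bh")

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(m1 > 0, m2 / m1, np.inf)
        log2fc = np.log2(fc)

    def make_calls(sig: np.ndarray) -> np.ndarray:
        calls = np.full(fc.shape, "unchanged", dtype=object)
        calls[sig & (fc >= fc_threshold)] = "up"
        calls[sig & (fc <= 1.0 / fc_threshold)] = "down"
        return calls

    gate = qval if use_q_for_calls else pval
    table = pd.DataFrame(
        {
            "mean_1": m1,
            "mean_2": m2,
            "fold_change": fc,
            "log2fc": log2fc,
            "t": tstat,
            "p": pval,
            "q": qval,
            "call": make_calls(gate < p_threshold),
            "call_on_q": make_calls(qval < p_threshold),
            "flag": np.where(degenerate, "zero-variance", ""),
        },
        index=matrix.intensities.index,
    )
    return DifferentialResult(
        table=table,
        group_labels=tuple(labels),
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
        used_q=use_q_for_calls,
    )


def classify_regulation(result: DifferentialResult) -> dict[str, int]:
    """Count up/down/unchanged calls; the counts partition all proteins."""
    counts = result.table["call"].value_counts()
    return {
        "n_up": int(counts.get("up", 0)),
        "n_down": int(counts.get("down", 0)),
        "n_unchanged": int(counts.get("unchanged", 0)),
    }


@dataclass(frozen=True)
class LfqSimParams:
    """Simulator for LFQ matrices with MNAR dropout.

    Protein base abundances are log-normal across proteins
    (log2 mean/SD); per-sample noise is log-normal within protein. A
    fraction of proteins carries a true fold change in group 2. Dropout
    follows a logistic model in log2 abundance:
    P(missing) = sigmoid(intercept + slope * log2_intensity), so a
    negative slope makes weak signals drop out more often (MNAR).
    """

    n_proteins: int = 2000
    n_per_group: int = 6
    log2_abundance_mean: float = 23.0
    log2_abundance_sd: float = 2.0
    log2_noise_sd: float = 0.5
    effect_fraction: float = 0.0
    effect_log2fc: float = 1.0
    dropout_intercept: float = -np.inf  # -inf disables dropout
    dropout_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_per_group < 2:
            raise ValueError("need >= 1 protein and >= 2 samples per group")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.log2_abundance_sd < 0 or self.log2_noise_sd < 0:
            raise ValueError("SDs must be >= 0")


def generate_lfq_matrix(
    params: LfqSimParams,
) -> tuple[ProteinMatrix, pd.Series]:
    """Simulate an LFQ matrix; returns the matrix and true effect labels.

    Labels are +1/-1 for true up/down-regulated proteins (in group 2
    relative to group 1) and 0 for nulls.
    """
    rng = np.random.default_rng(params.seed)
    n, k = params.n_proteins, params.n_per_group
    base = rng.normal(params.log2_abundance_mean, params.log2_abundance_sd, n)

    n_effect = int(round(params.effect_fraction * n))
    labels = np.zeros(n, dtype=int)
    if n_effect:
        idx = rng.choice(n, size=n_effect, replace=False)
        signs = rng.choice([-1, 1], size=n_effect)
        labels[idx] = signs

    log2 = np.empty((n, 2 * k))
    log2[:, :k] = base[:, None] + rng.normal(0, params.log2_noise_sd, (n, k))
    log2[:, k:] = (base + labels * params.effect_log2fc)[:, None] \
        + rng.normal(0, params.log2_noise_sd, (n, k))
    intensities = 2.0 ** log2

    if np.isfinite(params.dropout_intercept):
        logit = params.dropout_intercept + params.dropout_slope * log2
        p_miss = 1.0 / (1.0 + np.exp(-logit))
        intensities = np.where(rng.uniform(size=log2.shape) < p_miss,
                               np.nan, intensities)

    samples = [f"ctrl_{i+1}" for i in range(k)] + [f"treat_{i+1}" for i in range(k)]
    groups = pd.Series(["control"] * k + ["treated"] * k, index=samples)
    proteins = [f"P{i:05d}" for i in range(n)]
    matrix = ProteinMatrix(
        intensities=pd.DataFrame(intensities, index=proteins, columns=samples),
        groups=groups,
    )
    return matrix, pd.Series(labels, index=proteins, name="true_effect")


# --------------------------------------------------------------------------
# RNA-seq side: RPKM and housekeeping stability
# --------------------------------------------------------------------------

def rpkm(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (length * library).

    ``library_sizes`` defaults to the column sums of ``counts``.
    """
    lengths = pd.Series(gene_lengths_bp).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"no length for genes: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    return counts * 1e9 / np.outer(lengths.to_numpy(),
                                   library_sizes.to_numpy())


@dataclass
class HousekeepingStability:
    per_gene_p: pd.Series
    min_p: float
    skipped_genes: list


def housekeeping_stability(
    rpkm_matrix: pd.DataFrame,
    gene_set: list[str],
    groups: pd.Series,
) -> HousekeepingStability:
    """Exact two-sided Mann-Whitney per housekeeping gene between groups.

    Suitable for tiny sample sizes where the exact null distribution of
    the rank-sum statistic matters (3 vs 3 fully separated samples give
    p = 2/20 = 0.1). Genes absent from the matrix are reported as
    skipped, not errors.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    groups = pd.Series(groups).reindex(rpkm_matrix.columns)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, found {labels}")
    g1 = rpkm_matrix.columns[groups == labels[0]]
    g2 = rpkm_matrix.columns[groups == labels[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")

    pvals = {}
    skipped = []
    for gene in gene_set:
        if gene not in rpkm_matrix.index:
            skipped.append(gene)
            continue
        x = rpkm_matrix.loc[gene, g1].to_numpy(dtype=float)
        y = rpkm_matrix.loc[gene, g2].to_numpy(dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        pvals[gene] = float(res.pvalue)
    if not pvals:
        raise ValueError("no gene of the set is present in the matrix")
    per_gene = pd.Series(pvals, name="p")
    return HousekeepingStability(
        per_gene_p=per_gene,
        min_p=float(per_gene.min()),
        skipped_genes=skipped,
    )
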