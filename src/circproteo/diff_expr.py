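"""Two-group differential expression for circRNA and protein layers.

The circRNA layer is junction-read counts normalised to TPM and called
significant at fold change > 2 with p < 0.05; the protein layer is iTRAQ
relative abundances called at fold change > 1.5 with p < 0.05.  Both
thresholds are strict inequalities on the linear ratio, in either
direction, and significance is decided on the raw p-value; Benjamini–
Hochberg q-values are reported alongside.

The test producing per-feature p-values is configurable: Welch's t-test
on log2(x + pseudocount) by default, or the exact Mann-Whitney U test
(the test used for qPCR-style group comparisons, exact by enumeration for
the small 8-vs-7 design).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SHAM = "Sham"
BOO = "BOO"

CIRC_FC_THRESHOLD = 2.0
PROTEIN_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 1.0

#: exact Mann-Whitney enumeration is used up to this pooled sample size
EXACT_MWU_MAX_N = 16


@dataclass
class ExpressionMatrix:
    """Features x samples of non-negative values with two-group labels.

    ``feature_lengths`` (nt) is required only for TPM normalisation of the
    circRNA count layer.
    """

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    groups: pd.Series  # sample id -> {Sham, BOO}
    feature_lengths: pd.Series | None = None

    def __post_init__(self):
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups[self.groups.isna()].index)
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {SHAM, BOO}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups[self.groups == group].index)


def compute_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Length-normalised transcripts-per-million.

    Per sample: rate_i = count_i / length_i(kb); TPM_i = rate_i / sum(rates)
    * 1e6, so every sample column sums to one million.
    """
    if matrix.feature_lengths is None or (matrix.feature_lengths <= 0).any():
        raise ValueError("TPM requires positive feature lengths")
    rates = matrix.values.div(matrix.feature_lengths / 1000.0, axis=0)
    colsums = rates.sum(axis=0)
    if (colsums == 0).any():
        zero = list(colsums[colsums == 0].index)
        raise ValueError(f"all-zero sample columns, TPM undefined: {zero}")
    tpm = rates.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(tpm, matrix.groups.copy(), matrix.feature_lengths)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _mwu_u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #{(i,j): a_i > b_j} + 0.5 #{a_i == b_j}."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Exact by enumeration of every group assignment of the pooled values
    when the pooled size is at most ``EXACT_MWU_MAX_N`` (ties handled by
    the 0.5 convention); normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _mwu_u_statistic(a, b)
    n1, n2 = a.size, b.size
    n = n1 + n2
    if n <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([a, b])
        idx = np.arange(n)
        u_min = min(u_obs, n1 * n2 - u_obs)
        hits = 0
        for pick in combinations(idx, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(pick)] = True
            u = _mwu_u_statistic(pooled[mask], pooled[~mask])
            if u <= u_min + 1e-9 or u >= n1 * n2 - u_min - 1e-9:
                hits += 1
        p = min(1.0, hits / comb(n, n1))
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            .pvalue
        )
    return u_obs, p


def _welch_log_p(a: np.ndarray, b: np.ndarray, pseudocount: float) -> float:
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
        return 1.0
    res = stats.ttest_ind(la, lb, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def de_test(
    matrix: ExpressionMatrix,
    fc_threshold: float,
    alpha: float = DEFAULT_ALPHA,
    test: str = "welch",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature two-group DE calling.

    Returns a DataFrame with columns feature_id, mean_sham, mean_boo,
    log2fc (pseudocounted), p_value, q_value, direction, significant.
    A feature is significant iff its linear fold change strictly exceeds
    ``fc_threshold`` in either direction AND raw p < alpha.
    """
    sham = matrix.samples_in(SHAM)
    boo = matrix.samples_in(BOO)
    if len(sham) < 2 or len(boo) < 2:
        raise ValueError("need at least 2 samples per group")
    vals = matrix.values
    a = vals[sham].to_numpy(dtype=float)
    b = vals[boo].to_numpy(dtype=float)
    mean_sham = a.mean(axis=1)
    mean_boo = b.mean(axis=1)
    log2fc = np.log2((mean_boo + pseudocount) / (mean_sham + pseudocount))

    pvals = np.ones(len(vals))
    for i in range(len(vals)):
        if mean_sham[i] == 0 and mean_boo[i] == 0:
            continue  # constant-zero: p = 1 by convention
        if test == "welch":
            pvals[i] = _welch_log_p(a[i], b[i], pseudocount)
        elif test == "mannwhitney":
            pvals[i] = mann_whitney(a[i], b[i])[1]
        else:
            raise ValueError(f"unknown test {test!r}")
    qvals = bh_fdr(pvals)

    ratio = (mean_boo + pseudocount) / (mean_sham + pseudocount)
    fc_pass = (ratio > fc_threshold) | (ratio < 1.0 / fc_threshold)
    significant = fc_pass & (pvals < alpha)
    zero_both = (mean_sham == 0) & (mean_boo == 0)
    direction = np.where(
        zero_both | (log2fc == 0), "none", np.where(log2fc > 0, "up", "down")
    )
    return pd.DataFrame(
        {
            "feature_id": vals.index,
            "mean_sham": mean_sham,
            "mean_boo": mean_boo,
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "direction": direction,
            "significant": significant,
        }
    ).set_index("feature_id", drop=False)


def de_circ(counts: ExpressionMatrix, **kw) -> pd.DataFrame:
    """circRNA-layer DE: TPM normalisation then the FC>2 / p<0.05 rule."""
    tpm = compute_tpm(counts)
    return de_test(tpm, fc_threshold=CIRC_FC_THRESHOLD, **kw)


def de_protein(abundance: ExpressionMatrix, **kw) -> pd.DataFrame:
    """Protein-layer DE at the FC>1.5 / p<0.05 rule."""
    return de_test(abundance, fc_threshold=PROTEIN_FC_THRESHOLD, **kw)
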