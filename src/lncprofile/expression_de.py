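"""Microarray-style differential expression: quantile normalization,
above-background calling, signed absolute fold change and paired t-tests.

The filter reproduced here is the classic two-condition array workflow:
quantile-normalize linear intensities, require a probe to clear the
background floor in every replicate of at least one condition, compute the
signed absolute fold change of condition means on the linear scale
(+A/N when up, -N/A when down), test per-pair log2 ratios with a paired
Student t-test, and call a probe differential when |FC| >= 5 and p <= 0.05.
No multiple-testing correction enters the call; a Benjamini-Hochberg column
is attached for information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_REF = "N"   # neonatal / reference condition
GROUP_TEST = "A"  # adult / test condition

DEFAULT_FC_THRESHOLD = 5.0
DEFAULT_ALPHA = 0.05
DEFAULT_BACKGROUND_FLOOR = 32.0


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Probe x sample linear intensities with a paired two-group design.

    ``group_of_sample`` maps each sample to "N" or "A"; ``pair_of_sample``
    gives the replicate index pairing N_i with A_i.
    """

    intensities: pd.DataFrame  # probes x samples, linear scale
    group_of_sample: dict[str, str]
    pair_of_sample: dict[str, int]

    def __post_init__(self) -> None:
        samples = list(self.intensities.columns)
        missing = [s for s in samples if s not in self.group_of_sample]
        if missing:
            raise ExpressionError(f"samples without group label: {missing}")
        for g in (GROUP_REF, GROUP_TEST):
            pairs = sorted(self.pair_of_sample[s] for s in self.samples_in(g))
            if pairs != sorted(set(pairs)):
                raise ExpressionError(f"duplicate pair index in group {g}")
        if len(self.samples_in(GROUP_REF)) != len(self.samples_in(GROUP_TEST)):
            raise ExpressionError("unequal replicate counts between groups")
        if self.intensities.isna().any().any():
            raise ExpressionError("missing intensities")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.group_of_sample[s] == group]

    def paired_columns(self) -> list[tuple[str, str]]:
        """(N_i, A_i) sample-name pairs ordered by pair index."""
        by_pair_n = {self.pair_of_sample[s]: s for s in self.samples_in(GROUP_REF)}
        by_pair_a = {self.pair_of_sample[s]: s for s in self.samples_in(GROUP_TEST)}
        if set(by_pair_n) != set(by_pair_a):
            raise ExpressionError("pair indices do not match across groups")
        return [(by_pair_n[i], by_pair_a[i]) for i in sorted(by_pair_n)]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    def with_intensities(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, dict(self.group_of_sample), dict(self.pair_of_sample))


def read_expression_tsv(expr_path, samples_path) -> ExpressionMatrix:
    """Load ``expr.tsv`` (probe_id + sample columns) and its sample sheet."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(
        intensities=expr,
        group_of_sample=sheet["group"].to_dict(),
        pair_of_sample=sheet["pair"].astype(int).to_dict(),
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the mean empirical distribution.

    After the transform every column's sorted values equal the across-column
    mean of sorted values; ties within a column receive the mean of the
    target values their positions span, so within-column ranks are preserved.
    """
    x = m.intensities.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ExpressionError("non-positive intensity; floor the matrix first")
    n_probes, n_samples = x.shape
    if n_samples < 2:
        raise ExpressionError("quantile normalization needs >= 2 samples")
    order = np.argsort(x, axis=0, kind="stable")
    target = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        assigned = np.empty(n_probes)
        i = 0
        while i < n_probes:  # average targets across each tie run
            k = i
            while k + 1 < n_probes and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            assigned[i : k + 1] = target[i : k + 1].mean()
            i = k + 1
        out[idx, j] = assigned
    return m.with_intensities(
        pd.DataFrame(out, index=m.intensities.index, columns=m.intensities.columns)
    )


def call_above_background(
    m: ExpressionMatrix, floor: float = DEFAULT_BACKGROUND_FLOOR
) -> pd.Series:
    """True iff intensity >= floor in ALL replicates of at least one group."""
    x = m.intensities
    flags = None
    for g in (GROUP_REF, GROUP_TEST):
        ok = (x[m.samples_in(g)] >= floor).all(axis=1)
        flags = ok if flags is None else (flags | ok)
    return flags.rename("above_background")


def signed_fold_change(mean_n: float, mean_a: float) -> float:
    """Signed absolute fold change: +A/N when A >= N, else -N/A."""
    if mean_n <= 0 or mean_a <= 0:
        raise ExpressionError("group means must be positive")
    return mean_a / mean_n if mean_a >= mean_n else -mean_n / mean_a


def paired_t_test(n_values: np.ndarray, a_values: np.ndarray) -> float:
    """Two-sided paired Student t-test on log2(A_i) - log2(N_i).

    Returns NaN (a not-computable sentinel) when the per-pair differences
    have zero variance; such probes are excluded from significance calls.
    """
    diffs = np.log2(np.asarray(a_values, float)) - np.log2(np.asarray(n_values, float))
    if diffs.size < 2:
        raise ExpressionError("paired t-test needs >= 2 pairs")
    if np.ptp(diffs) == 0:
        return float("nan")
    res = stats.ttest_rel(np.log2(a_values), np.log2(n_values))
    return float(res.pvalue)


def differential_expression(
    m: ExpressionMatrix,
    floor: float = DEFAULT_BACKGROUND_FLOOR,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
    chrom_of_probe: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run the full per-probe pipeline and return a DE table.

    Columns: mean_N, mean_A, fc_signed, p_value, p_adj_info, regulation,
    above_background (+ chrom when a probe->chromosome map is supplied).
    """
    if normalize:
        m = quantile_normalize(m)
    above = call_above_background(m, floor)
    pairs = m.paired_columns()
    n_cols = [p[0] for p in pairs]
    a_cols = [p[1] for p in pairs]
    n_mat = m.intensities[n_cols].to_numpy(dtype=float)
    a_mat = m.intensities[a_cols].to_numpy(dtype=float)
    mean_n = n_mat.mean(axis=1)
    mean_a = a_mat.mean(axis=1)
    fc = np.where(mean_a >= mean_n, mean_a / mean_n, -mean_n / mean_a)
    diffs = np.log2(a_mat) - np.log2(n_mat)
    constant = np.ptp(diffs, axis=1) == 0
    pvals = np.full(len(mean_n), np.nan)
    if (~constant).any():
        res = stats.ttest_rel(np.log2(a_mat[~constant]), np.log2(n_mat[~constant]), axis=1)
        pvals[~constant] = res.pvalue
    table = pd.DataFrame(
        {
            "mean_N": mean_n,
            "mean_A": mean_a,
            "fc_signed": fc,
            "p_value": pvals,
        },
        index=pd.Index(m.probe_ids, name="probe_id"),
    )
    finite = np.isfinite(pvals)
    p_adj = np.full(len(pvals), np.nan)
    if finite.any():
        p_adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    table["p_adj_info"] = p_adj
    table["above_background"] = above.reindex(table.index).to_numpy()
    table["regulation"] = call_differential(table, fc_threshold, alpha)
    if chrom_of_probe is not None:
        table["chrom"] = [chrom_of_probe.get(p, "NA") for p in table.index]
    return table


def call_differential(
    table: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Regulation labels: up/down require |FC| >= threshold, p <= alpha and
    above-background status; NaN p-values never reach significance."""
    fc = table["fc_signed"]
    sig = (table["p_value"] <= alpha) & table["above_background"] & table["p_value"].notna()
    labels = np.where(
        sig & (fc >= fc_threshold), "up", np.where(sig & (fc <= -fc_threshold), "down", "none")
    )
    return pd.Series(labels, index=table.index, name="regulation")


def de_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts feeding the study-overview table: expressed, differential, up, down."""
    expressed = int(table["above_background"].sum())
    n_up = int((table["regulation"] == "up").sum())
    n_down = int((table["regulation"] == "down").sum())
    return {
        "n_total": int(len(table)),
        "n_expressed": expressed,
        "n_diff": n_up + n_down,
        "n_up": n_up,
        "n_down": n_down,
    }
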