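"""Validation statistics: qPCR relative quantification (2^-ddCt), Spearman
rank concordance between platforms, and Fisher-exact term enrichment with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# qPCR: 2^-ddCt
# ---------------------------------------------------------------------------

def read_qpcr_tsv(path) -> pd.DataFrame:
    """Load a Ct table: target_id, sample_id, group, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    required = {"target_id", "sample_id", "group", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns: {sorted(missing)}")
    if not np.isfinite(df[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValidationError("non-finite Ct values")
    return df


def ddct_fold_change(
    records: pd.DataFrame, target: str, group_test: str, group_ref: str
) -> float:
    """Relative expression of ``target`` in ``group_test`` vs ``group_ref``.

    dCt_g = mean(ct_target - ct_reference) within group g;
    ddCt = dCt_test - dCt_ref; returns 2**(-ddCt). The endogenous-control
    normalization makes the result invariant to uniform reference-Ct shifts.
    """
    sub = records[records["target_id"] == target]
    dct = {}
    for g in (group_test, group_ref):
        rows = sub[sub["group"] == g]
        if rows.empty:
            raise ValidationError(f"no qPCR records for target {target!r} group {g!r}")
        dct[g] = float((rows["ct_target"] - rows["ct_reference"]).mean())
    ddct = dct[group_test] - dct[group_ref]
    return float(2.0 ** (-ddct))


def signed_fc_from_ratio(r: float) -> float:
    """Express a linear expression ratio as a signed absolute fold change."""
    if r <= 0:
        raise ValidationError(f"ratio must be positive, got {r}")
    return r if r >= 1 else -1.0 / r


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman_rho(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and a two-sided p-value.

    For n <= ``exact_max_n`` the p-value is an exact permutation tail
    (fraction of y-orderings with |rho| at least as extreme); above that a
    t-approximation with n-2 degrees of freedom is used. Constant input
    yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)), dtype=float)
        rxc = rx - rx.mean()
        pc = perms - ry.mean()  # every permutation shares the same mean
        denom = np.sqrt((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum())
        rhos = pc @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


# ---------------------------------------------------------------------------
# Fisher-exact enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int            # study genes carrying the term
    n_study: int
    K: int            # background genes carrying the term
    N_background: int
    p_fisher: float   # one-sided over-representation
    p_bh: float


def fisher_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """One-sided over-representation test per term, BH-adjusted.

    ``term_map`` maps gene -> terms; genes without terms are allowed. The
    study set must be a subset of the background. p = P(X >= k) under the
    hypergeometric null; results sorted by (p_fisher, term_id).
    """
    study_set = set(study)
    bg_set = set(background)
    offenders = sorted(study_set - bg_set)
    if offenders:
        raise ValidationError(f"study genes absent from background: {offenders}")
    n_study, n_bg = len(study_set), len(bg_set)
    genes_of_term: dict[str, set[str]] = {}
    for gene in bg_set:
        for term in term_map.get(gene, ()):
            genes_of_term.setdefault(term, set()).add(gene)
    terms = sorted(genes_of_term)
    raw = []
    for term in terms:
        carriers = genes_of_term[term]
        k = len(carriers & study_set)
        K = len(carriers)
        p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_study))
        raw.append((term, k, K, min(1.0, p)))
    if not raw:
        return []
    p_bh = multipletests([r[3] for r in raw], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term, k, n_study, K, n_bg, p, float(adj))
        for (term, k, K, p), adj in zip(raw, p_bh)
    ]
    return sorted(results, key=lambda r: (r.p_fisher, r.term_id))


def read_term_map(path) -> dict[str, list[str]]:
    """TSV with columns gene_id, term_id -> gene -> [terms] mapping."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(str(gene), []).append(str(term))
    return out
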