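"""Rank-based replication of discovery modules in an independent cohort.

A module replicates when its SNPs are collectively high-ranked among the
replication GWAS score statistics. The set test is a Wilcoxon rank-sum of
the module SNPs' statistics against all remaining SNPs — on absolute
values for the default "mixed" alternative (module effects need not share
a direction), signed for "up"/"down"/"either" — exact for small sets,
normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

ALTERNATIVES = ("mixed", "up", "down", "either")


@dataclass
class SetTestResult:
    module: str
    n_set: int
    n_matched: int
    alternative: str
    p: float
    replicated: bool
    testable: bool = True


def gene_set_test(
    set_stats: np.ndarray,
    all_stats: np.ndarray,
    alternative: str = "mixed",
    exact_max_n: int = 10,
) -> float:
    """P-value that the set's statistics are extreme among ``all_stats``.

    ``all_stats`` is the full universe including the set; the set must be a
    strict, non-empty subset. Exact enumeration is used when the set holds
    at most ``exact_max_n`` members.
    """
    if alternative not in ALTERNATIVES:
        raise ConfigurationError(f"alternative must be one of {ALTERNATIVES}")
    set_stats = np.asarray(set_stats, dtype=float)
    all_stats = np.asarray(all_stats, dtype=float)
    if set_stats.size == 0:
        raise DataError("empty SNP set")
    if set_stats.size >= all_stats.size:
        raise DataError("set must be a strict subset of the statistic universe")
    # remove one occurrence of each set statistic from the universe
    rest = all_stats.tolist()
    for v in set_stats:
        try:
            rest.remove(v)
        except ValueError as exc:
            raise DataError("set statistic missing from universe") from exc
    rest = np.asarray(rest)

    if alternative == "mixed":
        x, y_, alt = np.abs(set_stats), np.abs(rest), "greater"
    elif alternative == "up":
        x, y_, alt = set_stats, rest, "greater"
    elif alternative == "down":
        x, y_, alt = set_stats, rest, "less"
    else:  # either
        x, y_, alt = set_stats, rest, "two-sided"
    method = "exact" if set_stats.size <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y_, alternative=alt, method=method,
                             use_continuity=True)
    return float(res.pvalue)


def replicate_modules(
    module_labels: pd.Series,
    replication_gwas: pd.DataFrame,
    modules: list[str] | None = None,
    threshold: float = 0.01,
    alternative: str = "mixed",
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Run the set test for each discovery module against a replication GWAS.

    ``module_labels`` maps snp_id -> module color; SNPs are matched to the
    replication panel by identifier and unmatched SNPs are dropped. A
    module with less than ``min_overlap`` of its SNPs present is marked
    untestable rather than failed. Returns the replication report frame.
    """
    stats_by_id = replication_gwas.set_index("snp_id")["score"]
    universe = stats_by_id.to_numpy(dtype=float)
    if modules is None:
        modules = [m for m in module_labels.unique() if m != "grey"]
    rows = []
    for module in modules:
        ids = module_labels.index[module_labels == module]
        matched = [i for i in ids if i in stats_by_id.index]
        result = SetTestResult(
            module=module,
            n_set=len(ids),
            n_matched=len(matched),
            alternative=alternative,
            p=np.nan,
            replicated=False,
            testable=True,
        )
        if len(ids) == 0 or len(matched) / len(ids) < min_overlap or \
                len(matched) >= universe.size:
            result.testable = False
        else:
            set_stats = stats_by_id.loc[matched].to_numpy(dtype=float)
            result.p = gene_set_test(set_stats, universe, alternative)
            result.replicated = bool(result.p < threshold)
        rows.append(result.__dict__)
    return pd.DataFrame(rows)
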