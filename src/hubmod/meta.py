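"""Cross-dataset meta-analysis of hub test results.

Interaction databases overlap poorly, so the set of dysregulated modules
found with one expression/network combination rarely coincides with the
set found with another.  Two combination rules are provided for hubs
tested in all N combinations:

* Fisher's combined probability test: statistic -2 * sum(ln p_i),
  referred to the upper tail of a chi-square distribution with 2N
  degrees of freedom;
* rank product: the geometric mean of a hub's within-dataset ranks,
  with a permutation null built by independently shuffling each
  dataset's rank column.  A hub consistently ranked near the top gets a
  small combined p.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

DEFAULT_N_NULL = 1000


@dataclass
class MetaResult:
    hub: str
    per_dataset_p: tuple
    per_dataset_rank: tuple
    combined_statistic: float
    combined_p: float
    method: str
    n_datasets: int


def fisher_combined(p_values) -> tuple[float, float]:
    """Fisher's combined test: returns (-2*sum(ln p_i), chi-square 2N
    upper-tail probability).

    Every p_i must lie in (0, 1]; clamping p-values away from zero is
    the caller's responsibility (permutation p-values from this package
    are never zero by construction).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    combined_p = float(chi2.sf(statistic, df=2 * p.size))
    return statistic, combined_p


def rank_product(rank_matrix, n_null: int = DEFAULT_N_NULL,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Rank products and permutation p-values for M hubs x N datasets.

    Each column must be a permutation of 1..M.  RP(h) is the geometric
    mean of hub h's ranks.  The null is built from ``n_null`` shuffles of
    every column; the pooled estimator is
    ``p(h) = (1 + #{null RP <= RP(h)}) / (1 + M * n_null)``.
    """
    ranks = np.asarray(rank_matrix, dtype=np.int64)
    if ranks.ndim != 2:
        raise ValueError("rank matrix must be 2-D (hubs x datasets)")
    m, n = ranks.shape
    expected = np.arange(1, m + 1)
    for j in range(n):
        if not np.array_equal(np.sort(ranks[:, j]), expected):
            raise ValueError(f"column {j} is not a permutation of 1..{m}")
    if n * np.log2(max(m, 2)) > 62:
        raise ValueError("rank products would overflow exact integer "
                         "arithmetic; reduce hubs or datasets")
    # tail counting is done on exact integer rank products, so ties with
    # null values are resolved identically regardless of dataset order
    prod = np.prod(ranks, axis=1)
    rp = prod.astype(float) ** (1.0 / n)
    rng = np.random.default_rng(seed)
    null_prod = np.ones((n_null, m), dtype=np.int64)
    for _ in range(n):
        perms = np.argsort(rng.random((n_null, m)), axis=1) + 1
        null_prod *= perms
    null_sorted = np.sort(null_prod.ravel())
    n_le = np.searchsorted(null_sorted, prod, side="right")
    p = (1 + n_le) / (1 + m * n_null)
    return rp, p


def _ranks_within(table: pd.DataFrame) -> dict[str, int]:
    """Ascending rank by p; ties broken by larger statistic, then hub ID."""
    df = table.copy()
    if "statistic" not in df.columns:
        df["statistic"] = 0.0
    df = df.sort_values(["p_value", "statistic", "hub"],
                        ascending=[True, False, True], kind="stable")
    return {hub: i + 1 for i, hub in enumerate(df["hub"])}


def summarize_hub_data(result_tables: list[pd.DataFrame],
                       method: str = "fisher",
                       n_null: int = DEFAULT_N_NULL,
                       seed: int = 0
                       ) -> tuple[list[MetaResult], list[str]]:
    """Meta-analyse hubs present in *all* N result tables.

    Tables are in the single-dataset result format (columns ``hub``,
    ``p_value``, optionally ``statistic`` and ``n_permutations``).  For
    Fisher, each p_i is clamped below at its table's permutation floor
    ``1/(B_i+1)`` when B_i is known.  For the rank product, ranks are
    assigned within each table over the shared hubs only.  Returns the
    meta results sorted by combined p (then hub ID) plus the side list of
    hubs that were missing from at least one table.
    """
    if method not in ("fisher", "rankprod"):
        raise ValueError(f"unknown meta-analysis method {method!r}")
    if len(result_tables) < 2:
        raise ValueError("meta-analysis needs at least 2 result tables")
    tables = [t.copy() for t in result_tables]
    for t in tables:
        t["hub"] = t["hub"].astype(str)
    hub_sets = [set(t["hub"]) for t in tables]
    shared = sorted(set.intersection(*hub_sets))
    skipped = sorted(set.union(*hub_sets) - set(shared))
    if not shared:
        raise ValueError("no hub is present in every result table")
    if skipped:
        logger.info("%d hubs missing from at least one table are not "
                    "meta-analysed", len(skipped))

    sub_tables = [t[t["hub"].isin(shared)].set_index("hub") for t in tables]
    n = len(tables)
    rank_maps = [_ranks_within(t.loc[shared].reset_index()) for t in sub_tables]

    results: list[MetaResult] = []
    if method == "fisher":
        for hub in shared:
            ps = []
            for t in sub_tables:
                p = float(t.at[hub, "p_value"])
                if "n_permutations" in t.columns:
                    b = t.at[hub, "n_permutations"]
                    if np.isfinite(b) and b > 0:
                        p = max(p, 1.0 / (float(b) + 1.0))
                ps.append(min(p, 1.0))
            stat, cp = fisher_combined(ps)
            results.append(MetaResult(
                hub=hub, per_dataset_p=tuple(ps),
                per_dataset_rank=tuple(rm[hub] for rm in rank_maps),
                combined_statistic=stat, combined_p=cp,
                method="fisher", n_datasets=n))
    else:
        rank_matrix = np.array([[rm[hub] for rm in rank_maps]
                                for hub in shared], dtype=float)
        rp, p = rank_product(rank_matrix, n_null=n_null, seed=seed)
        for i, hub in enumerate(shared):
            results.append(MetaResult(
                hub=hub,
                per_dataset_p=tuple(float(t.at[hub, "p_value"])
                                    for t in sub_tables),
                per_dataset_rank=tuple(int(r) for r in rank_matrix[i]),
                combined_statistic=float(rp[i]), combined_p=float(p[i]),
                method="rankprod", n_datasets=n))
    results.sort(key=lambda r: (r.combined_p, r.hub))
    return results, skipped


def meta_frame(results: list[MetaResult]) -> pd.DataFrame:
    """Meta results as a DataFrame (one p and rank column per dataset)."""
    if not results:
        return pd.DataFrame(columns=["hub", "combined_statistic",
                                     "combined_p", "method"])
    n = results[0].n_datasets
    rows = []
    for r in results:
        row = {"hub": r.hub}
        for i in range(n):
            row[f"p_{i + 1}"] = r.per_dataset_p[i]
        for i in range(n):
            row[f"rank_{i + 1}"] = r.per_dataset_rank[i]
        row["combined_statistic"] = r.combined_statistic
        row["combined_p"] = r.combined_p
        row["method"] = r.method
        rows.append(row)
    return pd.DataFrame(rows)


def write_meta_results(results: list[MetaResult], path) -> None:
    meta_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA")
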