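"""Core containers and tab-delimited I/O for the hub-module pipeline.

The pipeline consumes three primary inputs:

* an expression matrix (genes x samples, pre-normalised, missing values
  allowed),
* a sample-to-condition label table defining the biological states being
  compared (two or more, each with at least three samples so that a
  correlation coefficient is estimable),
* a molecular interaction network given as a gene/protein/microRNA edge
  list (undirected for protein-protein interactions, directed
  microRNA -> target for microRNA networks),

and produces per-hub test result tables.  All on-disk formats are plain
tab-delimited text.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens interpreted as missing in expression files (after whitespace strip)
MISSING_TOKENS = ("", "NA")


class ParseError(ValueError):
    """A file could not be interpreted in the documented dialect."""


class ValidationError(ValueError):
    """Structurally valid input violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (pre-normalised) expression values.

    ``data`` is a float DataFrame indexed by gene ID with sample IDs as
    columns; missing measurements are NaN.  Gene and sample IDs must be
    unique; a sample with no finite value at all is rejected because it
    can contribute nothing to any correlation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = pd.Index([str(g).strip() for g in self.data.index])
        cols = pd.Index([str(s).strip() for s in self.data.columns])
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        data = self.data.copy()
        data.index = idx
        data.columns = cols
        data = data.astype(float)
        all_missing = data.columns[data.isna().all(axis=0)]
        if len(all_missing) and len(data.index):
            raise ValidationError(
                f"samples with all values missing: {list(all_missing)[:5]}"
            )
        self.data = data

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy()


def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples table: header row of sample IDs, first column
    of gene IDs, remaining cells numeric or a missing token ("NA" or empty).

    Duplicate gene rows (e.g. multiple probes per gene) are collapsed to the
    row with the highest mean expression across samples; the number of rows
    collapsed away is logged.  Duplicate sample IDs are an error.
    """
    try:
        raw = pd.read_csv(
            path, sep=delimiter, index_col=0, dtype=str,
            keep_default_na=False, header=0,
        )
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty expression file") from None
    sample_ids = [str(c).strip() for c in raw.columns]
    if len(set(sample_ids)) != len(sample_ids):
        # pandas mangles duplicate header fields; re-read the header verbatim
        raise ValidationError(f"{path}: duplicate sample IDs in header")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    header = [h.strip() for h in header]
    if len(set(header)) != len(header):
        raise ValidationError(f"{path}: duplicate sample IDs in header")
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise ParseError(f"{path}: no data rows/columns")

    gene_ids = [str(g).strip() for g in raw.index]
    values = np.empty(raw.shape, dtype=float)
    cells = raw.to_numpy()
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            tok = cells[i, j].strip()
            if tok in MISSING_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {tok!r} at gene "
                        f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
                    ) from None
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)

    if df.index.has_duplicates:
        # keep, per duplicated gene ID, the row with the highest mean
        means = df.mean(axis=1, skipna=True).to_numpy()
        order = np.argsort(-np.nan_to_num(means, nan=-math.inf), kind="stable")
        kept = df.iloc[order]
        n_before = len(kept)
        kept = kept[~kept.index.duplicated(keep="first")]
        logger.info("collapsed %d duplicate gene rows (highest-mean rule)",
                    n_before - len(kept))
        # restore first-appearance order of the surviving gene IDs
        first_order = [g for g in dict.fromkeys(gene_ids) ]
        df = kept.loc[first_order]
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write an expression matrix; missing values serialised as "NA"."""
    expr.data.to_csv(path, sep=delimiter, na_rep="NA",
                     index_label="gene_id")


# ---------------------------------------------------------------------------
# Condition labels
# ---------------------------------------------------------------------------

@dataclass
class ConditionLabels:
    """Sample -> biological condition assignment.

    ``conditions`` is the distinct condition list in first-appearance
    order; every condition needs at least three samples (a Pearson or
    Spearman correlation over fewer than three points is meaningless).
    """

    assignment: dict[str, str]
    conditions: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.conditions is None:
            self.conditions = list(dict.fromkeys(self.assignment.values()))
        counts = self.condition_sizes()
        if len(self.conditions) < 2:
            raise ValidationError("need at least 2 conditions")
        small = {c: n for c, n in counts.items() if n < 3}
        if small:
            raise ValidationError(
                f"conditions with fewer than 3 samples: {small}"
            )

    def condition_sizes(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.conditions or []}
        for cond in self.assignment.values():
            counts[cond] = counts.get(cond, 0) + 1
        return counts

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == condition]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = sorted(set(self.assignment) - set(expr.sample_ids))
        if missing:
            raise ValidationError(
                f"labelled samples absent from expression data: {missing[:5]}"
            )


_LABEL_HEADER_NAMES = {"sample", "sample_id", "sampleid"}


def read_labels(path, delimiter: str = "\t") -> ConditionLabels:
    """Read a two-column sample/condition table (optional header line)."""
    assignment: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            sample, cond = fields[0], fields[1]
            if lineno == 1 and sample.lower() in _LABEL_HEADER_NAMES:
                continue
            if sample in assignment:
                raise ValidationError(
                    f"{path}:{lineno}: sample {sample!r} listed twice"
                )
            assignment[sample] = cond
    if not assignment:
        raise ParseError(f"{path}: no label rows")
    return ConditionLabels(assignment)


def write_labels(labels: ConditionLabels, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"sample{delimiter}condition\n")
        for sample, cond in labels.assignment.items():
            fh.write(f"{sample}{delimiter}{cond}\n")


# ---------------------------------------------------------------------------
# Interaction network and modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Network:
    """An interaction network as a set of edges over string node IDs.

    Undirected edges are stored canonically (lexicographically ordered
    pair); self-loops are disallowed.  Directed networks are used for
    microRNA -> target interactions, where only the source side is a hub
    candidate.
    """

    edges: frozenset
    directed: bool = False

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if not self.directed and a > b:
                raise ValidationError(
                    f"undirected edge ({a!r}, {b!r}) not canonically ordered"
                )

    @property
    def nodes(self) -> set:
        out = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def n_edges(self) -> int:
        return len(self.edges)


def read_edge_list(path, delimiter: str = "\t") -> list[tuple[str, str]]:
    """Read raw edges from a two-column TSV; a third column is ignored.

    Returns raw pairs; pass through :func:`hubmod.network.clean_network`
    to obtain a validated :class:`Network`.
    """
    edges: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns")
            edges.append((fields[0], fields[1]))
    return edges


def write_edge_list(network: Network, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}{delimiter}{b}\n")


@dataclass(frozen=True)
class NetworkModule:
    """A hub together with its expression-covered interaction partners."""

    hub: str
    partners: tuple

    def __post_init__(self) -> None:
        if self.hub in self.partners:
            raise ValidationError(f"hub {self.hub!r} listed among partners")
        if len(set(self.partners)) != len(self.partners):
            raise ValidationError("duplicate partners in module")

    @property
    def n_partners(self) -> int:
        return len(self.partners)


# ---------------------------------------------------------------------------
# Hub test results
# ---------------------------------------------------------------------------

@dataclass
class HubTestResult:
    """Outcome of the per-module differential-correlation permutation test.

    ``mean_corr`` maps each condition to the average hub-partner
    correlation over the module's surviving partners; ``statistic`` is the
    absolute mean-correlation difference (two conditions) or a one-way
    ANOVA F (more); ``p_value`` is the permutation p, never zero by the
    +1 rule (sampled mode) or by inclusion of the identity assignment
    (exhaustive mode).
    """

    hub: str
    n_partners: int
    mean_corr: dict[str, float]
    statistic: float
    p_value: float
    n_permutations: int
    statistic_kind: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")
        if self.statistic < 0:
            raise ValidationError("statistic must be non-negative")
        for c, r in self.mean_corr.items():
            if np.isfinite(r) and abs(r) > 1 + 1e-12:
                raise ValidationError(f"mean correlation {r} for {c} outside [-1,1]")


def results_frame(results: list[HubTestResult],
                  conditions: list[str] | None = None,
                  bh: bool = False) -> pd.DataFrame:
    """Results as a DataFrame sorted by (p_value, hub)."""
    if conditions is None:
        conditions = list(results[0].mean_corr) if results else []
    rows = []
    for r in results:
        row = {"hub": r.hub, "n_partners": r.n_partners}
        for c in conditions:
            row[f"mean_corr_{c}"] = r.mean_corr.get(c, np.nan)
        row["statistic"] = r.statistic
        row["p_value"] = r.p_value
        row["n_permutations"] = r.n_permutations
        rows.append(row)
    cols = (["hub", "n_partners"] + [f"mean_corr_{c}" for c in conditions]
            + ["statistic", "p_value", "n_permutations"])
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["p_value", "hub"], kind="stable").reset_index(drop=True)
    if bh and len(df):
        from statsmodels.stats.multitest import multipletests
        df["q_value"] = multipletests(df["p_value"].to_numpy(),
                                      method="fdr_bh")[1]
    return df


def write_results(results: list[HubTestResult], path,
                  conditions: list[str] | None = None,
                  bh: bool = False) -> None:
    """Write a result table, ascending by p then hub ID (total order, so
    re-serialisation is byte-identical)."""
    df = results_frame(results, conditions=conditions, bh=bh)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    """Read a result table produced by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    if "hub" not in df.columns or "p_value" not in df.columns:
        raise ParseError(f"{path}: not a hub result table (need hub, p_value)")
    df["hub"] = df["hub"].astype(str)
    return df
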