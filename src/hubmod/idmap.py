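"""Identifier mapping: from interaction-database exports to gene edge lists.

Protein interaction exports (PSI-MITAB) carry namespace-prefixed UniProt
accessions, while expression matrices are keyed by Entrez IDs or gene
symbols; microRNA target tables (TargetScan / Microcosm dialects) carry
microRNA names and target gene identifiers.  The functions here convert
those files into the plain two-column gene edge lists the rest of the
pipeline consumes, keeping count of everything lost along the way.

Only the first two MITAB columns (interactor A/B primary identifiers)
are consulted; alternative-identifier and alias columns are ignored.
UniProt isoform suffixes ("-2" etc.) are stripped.  All inputs are
user-supplied files; nothing is fetched from the network.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .data_model import Network, ParseError
from .network import clean_network

logger = logging.getLogger(__name__)

DEFAULT_NAMESPACES = frozenset({"uniprotkb"})

#: default column layouts per microRNA-target dialect; override any entry
#: via the ``columns`` argument (the layouts of both resources vary by
#: release, so the names are configuration, not gospel)
TARGETSCAN_COLUMNS = {"mir": "miR family", "gene": "Gene Symbol",
                      "gene_id": "Gene ID", "species": "Species ID"}
MICROCOSM_COLUMNS = {"mir": "mirna", "gene": "gene", "score": "score"}


@dataclass(frozen=True)
class InteractionRecord:
    """One binary interaction with namespace-stripped identifiers."""

    id_a: str
    id_b: str
    line: int


@dataclass
class MitabParseResult:
    records: list[InteractionRecord]
    n_rejected_namespace: int = 0
    n_malformed: int = 0
    n_isoforms_stripped: int = 0


@dataclass
class IdMapping:
    """Many-to-many identifier map (e.g. uniprot -> entrez/symbol)."""

    pairs: dict[str, set] = field(default_factory=dict)
    source_namespace: str = "uniprot"
    target_namespace: str = "gene"

    def __post_init__(self) -> None:
        if self.source_namespace == self.target_namespace:
            raise ValueError("source and target namespaces must differ")
        self.pairs = {s: set(t) for s, t in self.pairs.items() if t}

    def targets(self, source_id: str) -> set:
        return self.pairs.get(source_id, set())


def _split_namespaced(token: str) -> tuple[str, str]:
    token = token.strip()
    if ":" not in token:
        return "", token
    ns, value = token.split(":", 1)
    return ns.strip().lower(), value.strip()


def _strip_isoform(accession: str) -> tuple[str, bool]:
    if "-" in accession:
        stem, suffix = accession.rsplit("-", 1)
        if suffix.isdigit() and stem:
            return stem, True
    return accession, False


def parse_mitab(path, accepted_namespaces=DEFAULT_NAMESPACES
                ) -> MitabParseResult:
    """Parse the first two columns of a PSI-MITAB (tab-delimited) file.

    Lines starting with "#" are headers/comments.  A line is kept only
    when both primary identifiers carry an accepted namespace prefix
    (default ``uniprotkb``); rejected lines are counted by reason.
    """
    accepted = {ns.lower() for ns in accepted_namespaces}
    result = MitabParseResult(records=[])
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                result.n_malformed += 1
                continue
            ns_a, id_a = _split_namespaced(fields[0])
            ns_b, id_b = _split_namespaced(fields[1])
            if ns_a not in accepted or ns_b not in accepted:
                result.n_rejected_namespace += 1
                continue
            id_a, stripped_a = _strip_isoform(id_a)
            id_b, stripped_b = _strip_isoform(id_b)
            result.n_isoforms_stripped += int(stripped_a) + int(stripped_b)
            result.records.append(InteractionRecord(id_a, id_b, lineno))
    logger.info("parse_mitab: %d records kept, %d namespace-rejected, "
                "%d malformed, %d isoform suffixes stripped",
                len(result.records), result.n_rejected_namespace,
                result.n_malformed, result.n_isoforms_stripped)
    return result


def load_id_mapping(path, source_namespace: str = "uniprot",
                    target_namespace: str = "gene") -> IdMapping:
    """Load a two-column source/target TSV into a many-to-many mapping.

    Repeated sources accumulate; blank targets are skipped with a
    warning; an empty file yields an empty mapping (warned).
    """
    pairs: dict[str, set] = {}
    n_blank = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[1]:
                n_blank += 1
                logger.warning("%s:%d: blank target, line skipped",
                               path, lineno)
                continue
            pairs.setdefault(fields[0], set()).add(fields[1])
    if not pairs:
        logger.warning("%s: empty identifier mapping", path)
    return IdMapping(pairs=pairs, source_namespace=source_namespace,
                     target_namespace=target_namespace)


@dataclass
class PpiMapResult:
    network: Network
    n_unmapped_records: int
    n_expanded_edges: int

    @property
    def n_edges(self) -> int:
        return self.network.n_edges()


def generate_ppi_map(records: list[InteractionRecord],
                     mapping: IdMapping) -> PpiMapResult:
    """Expand protein interaction records to a gene-level network.

    Each record expands to the Cartesian product of its two sides'
    mapped gene sets (one-to-many mappings keep every gene); records
    unmapped on either side are dropped and counted.  The expanded edges
    are cleaned into an undirected network (self-loops and duplicates
    removed).
    """
    expanded: list[tuple[str, str]] = []
    n_unmapped = 0
    for rec in records:
        targets_a = mapping.targets(rec.id_a)
        targets_b = mapping.targets(rec.id_b)
        if not targets_a or not targets_b:
            n_unmapped += 1
            continue
        for a in targets_a:
            for b in targets_b:
                expanded.append((a, b))
    network = clean_network(expanded, directed=False)
    logger.info("generate_ppi_map: %d records unmapped, %d expanded edges, "
                "%d unique edges", n_unmapped, len(expanded),
                network.n_edges())
    return PpiMapResult(network=network, n_unmapped_records=n_unmapped,
                        n_expanded_edges=len(expanded))


@dataclass
class MicroRnaMapResult:
    network: Network
    n_rows_read: int
    n_filtered_species: int
    n_unmapped_genes: int

    @property
    def n_edges(self) -> int:
        return self.network.n_edges()


def generate_microrna_map(path, source: str,
                          species_filter: str | None = None,
                          mapping: IdMapping | None = None,
                          columns: dict[str, str] | None = None
                          ) -> MicroRnaMapResult:
    """Build a directed microRNA -> target gene network from a
    TargetScan- or Microcosm-style table.

    ``source`` selects the dialect ("targetscan" or "microcosm"), which
    fixes the default column names (override via ``columns``).  Rows not
    matching ``species_filter`` (taxon ID or name, compared as a string
    against the species column when one is configured and present) are
    dropped.  When ``mapping`` is given, the gene side is translated
    through it (one-to-many expands; unmapped genes are counted and
    dropped).
    """
    source = source.lower()
    if source == "targetscan":
        cols = dict(TARGETSCAN_COLUMNS)
    elif source == "microcosm":
        cols = dict(MICROCOSM_COLUMNS)
    else:
        raise ValueError(f"unknown microRNA-target source {source!r}; "
                         "expected 'targetscan' or 'microcosm'")
    if columns:
        cols.update(columns)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty table") from None
    for key in ("mir", "gene"):
        if cols[key] not in table.columns:
            raise ParseError(
                f"{path}: required column {cols[key]!r} (for {key!r}) "
                f"not found; available: {list(table.columns)}")

    n_read = len(table)
    n_filtered = 0
    species_col = cols.get("species")
    if species_filter is not None:
        if species_col is None or species_col not in table.columns:
            raise ParseError(
                f"{path}: species filter requested but species column "
                f"{species_col!r} is absent")
        keep = table[species_col].str.strip() == str(species_filter)
        n_filtered = int((~keep).sum())
        table = table[keep]

    edges: list[tuple[str, str]] = []
    n_unmapped = 0
    for mir, gene in zip(table[cols["mir"]], table[cols["gene"]]):
        mir, gene = mir.strip(), gene.strip()
        if not mir or not gene:
            n_unmapped += 1
            continue
        if mapping is not None:
            targets = mapping.targets(gene)
            if not targets:
                n_unmapped += 1
                continue
            edges.extend((mir, t) for t in targets)
        else:
            edges.append((mir, gene))
    network = clean_network(edges, directed=True)
    logger.info("generate_microrna_map(%s): %d rows, %d species-filtered, "
                "%d unmapped/blank, %d unique edges", source, n_read,
                n_filtered, n_unmapped, network.n_edges())
    return MicroRnaMapResult(network=network, n_rows_read=n_read,
                             n_filtered_species=n_filtered,
                             n_unmapped_genes=n_unmapped)
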