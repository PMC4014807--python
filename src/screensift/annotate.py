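"""Gene-centric mining: local GO and PPI stores, enrichment, subnetworks.

Annotation snapshots are NCBI-style tab-delimited files: a gene2go-like
layout (gene id, GO id, GO term text, category) and an interactions-like
layout with two interactor gene-id columns. Both readers are transparent
to gzip. Enrichment of a selected gene set is scored per GO category with
Fisher's exact test on the 2x2 table

    [[g_c,      G_c    ],
     [x - g_c,  N - G_c]]

where x is the number of selected genes, g_c of them in the category, G_c
the genome-wide category size and N the genome size (default 22000 protein
coding genes). This is the screen-table convention of the original tool:
the second column counts the whole genome rather than the non-selected
complement; ``background="standard"`` builds the conventional complement
table instead.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = [
    "GoAnnotation",
    "AnnotationStore",
    "AnnotationLoadReport",
    "load_go",
    "load_ppi",
    "go_enrichment",
    "EnrichmentResult",
    "search_go",
    "exclude_by_go",
    "ppi_subnetwork",
    "export_network",
    "load_network",
]

NAMESPACES = ("BP", "CC", "MF")
_CATEGORY_MAP = {
    "process": "BP",
    "biological_process": "BP",
    "biological process": "BP",
    "bp": "BP",
    "component": "CC",
    "cellular_component": "CC",
    "cellular component": "CC",
    "cc": "CC",
    "function": "MF",
    "molecular_function": "MF",
    "molecular function": "MF",
    "mf": "MF",
}
DEFAULT_GENOME_SIZE = 22_000


class GoAnnotation(NamedTuple):
    go_id: str
    term: str
    namespace: str


@dataclass
class AnnotationLoadReport:
    rows_read: int = 0
    rows_skipped: int = 0
    duplicates_collapsed: int = 0


@dataclass
class AnnotationStore:
    """Local gene -> GO mapping plus an undirected PPI edge set.

    PPI edges are canonical (smaller Entrez id first), with no self-loops
    or duplicates. ``genome_size`` is the N of the enrichment contingency
    table.
    """

    go_map: dict[int, set[GoAnnotation]] = field(default_factory=dict)
    ppi: set[tuple[int, int]] = field(default_factory=set)
    genome_size: int = DEFAULT_GENOME_SIZE
    go_report: AnnotationLoadReport | None = None
    ppi_report: AnnotationLoadReport | None = None

    def add_annotation(self, gene: int, go_id: str, term: str, namespace: str) -> None:
        if namespace not in NAMESPACES:
            raise ValueError(f"namespace must be one of {NAMESPACES}")
        self.go_map.setdefault(int(gene), set()).add(GoAnnotation(go_id, term, namespace))

    def add_edge(self, a: int, b: int) -> bool:
        """Add a canonical undirected edge; returns False for self-loops."""
        a, b = int(a), int(b)
        if a == b:
            return False
        self.ppi.add((min(a, b), max(a, b)))
        return True

    def category_sizes(self, namespace: str | None = None) -> dict[GoAnnotation, int]:
        """Genome-wide gene count per GO category (G_c), from the store."""
        sizes: dict[GoAnnotation, int] = {}
        for annots in self.go_map.values():
            for ann in annots:
                if namespace is None or ann.namespace == namespace:
                    sizes[ann] = sizes.get(ann, 0) + 1
        return sizes

    def ppi_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.ppi)
        return g


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _read_table(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    # NCBI files prefix the header with '#'
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    return df


def _find_column(df: pd.DataFrame, candidates: Iterable[str]) -> str | None:
    lowered = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def load_go(path: str | Path, store: AnnotationStore | None = None) -> AnnotationStore:
    """Load gene -> GO annotations from a gene2go-like tab-delimited file.

    Columns are located by header name (GeneID, GO_ID, GO_term, Category);
    duplicated (gene, GO) rows collapse to one annotation, and rows whose
    category string cannot be mapped to BP/CC/MF are skipped and counted in
    the load report.
    """
    store = store or AnnotationStore()
    report = AnnotationLoadReport()
    df = _read_table(path)
    gene_col = _find_column(df, ("geneid", "gene_id", "gene id", "entrez gene id", "entrez_id"))
    go_col = _find_column(df, ("go_id", "go id", "goid"))
    term_col = _find_column(df, ("go_term", "go term", "term"))
    cat_col = _find_column(df, ("category", "namespace", "ontology"))
    if gene_col is None or go_col is None or term_col is None or cat_col is None:
        raise ValueError(
            "gene2go-like file needs GeneID, GO_ID, GO_term and Category columns"
        )
    seen_before = sum(len(s) for s in store.go_map.values())
    for gene, go_id, term, cat in zip(df[gene_col], df[go_col], df[term_col], df[cat_col]):
        report.rows_read += 1
        ns = _CATEGORY_MAP.get(str(cat).strip().lower())
        try:
            gene = int(gene)
        except (ValueError, TypeError):
            ns = None
        if ns is None:
            report.rows_skipped += 1
            continue
        store.add_annotation(gene, str(go_id).strip(), str(term).strip(), ns)
    n_now = sum(len(s) for s in store.go_map.values())
    report.duplicates_collapsed = (
        report.rows_read - report.rows_skipped - (n_now - seen_before)
    )
    store.go_report = report
    return store


def load_ppi(
    path: str | Path,
    store: AnnotationStore | None = None,
    columns: tuple[str | int, str | int] | None = None,
) -> AnnotationStore:
    """Load an undirected PPI edge set from an interactions-like file.

    Interactor columns are found by header name (gene_id / interactant_id,
    the GeneRIF interactions layout) or may be given explicitly as names or
    0-based indices; otherwise the first two columns are used. Rows lacking
    two numeric gene ids are skipped and counted, self-interactions are
    dropped, and (A,B)/(B,A) duplicates collapse to one canonical edge.
    """
    store = store or AnnotationStore()
    report = AnnotationLoadReport()
    df = _read_table(path)
    if columns is not None:
        cols = [c if isinstance(c, str) else df.columns[c] for c in columns]
    else:
        a = _find_column(df, ("gene_id", "geneid", "gene a", "gene1", "interactor_a"))
        b = _find_column(df, ("interactant_id", "interactant id", "gene b", "gene2", "interactor_b"))
        cols = [a, b] if a and b else list(df.columns[:2])
    before = len(store.ppi)
    for va, vb in zip(df[cols[0]], df[cols[1]]):
        report.rows_read += 1
        try:
            ga, gb = int(str(va).strip()), int(str(vb).strip())
        except (ValueError, TypeError):
            report.rows_skipped += 1
            continue
        if not store.add_edge(ga, gb):
            report.rows_skipped += 1  # self-interaction
    report.duplicates_collapsed = (
        report.rows_read - report.rows_skipped - (len(store.ppi) - before)
    )
    store.ppi_report = report
    return store


@dataclass
class EnrichmentResult:
    """One GO category's contingency counts and Fisher-exact outcome."""

    go_id: str
    term: str
    namespace: str
    g_c: int
    x: int
    G_c: int
    N: int
    odds_ratio: float
    p_value: float


def go_enrichment(
    selected: Iterable[int],
    store: AnnotationStore,
    namespace: str | None = None,
    p_threshold: float = 1.0,
    background: str = "printed",
    alternative: str = "greater",
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Fisher-exact GO enrichment of a selected gene set.

    For every GO category with at least one selected gene, builds the 2x2
    table described in the module docstring (``background="printed"``; the
    ``"standard"`` option uses the non-selected complement in the second
    column) and computes the cross-product odds ratio and the one-sided
    (``alternative="greater"``, default) or two-sided Fisher p-value.
    Results with p <= ``p_threshold`` are returned sorted by ascending p,
    ties broken by GO id. ``fdr=True`` applies a Benjamini-Hochberg
    adjustment before thresholding.
    """
    selected = {int(g) for g in selected}
    if not selected:
        raise ValueError("selected gene set is empty")
    if background not in ("printed", "standard"):
        raise ValueError("background must be 'printed' or 'standard'")
    if namespace is not None and namespace not in NAMESPACES:
        raise ValueError(f"namespace must be one of {NAMESPACES}")
    x = len(selected)
    N = store.genome_size
    sizes = store.category_sizes(namespace)
    overlap: dict[GoAnnotation, int] = {}
    for gene in selected:
        for ann in store.go_map.get(gene, ()):
            if namespace is None or ann.namespace == namespace:
                overlap[ann] = overlap.get(ann, 0) + 1
    results: list[EnrichmentResult] = []
    for ann, g_c in overlap.items():
        G_c = sizes[ann]
        if background == "printed":
            table = [[g_c, G_c], [x - g_c, N - G_c]]
        else:
            table = [[g_c, G_c - g_c], [x - g_c, N - G_c - (x - g_c)]]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        results.append(
            EnrichmentResult(
                go_id=ann.go_id,
                term=ann.term,
                namespace=ann.namespace,
                g_c=g_c,
                x=x,
                G_c=G_c,
                N=N,
                odds_ratio=float(odds),
                p_value=float(p),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.go_id))
    if fdr:
        m = len(results)
        adj = [r.p_value * m / (i + 1) for i, r in enumerate(results)]
        # enforce monotonicity from the largest p down
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        for r, q in zip(results, adj):
            r.p_value = min(1.0, q)
    return [r for r in results if r.p_value <= p_threshold]


def search_go(
    store: AnnotationStore,
    term: str,
    namespace: str | None = None,
    within: Iterable[int] | None = None,
) -> set[int]:
    """Genes whose GO term text contains ``term`` (case-insensitive substring).

    Restricted to one namespace if given, and to the gene set ``within`` if
    given (e.g. the genes of a screen table).
    """
    if not term:
        raise ValueError("search term must be non-empty")
    if namespace is not None and namespace not in NAMESPACES:
        raise ValueError(f"namespace must be one of {NAMESPACES}")
    needle = term.lower()
    universe = (
        {int(g) for g in within} if within is not None else set(store.go_map.keys())
    )
    found: set[int] = set()
    for gene in universe:
        for ann in store.go_map.get(gene, ()):
            if namespace is not None and ann.namespace != namespace:
                continue
            if needle in ann.term.lower():
                found.add(gene)
                break
    return found


def exclude_by_go(table, store: AnnotationStore, term: str):
    """Derive a table without genes matching a GO term in any namespace.

    The screening use case: drop genes whose annotations contain e.g.
    "proteasome", because they perturb the readout directly rather than
    the process under study. Provenance records the term and the number of
    rows removed.
    """
    genes = set(table.records["entrez_id"].dropna().astype(int))
    flagged = search_go(store, term, namespace=None, within=genes)
    mask = ~table.records["entrez_id"].isin(flagged)
    return table.derive(
        table.records.loc[mask],
        f"exclude genes with GO term containing {term!r} ({int((~mask).sum())} rows removed)",
    )


def ppi_subnetwork(genes: Iterable[int], store: AnnotationStore) -> list[tuple[int, int]]:
    """All stored PPI edges with both endpoints in the gene set.

    Equivalent to searching every pair of genes in the list against the
    interaction database; returns canonical edges sorted for determinism.
    """
    gene_set = {int(g) for g in genes}
    edges = [(a, b) for a, b in store.ppi if a in gene_set and b in gene_set]
    return sorted(edges)


def connected_genes(edges: Iterable[tuple[int, int]]) -> set[int]:
    """Genes with at least one interaction in an edge list."""
    out: set[int] = set()
    for a, b in edges:
        out.update((a, b))
    return out


def export_network(
    edges: Iterable[tuple[int, int]], path: str | Path, fmt: str = "tsv"
) -> Path:
    """Write an edge list as 2-column TSV or SIF (interaction type "pp")."""
    path = Path(path)
    lines = []
    for a, b in edges:
        if fmt == "tsv":
            lines.append(f"{a}\t{b}")
        elif fmt == "sif":
            lines.append(f"{a} pp {b}")
        else:
            raise ValueError("format must be 'tsv' or 'sif'")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def load_network(path: str | Path) -> list[tuple[int, int]]:
    """Re-parse an exported network (TSV or SIF) into canonical edges."""
    edges: set[tuple[int, int]] = set()
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) == 3 and parts[1] == "pp":
            a, b = int(parts[0]), int(parts[2])
        elif len(parts) == 2:
            a, b = int(parts[0]), int(parts[1])
        else:
            raise ValueError(f"malformed network line {line!r}")
        edges.add((min(a, b), max(a, b)))
    return sorted(edges)
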