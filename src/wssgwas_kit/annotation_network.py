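"""Gene annotation of selected windows, bipartite networks and enrichment.

Selected SNP windows are mapped to positional candidate genes by interval
overlap; the resulting trait-window-gene table feeds a bipartite
gene-trait network, pleiotropy summaries (windows associated with more
than one trait), miRNA-gene target networks, and a generic hypergeometric
over-representation test with Benjamini-Hochberg adjustment.

Counting conventions: duplicate symbols within one window are collapsed;
a symbol recurring in several windows of the same trait contributes one
ENTRY per window but a single UNIQUE gene.  Both counts are exposed
because published summaries mix the two (per-trait totals and network
edge counts are entry-level; trait overlaps are unique-symbol).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .wssgwas import WindowResult


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneInterval:
    """Gene (or miRNA) span, 1-based inclusive coordinates."""

    symbol: str
    chrom: str
    start_bp: int
    end_bp: int
    node_type: str = "gene"  # gene | miRNA

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.symbol}: start_bp > end_bp")


def read_gene_intervals(path) -> list[GeneInterval]:
    """BED-like TSV: chrom, start, end, symbol[, node_type]; 1-based inclusive."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for r in frame.itertuples():
        out.append(
            GeneInterval(
                symbol=str(r.symbol), chrom=str(r.chrom),
                start_bp=int(r.start), end_bp=int(r.end),
                node_type=getattr(r, "node_type", "gene"),
            )
        )
    return out


@dataclass
class TraitWindowRow:
    trait: str
    chrom: str
    start_mb: float
    end_mb: float
    gv_percent: float
    members: list[tuple[str, str]]  # (symbol, node_type); empty = none found


@dataclass
class TraitWindowTable:
    """Per-(trait, window) gene annotations."""

    rows: list[TraitWindowRow]

    @property
    def traits(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.trait, None)
        return list(seen)

    def trait_symbols(self, trait: str, node_type: str | None = None) -> set[str]:
        """Unique member symbols annotated to a trait."""
        syms: set[str] = set()
        for r in self.rows:
            if r.trait == trait:
                syms.update(
                    s for s, t in r.members
                    if node_type is None or t == node_type
                )
        return syms

    def trait_entry_counts(self, node_type: str | None = None) -> dict[str, int]:
        """Per-trait member entries, counted once per (window, symbol)."""
        counts: dict[str, int] = {}
        for r in self.rows:
            k = len([s for s, t in r.members
                     if node_type is None or t == node_type])
            counts[r.trait] = counts.get(r.trait, 0) + k
        return counts

    def trait_gene_counts(self, node_type: str | None = None) -> dict[str, int]:
        """Per-trait unique symbol counts."""
        return {t: len(self.trait_symbols(t, node_type)) for t in self.traits}

    def all_symbols(self, node_type: str | None = None) -> set[str]:
        syms: set[str] = set()
        for t in self.traits:
            syms |= self.trait_symbols(t, node_type)
        return syms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": r.trait, "chrom": r.chrom,
                    "start_mb": r.start_mb, "end_mb": r.end_mb,
                    "gv_percent": r.gv_percent,
                    "members": ";".join(s for s, _ in r.members),
                }
                for r in self.rows
            ]
        )


def map_windows_to_genes(
    windows: list[WindowResult],
    genes: list[GeneInterval],
    trait: str,
    mode: str = "overlap",
) -> TraitWindowTable:
    """Assign genes to windows by closed-interval overlap.

    ``mode="overlap"`` (default) assigns a gene iff its interval
    intersects the window; ``mode="contained"`` requires the gene to lie
    entirely inside the window.
    """
    if mode not in ("overlap", "contained"):
        raise ConfigurationError(f"unknown mapping mode {mode!r}")
    rows = []
    for res in windows:
        w = res.window
        members: list[tuple[str, str]] = []
        seen: set[str] = set()
        for g in genes:
            if g.chrom != str(w.chrom) or g.symbol in seen:
                continue
            if mode == "overlap":
                hit = g.start_bp <= w.end_bp and g.end_bp >= w.start_bp
            else:
                hit = g.start_bp >= w.start_bp and g.end_bp <= w.end_bp
            if hit:
                members.append((g.symbol, g.node_type))
                seen.add(g.symbol)
        rows.append(
            TraitWindowRow(
                trait=trait, chrom=str(w.chrom),
                start_mb=w.start_bp / 1e6, end_mb=w.end_bp / 1e6,
                gv_percent=res.gv_percent, members=members,
            )
        )
    return TraitWindowTable(rows)


def build_gene_trait_network(table: TraitWindowTable) -> nx.Graph:
    """Bipartite graph: trait nodes vs gene/miRNA nodes, one edge per
    distinct (trait, symbol) pair, relation ``annotated_in``."""
    g = nx.Graph()
    for r in table.rows:
        if r.trait not in g:
            g.add_node(r.trait, node_type="trait", bipartite=0)
        for sym, typ in r.members:
            if sym not in g:
                g.add_node(sym, node_type=typ, bipartite=1)
            g.add_edge(r.trait, sym, relation="annotated_in")
    return g


def trait_overlap(
    table: TraitWindowTable, traits: set[str], exclusive: bool = False
) -> tuple[int, list[str]]:
    """Symbols annotated to every trait in ``traits`` (and, with
    ``exclusive``, to none of the others)."""
    known = set(table.traits)
    unknown = set(traits) - known
    if unknown:
        raise ConfigurationError(f"unknown traits: {sorted(unknown)}")
    sets = [table.trait_symbols(t) for t in traits]
    common = set.intersection(*sets) if sets else set()
    if exclusive:
        for other in known - set(traits):
            common -= table.trait_symbols(other)
    return len(common), sorted(common)


def pleiotropy_summary(table: TraitWindowTable) -> tuple[int, int, int]:
    """(distinct windows, pleiotropic, trait-specific); a window is keyed
    by (chrom, start, end) and pleiotropic when >= 2 traits share it."""
    traits_per_window: dict[tuple, set[str]] = {}
    for r in table.rows:
        key = (r.chrom, r.start_mb, r.end_mb)
        traits_per_window.setdefault(key, set()).add(r.trait)
    n_distinct = len(traits_per_window)
    n_pleio = sum(1 for v in traits_per_window.values() if len(v) >= 2)
    return n_distinct, n_pleio, n_distinct - n_pleio


def build_mirna_gene_network(
    targets: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
) -> nx.Graph:
    """miRNA-gene ``targets`` edges plus gene-gene ``interacts`` edges.

    ``targets`` columns: (mirna, gene); ``interactions``: (gene_a, gene_b).
    Self-loops are rejected.
    """
    g = nx.Graph()
    if targets is not None:
        for mir, gene in targets.itertuples(index=False):
            if mir == gene:
                raise ValueError(f"self-loop on {mir!r}")
            g.add_node(mir, node_type="miRNA", bipartite=0)
            if gene not in g:
                g.add_node(gene, node_type="gene", bipartite=1)
            g.add_edge(mir, gene, relation="targets")
    if interactions is not None:
        for a, b in interactions.itertuples(index=False):
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            for node in (a, b):
                if node not in g:
                    g.add_node(node, node_type="gene", bipartite=1)
            g.add_edge(a, b, relation="interacts")
    return g


def hub_genes(g: nx.Graph) -> list[str]:
    """Maximum-degree gene node(s); ties all reported, sorted."""
    genes = [n for n, d in g.nodes(data=True) if d.get("node_type") == "gene"]
    if not genes:
        return []
    deg = dict(g.degree(genes))
    top = max(deg.values())
    return sorted(n for n, k in deg.items() if k == top)


def targeted_genes(g: nx.Graph) -> set[str]:
    """Distinct gene nodes incident to at least one ``targets`` edge."""
    out: set[str] = set()
    for a, b, d in g.edges(data=True):
        if d.get("relation") == "targets":
            out.add(b if g.nodes[a].get("node_type") == "miRNA" else a)
    return out


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    term_size: int
    list_size: int
    background_size: int
    p: float
    p_adj: float


def hypergeometric_enrichment(
    gene_list: set[str] | list[str],
    background: set[str] | list[str],
    gene_sets: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per term, BH-adjusted.

    With N background genes, K of them in the term, and a query list of n,
    the p-value is P[overlap >= observed] under sampling without
    replacement.  Terms are intersected with the background; results come
    back sorted ascending by raw p.
    """
    background = set(background)
    if not background:
        raise ConfigurationError("empty background")
    query = set(gene_list)
    stray = query - background
    if stray:
        raise ConfigurationError(
            f"gene list not contained in background (e.g. {sorted(stray)[0]!r})"
        )
    N, n = len(background), len(query)
    raw: list[tuple[str, int, int, float]] = []
    for term, members in gene_sets.items():
        K = len(members & background)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        raw.append((term, k, K, min(p, 1.0)))
    if not raw:
        return []
    _, p_adj, _, _ = multipletests([r[3] for r in raw], method="fdr_bh")
    out = [
        EnrichmentResult(term, k, K, n, N, p, float(pa))
        for (term, k, K, p), pa in zip(raw, p_adj)
    ]
    return sorted(out, key=lambda r: r.p)
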