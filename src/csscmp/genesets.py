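"""Gene-set collections: GMT I/O and GO-derived construction.

Collections are built the way the MSigDB C5 (GO Biological Process)
collections are: annotations filtered by evidence code, NOT-qualified entries
dropped, each gene propagated to all ancestor terms along is_a / part_of
edges, and sets outside the 15-500 size window removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .contingency import ConfigurationError

logger = logging.getLogger(__name__)

#: experimentally grounded / curated evidence codes admitted by default
#: (electronic annotations, IEA, are deliberately excluded)
DEFAULT_EVIDENCE_WHITELIST = frozenset(
    {"IDA", "IPI", "IMP", "IGI", "IEP", "ISS", "TAS"}
)

KNOWN_EVIDENCE_CODES = frozenset({
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI",
    "HEP", "IBA", "IBD", "IKR", "IRD", "ISS", "ISO", "ISA", "ISM", "IGC",
    "RCA", "TAS", "NAS", "IC", "ND", "IEA",
})

PROPAGATION_RELATIONS = ("is_a", "part_of")


@dataclass
class GeneSet:
    set_id: str
    name: str
    genes: set

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named list of gene sets with provenance of the source files."""

    label: str
    sets: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [gs.set_id for gs in self.sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate set ids: {dupes}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def set_ids(self) -> set:
        return {gs.set_id for gs in self.sets}


def read_gmt(path, label: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate members are collapsed and empty member fields skipped; a line
    with fewer than 3 fields is a parse error reported with its line number.
    """
    path = Path(path)
    sets = []
    text = path.read_text()
    if not text.strip():
        logger.warning("GMT file %s is empty", path)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                f"(got {len(fields)})"
            )
        name, description, *members = fields
        genes = {m.strip() for m in members if m.strip()}
        sets.append(GeneSet(set_id=name, name=description, genes=genes))
    return GeneSetCollection(label=label or path.stem, sets=sets,
                             provenance={"source": str(path)})


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (round-trips membership exactly).

    Tabs inside set ids or descriptions would corrupt the format; they are
    replaced by spaces with a warning.
    """
    lines = []
    for gs in collection:
        sid, desc = gs.set_id, gs.name
        if "\t" in sid or "\t" in desc:
            logger.warning("tab character sanitized in set %r", sid)
            sid = sid.replace("\t", " ")
            desc = desc.replace("\t", " ")
        lines.append("\t".join([sid, desc, *sorted(gs.genes)]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def filter_by_size(collection: GeneSetCollection, min_size: int = 15,
                   max_size: int = 500) -> GeneSetCollection:
    """Keep sets with min_size <= |genes| <= max_size (bounds inclusive)."""
    if min_size > max_size:
        raise ConfigurationError(
            f"min_size {min_size} exceeds max_size {max_size}")
    kept = [gs for gs in collection if min_size <= len(gs.genes) <= max_size]
    prov = dict(collection.provenance)
    prov["size_filter"] = (f"{min_size}<=size<={max_size}: "
                           f"{len(collection)} -> {len(kept)} sets")
    return GeneSetCollection(label=collection.label, sets=kept,
                             provenance=prov)


def _propagation_graph(obo_graph: nx.MultiDiGraph,
                       relations: Sequence[str]) -> nx.DiGraph:
    """Child -> parent digraph restricted to the given relation types."""
    g = nx.DiGraph()
    g.add_nodes_from(obo_graph.nodes)
    for child, parent, key in obo_graph.edges(keys=True):
        if key in relations:
            g.add_edge(child, parent)
    return g


def _read_gaf(gaf_path, namespace_code: str, taxon: str | None,
              evidence_whitelist: frozenset):
    """Yield (term, gene symbol) pairs passing the GAF filters."""
    from Bio.UniProt import GOA

    with open(gaf_path) as handle:
        for rec in GOA.gafiterator(handle):
            if rec["Aspect"] != namespace_code:
                continue
            if rec["Evidence"] not in evidence_whitelist:
                continue
            qualifiers = rec.get("Qualifier") or []
            if any(q == "NOT" or q.startswith("NOT|") or q.endswith("|NOT")
                   or "NOT" in q.split("|") for q in qualifiers):
                continue
            if taxon is not None:
                taxons = rec.get("Taxon_ID") or []
                if not any(t.split(":")[-1] == taxon for t in taxons):
                    continue
            symbol = rec["DB_Object_Symbol"].strip().upper()
            if symbol:
                yield rec["GO_ID"], symbol


_NAMESPACE_CODES = {"biological_process": "P", "molecular_function": "F",
                    "cellular_component": "C"}


def build_go_collection(
    obo_path,
    gaf_path,
    namespace: str = "biological_process",
    evidence_whitelist: Iterable[str] = DEFAULT_EVIDENCE_WHITELIST,
    taxon: str | None = "9606",
    label: str = "GO_BP",
    min_size: int | None = None,
    max_size: int | None = None,
) -> GeneSetCollection:
    """Build one gene set per GO term from an ontology + annotation file.

    Annotations are filtered to the namespace, evidence whitelist and taxon,
    NOT-qualified entries dropped, then each gene is propagated to every
    ancestor reachable via is_a / part_of.  Obsolete terms (absent from the
    OBO graph or flagged obsolete) are skipped.  Apply
    :func:`filter_by_size` afterwards (or pass min/max_size) to mirror the
    usual 15-500 window.
    """
    import obonet

    whitelist = frozenset(evidence_whitelist)
    unknown = whitelist - KNOWN_EVIDENCE_CODES
    if unknown:
        logger.warning("unknown evidence codes in whitelist: %s",
                       sorted(unknown))
    graph = obonet.read_obo(obo_path)
    prop = _propagation_graph(graph, PROPAGATION_RELATIONS)
    if not nx.is_directed_acyclic_graph(prop):
        raise ValueError("ontology has a cycle over is_a/part_of edges")
    ns_code = _NAMESPACE_CODES[namespace]
    in_namespace = {
        node for node, data in graph.nodes(data=True)
        if data.get("namespace", namespace) == namespace
        and data.get("is_obsolete", "false") != "true"
    }
    term_genes: dict = {}
    n_direct = 0
    for term, gene in _read_gaf(gaf_path, ns_code, taxon, whitelist):
        if term not in in_namespace:
            continue
        n_direct += 1
        term_genes.setdefault(term, set()).add(gene)
        # obonet edges point child -> parent, so ancestors are descendants
        for ancestor in nx.descendants(prop, term):
            if ancestor in in_namespace:
                term_genes.setdefault(ancestor, set()).add(gene)
    sets = [
        GeneSet(set_id=term,
                name=graph.nodes[term].get("name", term),
                genes=genes)
        for term, genes in sorted(term_genes.items())
        if genes
    ]
    logger.info("%d annotations kept, %d terms with members", n_direct,
                len(sets))
    collection = GeneSetCollection(
        label=label, sets=sets,
        provenance={"obo": str(obo_path), "gaf": str(gaf_path),
                    "namespace": namespace, "taxon": taxon or "any",
                    "evidence": ",".join(sorted(whitelist))},
    )
    if min_size is not None or max_size is not None:
        collection = filter_by_size(collection, min_size or 0,
                                    max_size or 10 ** 9)
    return collection


def collection_overlap(c1, c2, top_k: int | None = None,
                       ranked1=None, ranked2=None) -> dict:
    """Shared set ids between two collections, optionally among the top k.

    When ``top_k`` is given, ``ranked1``/``ranked2`` are ranked
    :class:`~csscmp.scoring.ScoreResult` lists whose first ``top_k`` entries
    are intersected; ``top_k`` larger than a list is capped with a warning.
    """
    ids1 = c1.set_ids() if hasattr(c1, "set_ids") else set(c1)
    ids2 = c2.set_ids() if hasattr(c2, "set_ids") else set(c2)
    out = {"shared": len(ids1 & ids2), "n1": len(ids1), "n2": len(ids2)}
    if top_k is not None:
        if ranked1 is None or ranked2 is None:
            raise ConfigurationError("top_k requires two ranked result lists")
        k = top_k
        if k > min(len(ranked1), len(ranked2)):
            k = min(len(ranked1), len(ranked2))
            logger.warning("top_k capped to %d (shortest ranking)", k)
        top1 = {r.set_id for r in ranked1[:k]}
        top2 = {r.set_id for r in ranked2[:k]}
        out["top_k"] = k
        out["shared_top_k"] = len(top1 & top2)
    return out
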