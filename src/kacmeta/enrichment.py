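"""Fisher-exact term enrichment over GO and KEGG annotations.

For each term the engine builds a 2x2 contingency table

    a = study genes annotated to the term
    b = study genes not annotated
    c = background genes annotated to the term, outside the study
    d = remaining background genes

and computes the one-sided (enrichment) Fisher exact p-value, i.e. the upper
tail of the hypergeometric distribution

    p = sum_{x >= a}  C(K, x) C(N-K, n-x) / C(N, n)

with N = a+b+c+d, K = a+c (term size in background), n = a+b (study size).
For moderate N the sum is evaluated in exact integer arithmetic; very large
backgrounds fall back to a numerically stable survival-function evaluation.

Fold enrichment is the study-set frequency of the term divided by its
background frequency: (a/(a+b)) / ((a+c)/N).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import obonet
from scipy import stats

__all__ = [
    "OntologyDAG",
    "PathwayHierarchy",
    "ContingencyTable",
    "EnrichmentResult",
    "parse_obo",
    "parse_kegg_htext",
    "propagate_annotations",
    "build_contingency",
    "fisher_exact_greater",
    "run_enrichment",
]

# exact integer tail sums up to this population size; beyond it, log-space
_EXACT_N_MAX = 10_000


@dataclass(frozen=True)
class OntologyDAG:
    """Ontology terms plus the acyclic ``is_a`` parent graph."""

    terms: dict[str, tuple[str, str]]  # id -> (name, namespace)
    parents: dict[str, frozenset[str]]  # child -> direct is_a parents

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via is_a edges (excl. itself)."""
        out: set[str] = set()
        stack = list(self.parents.get(term_id, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


@dataclass(frozen=True)
class PathwayHierarchy:
    """KO-to-pathway mapping extracted from a KEGG BRITE htext file."""

    ko_to_pathways: dict[str, frozenset[str]]
    pathway_names: dict[str, str]
    orphan_kos: frozenset[str] = frozenset()

    def ancestors(self, ko_id: str) -> set[str]:
        """Pathways containing a KO; mirrors OntologyDAG for the engine."""
        return set(self.ko_to_pathways.get(ko_id, ()))


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def study_size(self) -> int:
        return self.a + self.b

    @property
    def term_size(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    table: ContingencyTable
    p_value: float
    fold_enrichment: float
    significant: bool
    p_adjusted: float | None = None


def _validate_obo_text(path: Path) -> None:
    """Cheap structural check giving line numbers for malformed stanzas."""
    in_stanza = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            if not stripped.endswith("]"):
                raise ValueError(f"{path}:{lineno}: malformed stanza header "
                                 f"{stripped!r}")
            in_stanza = True
            continue
        if in_stanza and ":" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'tag: value' line, "
                             f"got {stripped!r}")


def parse_obo(path: str | Path) -> OntologyDAG:
    """Load an OBO 1.2/1.4 ontology (e.g. go-basic.obo) into an is_a DAG.

    Obsolete terms are excluded.  A cycle among is_a edges is an error.
    """
    path = Path(path)
    _validate_obo_text(path)
    graph = obonet.read_obo(str(path))  # child -> parent MultiDiGraph
    is_a = nx.DiGraph()
    terms: dict[str, tuple[str, str]] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", ""), data.get("namespace", ""))
        is_a.add_node(node)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            is_a.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(is_a):
        cycle = nx.find_cycle(is_a)
        raise ValueError(f"is_a cycle detected: {cycle}")
    parents = {
        node: frozenset(is_a.successors(node)) for node in is_a.nodes
    }
    return OntologyDAG(terms=terms, parents=parents)


_KEGG_C = re.compile(r"^C\s+(\d{5})\s+(.*?)(?:\s*\[PATH:[^\]]+\])?\s*$")
_KEGG_D = re.compile(r"^D\s+(K\d{5})\s+(.*)$")


def parse_kegg_htext(path: str | Path) -> PathwayHierarchy:
    """Parse a KEGG BRITE htext (ko00001-style) into KO -> pathway mappings.

    The file uses A/B/C/D indentation levels; D-level KO entries are mapped
    to their enclosing C-level pathway.  A KO appearing before any C line is
    flagged as an orphan rather than silently dropped.
    """
    ko_to_pathways: dict[str, set[str]] = {}
    pathway_names: dict[str, str] = {}
    orphans: set[str] = set()
    current_pathway: str | None = None
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "+", "!", "%")):
            continue
        if line[0] in "AB":
            current_pathway = None
            continue
        if line[0] == "C":
            m = _KEGG_C.match(line)
            if m:
                current_pathway = m.group(1)
                pathway_names[current_pathway] = m.group(2).strip()
            else:
                current_pathway = None
            continue
        if line[0] == "D":
            m = _KEGG_D.match(line)
            if not m:
                continue
            ko = m.group(1)
            if current_pathway is None:
                orphans.add(ko)
            else:
                ko_to_pathways.setdefault(ko, set()).add(current_pathway)
    return PathwayHierarchy(
        ko_to_pathways={k: frozenset(v) for k, v in ko_to_pathways.items()},
        pathway_names=pathway_names,
        orphan_kos=frozenset(orphans),
    )


def propagate_annotations(
    direct: Mapping[str, Iterable[str]],
    dag: OntologyDAG | PathwayHierarchy,
    enabled: bool = True,
) -> dict[str, set[str]]:
    """Extend each gene's annotations to every ancestor of its direct terms.

    With ``enabled=False`` the direct annotations are returned unchanged
    (as sets).  Terms unknown to the DAG are kept as-is but not propagated.
    """
    out: dict[str, set[str]] = {}
    known = dag.terms if isinstance(dag, OntologyDAG) else dag.ko_to_pathways
    for gene, terms in direct.items():
        expanded = set(terms)
        if enabled:
            for t in list(expanded):
                if t in known:
                    expanded |= dag.ancestors(t)
        out[gene] = expanded
    return out


def build_contingency(
    term: str,
    study_genes: set[str],
    background_genes: set[str],
    annotations: Mapping[str, set[str]],
) -> ContingencyTable:
    """2x2 table for one term given study and background gene sets."""
    if not study_genes <= background_genes:
        extra = sorted(study_genes - background_genes)[:5]
        raise ValueError(f"study genes not in background, e.g. {extra}")
    with_term = {g for g in background_genes if term in annotations.get(g, ())}
    a = len(study_genes & with_term)
    b = len(study_genes) - a
    c = len(with_term) - a
    d = len(background_genes) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p-value.

    Exact integer tail sums are used up to N = 10^4; larger populations use
    the log-space hypergeometric survival function, so the computation never
    overflows for N up to at least 10^6.
    """
    a, N = table.a, table.n
    K, n = table.term_size, table.study_size
    if a == 0:
        return 1.0
    if N <= _EXACT_N_MAX:
        x_max = min(K, n)
        num = sum(math.comb(K, x) * math.comb(N - K, n - x)
                  for x in range(a, x_max + 1))
        return num / math.comb(N, n)
    return float(stats.hypergeom.sf(a - 1, N, K, n))


def fold_enrichment(table: ContingencyTable) -> float:
    """(a/(a+b)) / ((a+c)/N); undefined (error) when the term is empty."""
    if table.term_size == 0:
        raise ValueError("fold enrichment undefined for an empty term")
    if table.study_size == 0:
        raise ValueError("fold enrichment undefined for an empty study set")
    return (table.a / table.study_size) / (table.term_size / table.n)


def run_enrichment(
    study_genes: set[str],
    background_genes: set[str] | None,
    annotations: Mapping[str, set[str]],
    dag: OntologyDAG | PathwayHierarchy | None = None,
    alpha: float = 0.01,
    correction: Literal["none", "bh"] = "none",
    propagate: bool = True,
    two_sided: bool = False,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Fisher-exact enrichment for every term hit by the study set.

    ``background_genes=None`` uses the annotated universe (every gene with at
    least one annotation); study genes without any annotation are then
    outside the population and are dropped from the study set, as is
    conventional for annotated-universe backgrounds.  An explicit background
    is strict: the study must be a subset of it.
    Results cover every term with a >= 1 and are
    sorted by descending fold enrichment, then ascending p.  Significance is
    ``p < alpha`` on the raw p-value (``correction="none"``, mirroring a plain
    p < 0.01 cut) or on Benjamini-Hochberg adjusted values (``"bh"``).
    """
    if not study_genes:
        raise ValueError("study set is empty")
    ann = propagate_annotations(annotations, dag, enabled=True) \
        if (dag is not None and propagate) else {g: set(t) for g, t in annotations.items()}
    if background_genes is None:
        background_genes = {g for g, t in ann.items() if t}
        study_genes = study_genes & background_genes
        if not study_genes:
            raise ValueError("no study gene carries any annotation")
    if not study_genes <= background_genes:
        extra = sorted(study_genes - background_genes)[:5]
        raise ValueError(f"study genes not in background, e.g. {extra}")

    study_terms: set[str] = set()
    for g in study_genes:
        study_terms |= ann.get(g, set())

    results: list[EnrichmentResult] = []
    for term in sorted(study_terms):
        table = build_contingency(term, study_genes, background_genes, ann)
        if table.a == 0:
            continue
        if two_sided:
            p = float(stats.fisher_exact(
                [[table.a, table.b], [table.c, table.d]],
                alternative="two-sided")[1])
        else:
            p = fisher_exact_greater(table)
        name = (term_names or {}).get(term, "")
        if not name and isinstance(dag, OntologyDAG) and term in dag.terms:
            name = dag.terms[term][0]
        results.append(EnrichmentResult(
            term_id=term, term_name=name, table=table, p_value=p,
            fold_enrichment=fold_enrichment(table), significant=False))

    if correction == "bh" and results:
        adjusted = stats.false_discovery_control(
            [r.p_value for r in results], method="bh")
        results = [
            EnrichmentResult(r.term_id, r.term_name, r.table, r.p_value,
                             r.fold_enrichment, bool(adj < alpha), float(adj))
            for r, adj in zip(results, adjusted)
        ]
    else:
        results = [
            EnrichmentResult(r.term_id, r.term_name, r.table, r.p_value,
                             r.fold_enrichment, bool(r.p_value < alpha))
            for r in results
        ]
    results.sort(key=lambda r: (-r.fold_enrichment, r.p_value, r.term_id))
    return results
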