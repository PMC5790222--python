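"""Edge-list parsing and forest export (edge list, DOT, Newick).

The interchange format is a plain text edge list: one edge per line, two
whitespace- or comma-separated node labels, ``#`` starting a comment.
Duplicate lines merge into one edge (with a logged warning) and columns
beyond the second are ignored. Labels are kept verbatim.
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING, Iterable

from .graph import DirectedGraph

if TYPE_CHECKING:  # pragma: no cover
    from .core import ArborescenceResult

__all__ = ["read_edgelist", "write_edgelist", "export_forest", "read_ranking"]

logger = logging.getLogger(__name__)

#: characters that force quoting of a label in Newick output
_NEWICK_RESERVED = set("()[]{}:;,'\" \t\n")

EXPORT_FORMATS = ("edgelist", "dot", "newick")


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",") if f.strip()]
    return line.split()


def read_edgelist(path: str) -> DirectedGraph:
    """Read a directed graph from a plain-text edge list file.

    Raises :class:`ValueError` with the offending line number on a
    non-comment line with fewer than two columns. An empty file yields an
    empty graph.
    """
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    warned_extra = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}"
                )
            if len(fields) > 2 and not warned_extra:
                logger.warning(
                    "%s:%d: ignoring columns beyond the second", path, lineno
                )
                warned_extra = True
            edge = (fields[0], fields[1])
            if edge in seen:
                n_dupes += 1
                continue
            seen.add(edge)
            edges.append(edge)
    if n_dupes:
        logger.warning("%s: merged %d duplicate edge line(s)", path, n_dupes)
    return DirectedGraph.from_edges(edges)


def write_edgelist(g: DirectedGraph, path: str) -> None:
    """Write ``g`` as a tab-separated edge list (isolated nodes as comments)."""
    endpoints = {x for e in g.edges for x in e}
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
        for n in sorted(g.nodes - endpoints):
            fh.write(f"# isolated: {n}\n")


def _newick_label(label: str) -> str:
    if any(c in _NEWICK_RESERVED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_subtree(node: str, children: dict[str, list[str]]) -> str:
    kids = sorted(children.get(node, ()))
    if not kids:
        return _newick_label(node)
    inner = ",".join(_newick_subtree(k, children) for k in kids)
    return f"({inner}){_newick_label(node)}"


def export_forest(result: "ArborescenceResult", fmt: str = "edgelist") -> str:
    """Serialise the arborescence forest of ``result``.

    * ``edgelist`` — the surviving forest edges, tab-separated.
    * ``newick`` — one rooted tree per line (one per forest root), each
      terminated by ``;``; labels containing reserved characters are
      single-quoted.
    * ``dot`` — a Graphviz digraph; multi-member super nodes carry their
      SCC members in the label, edges removed during rooting appear
      dashed.
    """
    forest = result.forest
    if fmt == "edgelist":
        return "".join(f"{u}\t{v}\n" for u, v in sorted(forest.edges))
    if fmt == "newick":
        children: dict[str, list[str]] = {}
        for u, v in forest.edges:
            children.setdefault(u, []).append(v)
        return "".join(
            _newick_subtree(root, children) + ";\n" for root in result.roots
        )
    if fmt == "dot":
        lines = ["digraph arborescence_forest {"]
        cd = result.condensed
        for idx, comp in enumerate(cd.partition.components):
            ident = cd.component_label[idx]
            if len(comp) > 1:
                members = ",".join(sorted(comp))
                lines.append(f'  "{ident}" [label="{ident}\\n{{{members}}}", shape=box];')
            else:
                lines.append(f'  "{ident}";')
        for u, v in sorted(forest.edges):
            lines.append(f'  "{u}" -> "{v}";')
        for u, v in result.removed_in_rooting:
            lines.append(f'  "{u}" -> "{v}" [style=dashed];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")


def read_ranking(path: str) -> dict[str, int]:
    """Read a two-column ``node<TAB>integer_rank`` file (0 = top)."""
    ranks: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'node<TAB>rank'")
            try:
                ranks[fields[0]] = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: rank {fields[1]!r} is not an integer")
    return ranks
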