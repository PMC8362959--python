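"""Bipartite opinion-graph data model and I/O.

A graph-based open-ended survey (GOS) produces a bipartite graph: one vertex
set holds *opinions* (free-format answers, plus any initial choice items) and
the other holds *respondents*; an edge means "this respondent supports this
opinion".  The graph grows incrementally: each respondent is shown a uniform
random sample of the current opinion pool (between 8 and 24 items), supports
any subset of them, and may author new opinions which are attached to the
authoring respondent.

This module provides the in-memory container (:class:`OpinionGraph`), the
incremental construction rule (:meth:`OpinionGraph.add_respondent_response`),
and lossless CSV / GraphML round-trips.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "MIN_DISPLAY",
    "MAX_DISPLAY",
    "OpinionVertex",
    "RespondentVertex",
    "OpinionGraph",
    "ProtocolViolation",
    "EmptyResponseError",
    "SurveyFormatError",
    "read_survey",
    "write_survey",
    "write_graphml",
]

#: Bounds on how many opinions a respondent is shown at once.
MIN_DISPLAY = 8
MAX_DISPLAY = 24


class ProtocolViolation(ValueError):
    """A response referenced opinions that were never displayed."""


class EmptyResponseError(ValueError):
    """A respondent neither supported an opinion nor authored one."""


class SurveyFormatError(ValueError):
    """A survey file violates the tabular interface contract."""


@dataclass(frozen=True)
class OpinionVertex:
    """One opinion: an initial choice item or a respondent-authored answer."""

    opinion_id: str
    text: str
    is_initial: bool
    author_id: str | None
    creation_index: int

    def __post_init__(self) -> None:
        if self.is_initial != (self.author_id is None):
            raise ValueError(
                f"opinion {self.opinion_id!r}: is_initial must hold exactly "
                "when author_id is absent"
            )


@dataclass(frozen=True)
class RespondentVertex:
    """One respondent, with the opinion sample they were shown (if recorded)."""

    respondent_id: str
    arrival_index: int
    displayed: frozenset[str] | None = None


class OpinionGraph:
    """Bipartite graph of opinions and respondents.

    Vertices are kept in insertion order; edges form a simple bipartite graph
    (duplicate supports collapse).  Respondents that submit an empty response
    are never added; callers wanting a record of such events can consult the
    ``rejection_log`` they maintain around :meth:`add_respondent_response`
    (the simulator does exactly that).
    """

    def __init__(self) -> None:
        self.opinions: dict[str, OpinionVertex] = {}
        self.respondents: dict[str, RespondentVertex] = {}
        self.edges: set[tuple[str, str]] = set()
        # adjacency: respondent -> opinions, opinion -> respondents
        self._adj_r: dict[str, set[str]] = {}
        self._adj_o: dict[str, set[str]] = {}
        #: ids of imported respondent rows with zero actions (excluded from the graph)
        self.rejection_log: list[str] = []

    # ------------------------------------------------------------------ sizes
    @property
    def n_opinions(self) -> int:
        return len(self.opinions)

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def opinions_of(self, respondent_id: str) -> frozenset[str]:
        return frozenset(self._adj_r[respondent_id])

    def respondents_of(self, opinion_id: str) -> frozenset[str]:
        return frozenset(self._adj_o[opinion_id])

    # ------------------------------------------------------------ construction
    def _next_opinion_id(self) -> str:
        return f"o{len(self.opinions):05d}"

    def _next_respondent_id(self) -> str:
        return f"r{len(self.respondents):05d}"

    def add_initial_opinion(self, text: str, opinion_id: str | None = None) -> str:
        """Seed the survey with one initial choice item (before any respondent)."""
        oid = opinion_id if opinion_id is not None else self._next_opinion_id()
        if oid in self.opinions or oid in self.respondents:
            raise SurveyFormatError(f"duplicate vertex id {oid!r}")
        self.opinions[oid] = OpinionVertex(
            opinion_id=oid,
            text=text,
            is_initial=True,
            author_id=None,
            creation_index=len(self.opinions),
        )
        self._adj_o[oid] = set()
        return oid

    def add_respondent_response(
        self,
        displayed: Iterable[str],
        supported: Iterable[str],
        new_texts: Sequence[str] = (),
        respondent_id: str | None = None,
    ) -> str:
        """Record one respondent's turn and grow the graph accordingly.

        Creates one respondent vertex, one support edge per supported opinion,
        and one authored opinion vertex (attached to the respondent) per entry
        of ``new_texts``.

        Raises
        ------
        ProtocolViolation
            If ``supported`` is not a subset of ``displayed`` or a displayed
            id does not exist.
        EmptyResponseError
            If the respondent neither supports nor authors anything.
        """
        displayed = frozenset(displayed)
        supported = frozenset(supported)
        unknown = displayed - self.opinions.keys()
        if unknown:
            raise ProtocolViolation(f"displayed ids not in graph: {sorted(unknown)}")
        if not supported <= displayed:
            raise ProtocolViolation(
                f"supported opinions {sorted(supported - displayed)} were not displayed"
            )
        if not supported and not new_texts:
            raise EmptyResponseError("empty response: no support and no new opinion")

        rid = respondent_id if respondent_id is not None else self._next_respondent_id()
        if rid in self.respondents or rid in self.opinions:
            raise SurveyFormatError(f"duplicate vertex id {rid!r}")
        self.respondents[rid] = RespondentVertex(
            respondent_id=rid,
            arrival_index=len(self.respondents),
            displayed=displayed,
        )
        self._adj_r[rid] = set()
        for oid in supported:
            self._add_edge(rid, oid)
        for text in new_texts:
            oid = self._next_opinion_id()
            self.opinions[oid] = OpinionVertex(
                opinion_id=oid,
                text=text,
                is_initial=False,
                author_id=rid,
                creation_index=len(self.opinions),
            )
            self._adj_o[oid] = set()
            self._add_edge(rid, oid)
        return rid

    def _add_edge(self, rid: str, oid: str) -> None:
        self.edges.add((rid, oid))
        self._adj_r[rid].add(oid)
        self._adj_o[oid].add(rid)

    # ---------------------------------------------------------------- queries
    def authored_by(self, respondent_id: str) -> list[str]:
        """Opinion ids authored by the given respondent, in creation order."""
        return [
            o.opinion_id
            for o in self.opinions.values()
            if o.author_id == respondent_id
        ]

    def degree_summary(self) -> tuple[list[int], list[int]]:
        """Degree sequences (opinion side, respondent side), insertion order.

        Each sequence sums to the edge count (handshake lemma on a bipartite
        graph).
        """
        opinion_deg = [len(self._adj_o[oid]) for oid in self.opinions]
        respondent_deg = [len(self._adj_r[rid]) for rid in self.respondents]
        return opinion_deg, respondent_deg

    def validate(self) -> None:
        """Check all structural invariants; raise ``SurveyFormatError`` if violated."""
        if self.opinions.keys() & self.respondents.keys():
            raise SurveyFormatError("vertex id used on both sides")
        for rid, oid in self.edges:
            if rid not in self.respondents or oid not in self.opinions:
                raise SurveyFormatError(f"dangling edge ({rid!r}, {oid!r})")
        for o in self.opinions.values():
            if o.author_id is not None and (o.author_id, o.opinion_id) not in self.edges:
                raise SurveyFormatError(
                    f"authored opinion {o.opinion_id!r} not connected to its author"
                )
        idx = [o.creation_index for o in self.opinions.values()]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise SurveyFormatError("opinion creation indices not strictly increasing")


# ------------------------------------------------------------------------ I/O
def write_survey(
    graph: OpinionGraph,
    opinion_csv: str | Path,
    edge_csv: str | Path,
    respondent_csv: str | Path | None = None,
) -> None:
    """Write the graph as tidy CSV tables (opinions, edges, optionally respondents)."""
    with open(opinion_csv, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["opinion_id", "text", "is_initial", "author_id", "creation_index"])
        for o in graph.opinions.values():
            w.writerow(
                [o.opinion_id, o.text, int(o.is_initial), o.author_id or "", o.creation_index]
            )
    with open(edge_csv, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["respondent_id", "opinion_id"])
        for r in graph.respondents.values():
            for oid in sorted(graph._adj_r[r.respondent_id]):
                w.writerow([r.respondent_id, oid])
    if respondent_csv is not None:
        with open(respondent_csv, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["respondent_id", "arrival_index", "displayed"])
            for r in graph.respondents.values():
                shown = ";".join(sorted(r.displayed)) if r.displayed is not None else ""
                w.writerow([r.respondent_id, r.arrival_index, shown])


def read_survey(
    edge_csv: str | Path,
    opinion_csv: str | Path,
    respondent_csv: str | Path | None = None,
) -> OpinionGraph:
    """Load a survey from its CSV tables into an :class:`OpinionGraph`.

    Respondents present only in the edge file are created with arrival order
    equal to their first appearance.  Unknown opinion ids in the edge file are
    a load error naming the offending row.
    """
    g = OpinionGraph()
    opinions = pd.read_csv(opinion_csv, dtype=str, keep_default_na=False)
    required = {"opinion_id", "text", "is_initial", "author_id", "creation_index"}
    if not required <= set(opinions.columns):
        raise SurveyFormatError(
            f"opinion table missing columns {sorted(required - set(opinions.columns))}"
        )
    opinions = opinions.sort_values("creation_index", key=lambda s: s.astype(int))
    for row in opinions.itertuples(index=False):
        oid = row.opinion_id
        if oid in g.opinions:
            raise SurveyFormatError(f"duplicate opinion_id {oid!r}")
        g.opinions[oid] = OpinionVertex(
            opinion_id=oid,
            text=row.text,
            is_initial=bool(int(row.is_initial)),
            author_id=row.author_id or None,
            creation_index=int(row.creation_index),
        )
        g._adj_o[oid] = set()

    displayed_of: dict[str, frozenset[str]] = {}
    arrival_of: dict[str, int] = {}
    if respondent_csv is not None:
        resp = pd.read_csv(respondent_csv, dtype=str, keep_default_na=False)
        for row in resp.itertuples(index=False):
            arrival_of[row.respondent_id] = int(row.arrival_index)
            if row.displayed:
                displayed_of[row.respondent_id] = frozenset(row.displayed.split(";"))

    with open(edge_csv, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"respondent_id", "opinion_id"} <= set(
            reader.fieldnames
        ):
            raise SurveyFormatError("edge table must have respondent_id,opinion_id columns")
        for lineno, row in enumerate(reader, start=2):
            rid, oid = row["respondent_id"], row["opinion_id"]
            if oid not in g.opinions:
                raise SurveyFormatError(
                    f"{edge_csv}, row {lineno}: unknown opinion_id {oid!r}"
                )
            if rid in g.opinions:
                raise SurveyFormatError(
                    f"{edge_csv}, row {lineno}: id {rid!r} is an opinion id"
                )
            if rid not in g.respondents:
                g.respondents[rid] = RespondentVertex(
                    respondent_id=rid,
                    arrival_index=arrival_of.get(rid, len(g.respondents)),
                    displayed=displayed_of.get(rid),
                )
                g._adj_r[rid] = set()
            g._add_edge(rid, oid)

    # respondent rows with zero actions: rejection-logged, not vertices
    for rid in arrival_of:
        if rid in g.opinions:
            raise SurveyFormatError(f"id {rid!r} appears on both sides")
        if rid not in g.respondents:
            g.rejection_log.append(rid)
    g.validate()
    return g


def to_networkx(graph: OpinionGraph) -> nx.Graph:
    """Represent the survey as a networkx graph with a 0/1 ``bipartite`` attribute."""
    G = nx.Graph()
    for o in graph.opinions.values():
        G.add_node(
            o.opinion_id,
            bipartite=0,
            text=o.text,
            is_initial=int(o.is_initial),
            author_id=o.author_id or "",
            creation_index=o.creation_index,
        )
    for r in graph.respondents.values():
        G.add_node(r.respondent_id, bipartite=1, arrival_index=r.arrival_index)
    G.add_edges_from(graph.edges)
    return G


def write_graphml(graph: OpinionGraph, path: str | Path) -> None:
    """Export to GraphML (opinion vertices carry bipartite=0, respondents 1)."""
    nx.write_graphml(to_networkx(graph), str(path))
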