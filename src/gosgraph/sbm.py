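"""Nonparametric Bayesian stochastic-block-model clustering of opinion graphs.

The clustering objective is a microcanonical description length (DL) for the
non-degree-corrected SBM on a bipartite graph, in the spirit of Peixoto's
nonparametric framework.  For a partition ``b`` with group sizes ``n_r``,
block edge counts ``e_rs`` and ``E`` edges in total:

* partition term, per side with ``N`` vertices in ``B`` groups::

      ln N + ln C(N-1, B-1) + ln( N! / prod_r n_r! )

  (uniform hyperprior over the number of groups, over size compositions, and
  over assignments with those sizes);

* edge-count term: ``ln C(B1*B2 + E - 1, E)``, a uniform prior over the ways
  of distributing ``E`` edges among the ``B1 x B2`` opinion-by-respondent
  group cells;

* graph term: ``sum_rs ln C(n_r * n_s, e_rs)``, the log-number of simple
  bipartite graphs consistent with the block edge counts.

Minimising the sum performs Bayesian model selection: the number of groups
``B`` is an output, never an input.  When per-opinion annotation priors are
supplied, each opinion group is aligned with a single annotation label (the
one maximising the summed log-prior of its members) and the objective gains
``- sum_v log p_v(label of v's group)``, so vertices with similar priors are
pulled into the same group.  Unannotated vertices (uniform prior) contribute
nothing.

Inference is agglomerative initialisation (every vertex its own group,
greedy merges while the DL decreases) followed by annealed single-vertex
Metropolis-Hastings restricted to same-side moves, plus a zero-temperature
polish.  An exhaustive enumeration oracle is provided for graphs of at most
eight vertices.

A degree-corrected variant (Karrer-Newman style block entropy
``- sum_rs e_rs ln(e_rs / (d_r d_s))`` with ``d_r`` the group degree sums)
is available behind a flag; the non-degree-corrected model is the default.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .annotations import PriorVectors
from .opinion_graph import OpinionGraph

__all__ = [
    "Partition",
    "ObjectiveBreakdown",
    "objective",
    "MCMCSampler",
    "mcmc_step",
    "infer",
    "exhaustive_map",
]

_lgamma = math.lgamma


def _lnbinom(n: float, k: float) -> float:
    if k < 0 or k > n:
        raise ValueError(f"binomial coefficient C({n}, {k}) undefined")
    if k == 0 or k == n:
        return 0.0
    return _lgamma(n + 1) - _lgamma(k + 1) - _lgamma(n - k + 1)


@dataclass(frozen=True)
class Partition:
    """Joint group assignment of all vertices; groups never mix sides."""

    group_of: dict[str, int]

    @property
    def B(self) -> int:
        return len(set(self.group_of.values()))

    def labels_for(self, vertex_ids: Iterable[str]) -> list[int]:
        return [self.group_of[v] for v in vertex_ids]

    def canonical(self) -> "Partition":
        """Renumber groups 0..B-1 by first appearance (insertion order)."""
        remap: dict[int, int] = {}
        out = {}
        for v, g in self.group_of.items():
            if g not in remap:
                remap[g] = len(remap)
            out[v] = remap[g]
        return Partition(out)


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Description-length decomposition of a partition's score, in nats."""

    dl_partition: float
    dl_edge_counts: float
    dl_graph_given_partition: float
    log_prior_annotations: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dl_partition": self.dl_partition,
            "dl_edge_counts": self.dl_edge_counts,
            "dl_graph_given_partition": self.dl_graph_given_partition,
            "log_prior_annotations": self.log_prior_annotations,
            "total": self.total,
        }


class MixedSideGroupError(ValueError):
    """A group contained both opinion and respondent vertices."""


# ---------------------------------------------------------------------------
# internal fast state
# ---------------------------------------------------------------------------
class _State:
    """Indexed, incrementally-updated SBM state for one graph."""

    def __init__(
        self,
        graph: OpinionGraph,
        priors: PriorVectors | None = None,
        degree_corrected: bool = False,
    ):
        self.graph = graph
        self.dc = degree_corrected
        self.vids: list[str] = list(graph.opinions) + list(graph.respondents)
        self.index = {v: i for i, v in enumerate(self.vids)}
        self.N1 = graph.n_opinions
        self.N = len(self.vids)
        self.E = graph.n_edges
        self.adj: list[list[int]] = [[] for _ in range(self.N)]
        for rid, oid in graph.edges:
            i, j = self.index[oid], self.index[rid]
            self.adj[i].append(j)
            self.adj[j].append(i)
        self.deg = [len(a) for a in self.adj]

        # annotation log-priors: rows of zeros for unannotated / uniform
        self.K = 0
        self.logp: np.ndarray | None = None
        if priors is not None and priors.space.K > 0:
            self.K = priors.space.K
            logp = np.zeros((self.N1, self.K))
            for i, oid in enumerate(graph.opinions):
                vec = priors.get(oid)
                if vec is not None and (vec.max() - vec.min()) > 1e-15:
                    logp[i] = np.log(vec)
            self.logp = logp

        # mutable partition state (filled by set_partition)
        self.b: list[int] = []
        self.n: dict[int, int] = {}
        self.members: dict[int, set[int]] = {}
        self.blocks: dict[int, Counter] = {}
        self.gdeg: dict[int, int] = {}
        self.side_groups: tuple[list[int], list[int]] = ([], [])
        self.side_pos: tuple[dict[int, int], dict[int, int]] = ({}, {})
        self.S: dict[int, np.ndarray] = {}
        self.label: dict[int, int] = {}
        self._next_gid = 0
        self.total = 0.0

    # ------------------------------------------------------------ bookkeeping
    def side(self, v: int) -> int:
        return 0 if v < self.N1 else 1

    @property
    def B1(self) -> int:
        return len(self.side_groups[0])

    @property
    def B2(self) -> int:
        return len(self.side_groups[1])

    def set_partition(self, groups: list[int]) -> None:
        """Install an assignment (vertex index -> arbitrary group key)."""
        remap: dict[int, int] = {}
        self.b = []
        self.n = {}
        self.members = {}
        self.blocks = {}
        self.gdeg = {}
        self.side_groups = ([], [])
        self.side_pos = ({}, {})
        self.S = {}
        self.label = {}
        for v, g_raw in enumerate(groups):
            key = (self.side(v), g_raw)
            if key not in remap:
                gid = len(remap)
                remap[key] = gid
                self.n[gid] = 0
                self.members[gid] = set()
                self.blocks[gid] = Counter()
                self.gdeg[gid] = 0
                lst, pos = self.side_groups[self.side(v)], self.side_pos[self.side(v)]
                pos[gid] = len(lst)
                lst.append(gid)
                if self.side(v) == 0:
                    self.S[gid] = np.zeros(self.K) if self.K else np.zeros(0)
            gid = remap[key]
            self.b.append(gid)
            self.n[gid] += 1
            self.members[gid].add(v)
            self.gdeg[gid] += self.deg[v]
            if self.side(v) == 0 and self.logp is not None:
                self.S[gid] += self.logp[v]
        self._next_gid = len(remap)
        for v in range(self.N1):
            gv = self.b[v]
            for u in self.adj[v]:
                gu = self.b[u]
                self.blocks[gv][gu] += 1
                self.blocks[gu][gv] += 1
        self.refresh_labels()
        self.total = self.compute_total()

    def singletons(self) -> None:
        self.set_partition(list(range(self.N)))

    def refresh_labels(self) -> None:
        """Re-align each opinion group with its best annotation label."""
        if self.logp is None:
            return
        for g in self.side_groups[0]:
            self.label[g] = int(np.argmax(self.S[g]))

    # ------------------------------------------------------------- objective
    def _cell(self, nr: int, nt: int, e: int, dr: int, dt: int) -> float:
        if e == 0:
            return 0.0
        if self.dc:
            return -e * (math.log(e) - math.log(dr) - math.log(dt))
        return _lnbinom(nr * nt, e)

    def _dl_partition_side(self, side: int) -> float:
        lst = self.side_groups[side]
        Ns = self.N1 if side == 0 else self.N - self.N1
        if Ns == 0:
            return 0.0
        B = len(lst)
        term = math.log(Ns) + _lnbinom(Ns - 1, B - 1) + _lgamma(Ns + 1)
        for g in lst:
            term -= _lgamma(self.n[g] + 1)
        return term

    def _dl_edge_counts(self, B1: int | None = None, B2: int | None = None) -> float:
        B1 = self.B1 if B1 is None else B1
        B2 = self.B2 if B2 is None else B2
        if self.E == 0 or B1 * B2 == 0:
            return 0.0
        return _lnbinom(B1 * B2 + self.E - 1, self.E)

    def log_prior_total(self) -> float:
        if self.logp is None:
            return 0.0
        return float(sum(self.S[g][self.label[g]] for g in self.side_groups[0]))

    def compute_total(self) -> float:
        dl_graph = 0.0
        for g in self.side_groups[0]:
            ng, dg = self.n[g], self.gdeg[g]
            for t, e in self.blocks[g].items():
                dl_graph += self._cell(ng, self.n[t], e, dg, self.gdeg[t])
        return (
            self._dl_partition_side(0)
            + self._dl_partition_side(1)
            + self._dl_edge_counts()
            + dl_graph
            - self.log_prior_total()
        )

    def breakdown(self) -> ObjectiveBreakdown:
        dl_graph = 0.0
        for g in self.side_groups[0]:
            ng, dg = self.n[g], self.gdeg[g]
            for t, e in self.blocks[g].items():
                dl_graph += self._cell(ng, self.n[t], e, dg, self.gdeg[t])
        dl_part = self._dl_partition_side(0) + self._dl_partition_side(1)
        dl_ec = self._dl_edge_counts()
        lp = self.log_prior_total()
        return ObjectiveBreakdown(
            dl_partition=dl_part,
            dl_edge_counts=dl_ec,
            dl_graph_given_partition=dl_graph,
            log_prior_annotations=lp,
            total=dl_part + dl_ec + dl_graph - lp,
        )

    # ------------------------------------------------------------ move delta
    def _neighbor_groups(self, v: int) -> Counter:
        k = Counter()
        b = self.b
        for u in self.adj[v]:
            k[b[u]] += 1
        return k

    def delta_move(self, v: int, s: int | None, k_v: Counter | None = None) -> float:
        """DL change from moving vertex ``v`` to group ``s`` (None = fresh group).

        Group labels are held fixed (fresh groups take the vertex's own best
        label), matching the within-sweep objective of the sampler.
        """
        r = self.b[v]
        if s == r:
            return 0.0
        if k_v is None:
            k_v = self._neighbor_groups(v)
        side = self.side(v)
        n, blocks, gdeg = self.n, self.blocks, self.gdeg
        nr, ns = n[r], (n[s] if s is not None else 0)
        dv = self.deg[v]
        dr_old, dr_new = gdeg[r], gdeg[r] - dv
        ds_old = gdeg[s] if s is not None else 0
        ds_new = ds_old + dv

        d = 0.0
        # graph term: cells touching the source group
        for t, e in blocks[r].items():
            if t == r:  # cannot happen (bipartite) but keep the guard cheap
                continue
            ke = k_v.get(t, 0)
            d -= self._cell(nr, n[t], e, dr_old, gdeg[t])
            d += self._cell(nr - 1, n[t], e - ke, dr_new, gdeg[t])
        # cells touching the target group
        if s is not None:
            touched = set(blocks[s]) | set(k_v)
            for t in touched:
                e = blocks[s].get(t, 0)
                ke = k_v.get(t, 0)
                d -= self._cell(ns, n[t], e, ds_old, gdeg[t])
                d += self._cell(ns + 1, n[t], e + ke, ds_new, gdeg[t])
        else:
            for t, ke in k_v.items():
                d += self._cell(1, n[t], ke, ds_new, gdeg[t])

        # partition term (sizes)
        d += _lgamma(nr + 1) - _lgamma(nr)  # n_r -> n_r - 1
        if s is not None:
            d += _lgamma(ns + 1) - _lgamma(ns + 2)
        # (fresh group of size 1 contributes lgamma(2) = 0)

        # group-count changes
        Bs_old = len(self.side_groups[side])
        Bs_new = Bs_old + (1 if s is None else 0) - (1 if nr == 1 else 0)
        if Bs_new != Bs_old:
            Ns = self.N1 if side == 0 else self.N - self.N1
            d += _lnbinom(Ns - 1, Bs_new - 1) - _lnbinom(Ns - 1, Bs_old - 1)
            if side == 0:
                d += self._dl_edge_counts(B1=Bs_new) - self._dl_edge_counts()
            else:
                d += self._dl_edge_counts(B2=Bs_new) - self._dl_edge_counts()

        # annotation prior (fixed labels; fresh group takes v's best label)
        if side == 0 and self.logp is not None:
            row = self.logp[v]
            lab_s = int(np.argmax(row)) if s is None else self.label[s]
            d -= row[lab_s] - row[self.label[r]]
        return d

    def apply_move(self, v: int, s: int | None, k_v: Counter | None = None) -> int:
        """Execute the move; returns the (possibly fresh) target group id."""
        r = self.b[v]
        if s == r:
            return r
        if k_v is None:
            k_v = self._neighbor_groups(v)
        side = self.side(v)
        if s is None:
            s = self._next_gid
            self._next_gid += 1
            self.n[s] = 0
            self.members[s] = set()
            self.blocks[s] = Counter()
            self.gdeg[s] = 0
            lst, pos = self.side_groups[side], self.side_pos[side]
            pos[s] = len(lst)
            lst.append(s)
            if side == 0:
                self.S[s] = np.zeros(self.K) if self.K else np.zeros(0)
                if self.logp is not None:
                    self.label[s] = int(np.argmax(self.logp[v]))
        self.b[v] = s
        self.n[r] -= 1
        self.n[s] += 1
        self.members[r].discard(v)
        self.members[s].add(v)
        self.gdeg[r] -= self.deg[v]
        self.gdeg[s] += self.deg[v]
        for t, ke in k_v.items():
            self.blocks[r][t] -= ke
            self.blocks[t][r] -= ke
            if self.blocks[r][t] == 0:
                del self.blocks[r][t]
                del self.blocks[t][r]
            self.blocks[s][t] += ke
            self.blocks[t][s] += ke
        if side == 0 and self.logp is not None:
            self.S[r] -= self.logp[v]
            self.S[s] += self.logp[v]
        if self.n[r] == 0:
            self._drop_group(r, side)
        return s

    def _drop_group(self, g: int, side: int) -> None:
        lst, pos = self.side_groups[side], self.side_pos[side]
        i = pos.pop(g)
        last = lst.pop()
        if last != g:
            lst[i] = last
            pos[last] = i
        del self.n[g]
        del self.members[g]
        del self.blocks[g]
        del self.gdeg[g]
        self.S.pop(g, None)
        self.label.pop(g, None)

    # ------------------------------------------------------------ merge delta
    def delta_merge(self, g1: int, g2: int) -> float:
        """DL change from merging same-side groups g1 and g2 (optimal labels)."""
        side = 0 if g1 in self.side_pos[0] else 1
        n, blocks, gdeg = self.n, self.blocks, self.gdeg
        n1, n2 = n[g1], n[g2]
        d1, d2 = gdeg[g1], gdeg[g2]
        d = 0.0
        for t in set(blocks[g1]) | set(blocks[g2]):
            e1 = blocks[g1].get(t, 0)
            e2 = blocks[g2].get(t, 0)
            d -= self._cell(n1, n[t], e1, d1, gdeg[t])
            d -= self._cell(n2, n[t], e2, d2, gdeg[t])
            d += self._cell(n1 + n2, n[t], e1 + e2, d1 + d2, gdeg[t])
        d += _lgamma(n1 + 1) + _lgamma(n2 + 1) - _lgamma(n1 + n2 + 1)
        Ns = self.N1 if side == 0 else self.N - self.N1
        Bs = len(self.side_groups[side])
        d += _lnbinom(Ns - 1, Bs - 2) - _lnbinom(Ns - 1, Bs - 1)
        if side == 0:
            d += self._dl_edge_counts(B1=Bs - 1) - self._dl_edge_counts()
        else:
            d += self._dl_edge_counts(B2=Bs - 1) - self._dl_edge_counts()
        if side == 0 and self.logp is not None:
            merged = self.S[g1] + self.S[g2]
            d -= float(merged.max() - self.S[g1].max() - self.S[g2].max())
        return d

    def apply_merge(self, g1: int, g2: int) -> None:
        """Merge g1 into g2 (moving members keeps all counters consistent)."""
        for v in list(self.members[g1]):
            self.apply_move(v, g2)
        if self.logp is not None and g2 in self.S:
            self.label[g2] = int(np.argmax(self.S[g2]))

    # ------------------------------------------------------------ MCMC moves
    def step(self, rng: np.random.Generator, beta: float) -> bool:
        """One single-vertex Metropolis-Hastings proposal; returns acceptance."""
        v = int(rng.integers(self.N))
        side = self.side(v)
        lst = self.side_groups[side]
        Bs = len(lst)
        j = int(rng.integers(Bs + 1))
        if j == Bs:
            s: int | None = None  # fresh group
        else:
            s = lst[j]
        r = self.b[v]
        if s == r or (s is None and self.n[r] == 1):
            return True  # staying put (fresh from a singleton is a no-op)
        k_v = self._neighbor_groups(v)
        d = self.delta_move(v, s, k_v)
        Bs_new = Bs + (1 if s is None else 0) - (1 if self.n[r] == 1 else 0)
        log_acc = -beta * d + math.log(Bs + 1) - math.log(Bs_new + 1)
        if log_acc >= 0 or rng.random() < math.exp(log_acc):
            self.apply_move(v, s, k_v)
            self.total += d
            return True
        return False

    def sweep(self, rng: np.random.Generator, beta: float) -> None:
        for _ in range(self.N):
            self.step(rng, beta)

    # ----------------------------------------------------- greedy refinement
    def fast_sweep(self, rng: np.random.Generator) -> bool:
        """Cheap greedy pass: one sampled two-hop move candidate per vertex."""
        improved = False
        order = rng.permutation(self.N)
        for v in order:
            if not self.adj[v]:
                continue
            u = self.adj[v][int(rng.integers(len(self.adj[v])))]
            if not self.adj[u]:
                continue
            w = self.adj[u][int(rng.integers(len(self.adj[u])))]
            s = self.b[w]
            if s == self.b[v] or (w == v):
                continue
            k_v = self._neighbor_groups(v)
            d = self.delta_move(v, s, k_v)
            if d < -1e-10:
                self.apply_move(v, s, k_v)
                self.total += d
                improved = True
        return improved

    def polish(self, allow_new: bool = True) -> bool:
        """Zero-temperature pass: best strictly-improving move per vertex.

        ``allow_new=False`` disables moves into fresh groups (used during
        agglomeration, where group counts must only shrink).
        """
        improved = False
        for v in range(self.N):
            side = self.side(v)
            k_v = self._neighbor_groups(v)
            lst = self.side_groups[side]
            if len(lst) > 64:
                # over-fine side: only consider groups two hops away
                cand: list[int | None] = list(
                    {self.b[w] for u in self.adj[v] for w in self.adj[u]}
                )
            else:
                cand = list(lst)
            if allow_new:
                cand = cand + [None]
            best_d, best_s = -1e-10, None
            found = False
            for s in cand:
                if s == self.b[v] or (s is None and self.n[self.b[v]] == 1):
                    continue
                d = self.delta_move(v, s, k_v)
                if d < best_d:
                    best_d, best_s, found = d, s, True
            if found:
                self.apply_move(v, best_s, k_v)
                self.total += best_d
                improved = True
        return improved

    def greedy_merge(self) -> bool:
        """Merge the best same-side pair while the DL strictly decreases."""
        improved = False
        while True:
            best = None
            for side in (0, 1):
                lst = self.side_groups[side]
                for i in range(len(lst)):
                    for j in range(i + 1, len(lst)):
                        d = self.delta_merge(lst[i], lst[j])
                        if d < -1e-10 and (best is None or d < best[0]):
                            best = (d, lst[i], lst[j])
            if best is None:
                return improved
            d, g1, g2 = best
            self.apply_merge(g1, g2)
            self.refresh_labels()
            self.total = self.compute_total()
            improved = True

    def _merge_partners(
        self, g: int, rng: np.random.Generator, candidates: int
    ) -> set[int]:
        """Sample candidate merge partners for ``g`` via two-hop walks."""
        partners: set[int] = set()
        mem = tuple(self.members[g])
        for _ in range(candidates):
            v = mem[int(rng.integers(len(mem)))]
            if self.adj[v]:
                u = self.adj[v][int(rng.integers(len(self.adj[v])))]
                if self.adj[u]:
                    w = self.adj[u][int(rng.integers(len(self.adj[u])))]
                    if self.b[w] != g:
                        partners.add(self.b[w])
        side = 0 if g in self.side_pos[0] else 1
        lst = self.side_groups[side]
        if not partners and len(lst) > 1:
            other = lst[int(rng.integers(len(lst)))]
            if other != g:
                partners.add(other)
        return partners

    def agglomerate(
        self,
        rng: np.random.Generator,
        candidates: int = 3,
        sigma: float = 1.5,
    ) -> None:
        """Multilevel agglomeration from singletons.

        Merging two groups of an over-fine partition usually *raises* the
        description length even when the coarse structure is real (the
        singleton partition fits every edge perfectly), so improvement-only
        merging stalls immediately.  Instead we force the best sampled merges,
        shrinking each side by a factor ``sigma`` per round all the way down
        to one group, score every level, and restore the level with the
        lowest description length.  The subsequent MCMC repairs the greedy
        misassignments.
        """
        best_total = self.compute_total()
        best_b = list(self.b)
        max_rounds = 4 * (1 + int(math.log(max(self.N, 2)) / math.log(sigma)))
        rounds = 0
        while self.B1 + self.B2 > 2 and rounds < max_rounds:
            rounds += 1
            for side in (0, 1):
                lst = self.side_groups[side]
                Bs = len(lst)
                if Bs <= 1:
                    continue
                n_merges = Bs - max(1, int(Bs / sigma))
                proposals: list[tuple[float, int, int]] = []
                for g in list(lst):
                    for p in self._merge_partners(g, rng, candidates):
                        proposals.append((self.delta_merge(g, p), g, p))
                proposals.sort()
                touched: set[int] = set()
                done = 0
                for d, g, p in proposals:
                    if done >= n_merges:
                        break
                    if g in touched or p in touched or g not in self.n or p not in self.n:
                        continue
                    self.apply_merge(g, p)
                    touched.update((g, p))
                    done += 1
                # top up with random pairs if sampling starved the round
                while done < n_merges and len(self.side_groups[side]) > 1:
                    lst2 = self.side_groups[side]
                    g = lst2[int(rng.integers(len(lst2)))]
                    p = lst2[int(rng.integers(len(lst2)))]
                    if g != p:
                        self.apply_merge(g, p)
                        done += 1
            # refine the level before scoring it: forced merges are greedy and
            # misplace vertices, which would make every level look bad
            self.fast_sweep(rng)
            self.fast_sweep(rng)
            if self.B1 + self.B2 <= 40:
                self.polish(allow_new=False)
            self.refresh_labels()
            total = self.compute_total()
            if total < best_total - 1e-12:
                best_total = total
                best_b = list(self.b)
        self.set_partition(best_b)

    # ---------------------------------------------------------------- export
    def to_partition(self) -> Partition:
        return Partition({v: self.b[i] for i, v in enumerate(self.vids)}).canonical()


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------
def _state_from_partition(
    graph: OpinionGraph,
    part: Partition,
    priors: PriorVectors | None,
    degree_corrected: bool = False,
) -> _State:
    state = _State(graph, priors, degree_corrected)
    sides_seen: dict[int, int] = {}
    groups = []
    for i, vid in enumerate(state.vids):
        if vid not in part.group_of:
            raise ValueError(f"partition misses vertex {vid!r}")
        g = part.group_of[vid]
        side = state.side(i)
        if sides_seen.setdefault(g, side) != side:
            raise MixedSideGroupError(f"group {g} mixes opinions and respondents")
        groups.append(g)
    state.set_partition(groups)
    return state


def objective(
    graph: OpinionGraph,
    part: Partition,
    priors: PriorVectors | None = None,
    label_of_group: Mapping[int, int] | None = None,
    degree_corrected: bool = False,
) -> ObjectiveBreakdown:
    """Score a partition: description length minus annotation log-prior.

    Without ``label_of_group`` each opinion group is aligned with the
    annotation label maximising its members' summed log-prior (the optimal
    alignment); an explicit map overrides this.
    """
    state = _state_from_partition(graph, part, priors, degree_corrected)
    if label_of_group is not None and state.logp is not None:
        canon = part.canonical()
        for i, vid in enumerate(state.vids):
            g_user = part.group_of[vid]
            if g_user in label_of_group:
                state.label[state.b[i]] = label_of_group[g_user]
        del canon
    return state.breakdown()


def group_annotation_labels(
    graph: OpinionGraph,
    part: Partition,
    priors: PriorVectors,
) -> dict[int, str]:
    """Aligned annotation label ("annotator:category") per opinion group.

    The label of a group is the one maximising its members' summed
    log-prior — the same alignment the objective uses.  Groups with no
    annotated member are omitted.
    """
    state = _state_from_partition(graph, part, priors)
    out: dict[int, str] = {}
    if state.logp is None:
        return out
    names = priors.space.header_names()
    for i, vid in enumerate(state.vids[: state.N1]):
        g_user = part.group_of[vid]
        gid = state.b[i]
        if g_user not in out and np.any(state.S[gid] != 0):
            out[g_user] = names[int(np.argmax(state.S[gid]))]
    return out


class MCMCSampler:
    """Stateful single-vertex Metropolis-Hastings sampler over partitions.

    Proposals move one vertex to a uniformly chosen same-side group (or a
    fresh group) and are accepted with probability
    ``min(1, exp(-beta * dDL) * (B_side + 1) / (B_side' + 1))``; the count
    correction makes the chain satisfy detailed balance with respect to
    ``exp(-beta * total)`` over side-respecting partitions.
    """

    def __init__(
        self,
        graph: OpinionGraph,
        part: Partition,
        priors: PriorVectors | None = None,
        degree_corrected: bool = False,
    ):
        self.state = _state_from_partition(graph, part, priors, degree_corrected)

    def step(self, rng: np.random.Generator, beta: float = 1.0) -> bool:
        return self.state.step(rng, beta)

    @property
    def partition(self) -> Partition:
        return self.state.to_partition()

    @property
    def total(self) -> float:
        return self.state.total


def mcmc_step(
    graph: OpinionGraph,
    part: Partition,
    priors: PriorVectors | None,
    rng: np.random.Generator,
    beta: float = 1.0,
) -> tuple[Partition, bool]:
    """One Metropolis-Hastings proposal from ``part``; convenience wrapper.

    For long chains prefer :class:`MCMCSampler`, which keeps its state
    between steps instead of rebuilding it.
    """
    sampler = MCMCSampler(graph, part, priors)
    accepted = sampler.step(rng, beta)
    return sampler.partition, accepted


def infer(
    graph: OpinionGraph,
    priors: PriorVectors | None = None,
    n_sweeps: int = 40,
    n_restarts: int = 10,
    seed: int = 0,
    beta_range: tuple[float, float] = (1.0, 5.0),
    degree_corrected: bool = False,
) -> tuple[Partition, ObjectiveBreakdown]:
    """Best-of-restarts annealed MCMC minimisation of the description length.

    Each restart starts from singleton groups, greedily agglomerates while
    the DL decreases, anneals ``n_sweeps`` MCMC sweeps with the inverse
    temperature rising geometrically over ``beta_range``, then applies
    zero-temperature polish (single-vertex moves and pairwise merges) until a
    local minimum is reached.  The lowest total over restarts wins.  The
    number of groups is inferred, never supplied.
    """
    if graph.n_opinions + graph.n_respondents == 0:
        raise ValueError("empty graph")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    betas = np.geomspace(beta_range[0], beta_range[1], n_sweeps)
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best: tuple[float, Partition, ObjectiveBreakdown] | None = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        state = _State(graph, priors, degree_corrected)
        state.singletons()
        state.agglomerate(rng)
        for beta in betas:
            state.sweep(rng, float(beta))
            state.refresh_labels()
            state.total = state.compute_total()
        for _ in range(50):
            moved = state.polish()
            state.refresh_labels()
            state.total = state.compute_total()
            merged = state.greedy_merge()
            if not moved and not merged:
                break
        bd = state.breakdown()
        if best is None or bd.total < best[0] - 1e-12:
            best = (bd.total, state.to_partition(), bd)
    assert best is not None
    return best[1], best[2]


def _set_partitions(items: list[int]):
    """All set partitions of ``items`` in canonical (restricted-growth) order."""
    if not items:
        yield []
        return

    def rec(i: int, blocks: list[list[int]]):
        if i == len(items):
            yield [list(b) for b in blocks]
            return
        for b in blocks:
            b.append(items[i])
            yield from rec(i + 1, blocks)
            b.pop()
        blocks.append([items[i]])
        yield from rec(i + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def exhaustive_map(
    graph: OpinionGraph,
    priors: PriorVectors | None = None,
    degree_corrected: bool = False,
) -> tuple[Partition, ObjectiveBreakdown]:
    """Global minimum of the objective by enumerating all same-side partitions.

    Refuses graphs with more than eight vertices (the state space grows as a
    product of Bell numbers).  Ties are broken by enumeration order, which is
    canonical.
    """
    n_total = graph.n_opinions + graph.n_respondents
    if n_total > 8:
        raise ValueError(f"exhaustive search refused for {n_total} > 8 vertices")
    if n_total == 0:
        raise ValueError("empty graph")
    vids = list(graph.opinions) + list(graph.respondents)
    o_idx = list(range(graph.n_opinions))
    r_idx = list(range(graph.n_opinions, n_total))
    state = _State(graph, priors, degree_corrected)
    best: tuple[float, list[int]] | None = None
    for po in _set_partitions(o_idx):
        for pr in _set_partitions(r_idx):
            groups = [0] * n_total
            gi = 0
            for block in po + pr:
                for v in block:
                    groups[v] = gi
                gi += 1
            state.set_partition(groups)
            t = state.total
            if best is None or t < best[0] - 1e-12:
                best = (t, list(groups))
    assert best is not None
    state.set_partition(best[1])
    part = Partition({vids[i]: best[1][i] for i in range(n_total)}).canonical()
    return part, state.breakdown()
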