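"""Summary surfaces computed from a clustered opinion graph.

Three views of a clustering result:

* the *posting rate* — how many respondents authored their own opinion rather
  than only selecting existing ones;
* the *propensity matrix* — an opinion-group by respondent-group table where
  entry (i, j) is the fraction of respondent group j's edges that land in
  opinion group i (each column normalised to one);
* *palette profiles* — one probability vector per respondent giving the share
  of their supports in each opinion group, drawn as a stacked-area "palette
  diagram" after reordering respondents so that similar profiles sit next to
  each other (adjacent-L1 seriation via greedy nearest neighbour plus 2-opt).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .opinion_graph import OpinionGraph
from .sbm import Partition

__all__ = [
    "PostingRate",
    "PropensityMatrix",
    "PaletteProfileSet",
    "posting_rate",
    "posting_percentage",
    "propensity_matrix",
    "respondent_profiles",
    "order_profiles",
    "render_outputs",
]


@dataclass(frozen=True)
class PostingRate:
    authors: int
    total: int
    percentage: float  # 100 * authors / total, round-half-up to 1 decimal
    status: str = "ok"


def posting_percentage(authors: int, total: int) -> float:
    """Percentage of respondents who authored an opinion, round-half-up to 0.1."""
    if total == 0:
        raise ValueError("empty survey: no respondents")
    pct = decimal.Decimal(100 * authors) / decimal.Decimal(total)
    return float(pct.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def posting_rate(graph: OpinionGraph) -> PostingRate:
    """Count respondents with at least one authored opinion."""
    if graph.n_respondents == 0:
        return PostingRate(0, 0, float("nan"), status="empty survey")
    authors = len({o.author_id for o in graph.opinions.values() if o.author_id})
    return PostingRate(
        authors, graph.n_respondents, posting_percentage(authors, graph.n_respondents)
    )


@dataclass
class PropensityMatrix:
    """Column-normalised edge fractions between opinion and respondent groups."""

    values: np.ndarray  # shape (n opinion groups, n respondent groups)
    row_labels: list[str]
    col_labels: list[str]
    flagged_columns: list[str] = field(default_factory=list)  # zero-edge columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


def _split_groups(graph: OpinionGraph, part: Partition) -> tuple[list[int], list[int]]:
    """Sorted distinct group indices on each side; raises on missing vertices."""
    o_groups = sorted({part.group_of[o] for o in graph.opinions})
    r_groups = sorted({part.group_of[r] for r in graph.respondents})
    return o_groups, r_groups


def propensity_matrix(
    graph: OpinionGraph,
    part: Partition,
    n_rows: int | None = None,
) -> PropensityMatrix:
    """Edge fractions e[i, j] / sum_i e[i, j] between group pairs.

    ``n_rows`` pads with empty (all-zero) opinion-group rows so that tables
    from different surveys share a row count.  Columns whose respondent group
    has no incident edges are flagged and emitted as zeros, never NaN.
    """
    o_groups, r_groups = _split_groups(graph, part)
    oi = {g: i for i, g in enumerate(o_groups)}
    ri = {g: j for j, g in enumerate(r_groups)}
    counts = np.zeros((len(o_groups), len(r_groups)))
    for rid, oid in graph.edges:
        counts[oi[part.group_of[oid]], ri[part.group_of[rid]]] += 1

    col_sums = counts.sum(axis=0)
    values = np.zeros_like(counts)
    nonzero = col_sums > 0
    values[:, nonzero] = counts[:, nonzero] / col_sums[nonzero]
    flagged = [f"R{g}" for g, ok in zip(r_groups, nonzero) if not ok]

    row_labels = [f"G{g}" for g in o_groups]
    if n_rows is not None:
        if n_rows < len(o_groups):
            raise ValueError("n_rows smaller than the number of opinion groups")
        pad = n_rows - len(o_groups)
        values = np.vstack([values, np.zeros((pad, values.shape[1]))])
        row_labels += [f"Gpad{k}" for k in range(pad)]
    return PropensityMatrix(
        values=values,
        row_labels=row_labels,
        col_labels=[f"R{g}" for g in r_groups],
        flagged_columns=flagged,
    )


@dataclass
class PaletteProfileSet:
    """Per-respondent opinion-group propensity profiles plus a display order."""

    profiles: pd.DataFrame  # rows: respondents, columns: opinion groups, rows sum to 1
    ordering: list[str]
    objective_value: float
    excluded: list[str] = field(default_factory=list)  # degree-0 respondents


def respondent_profiles(graph: OpinionGraph, part: Partition) -> PaletteProfileSet:
    """Normalised per-respondent support shares over opinion groups.

    Respondents with no edges cannot be normalised; they are excluded and
    listed in ``excluded``.  The initial ordering is arrival order with
    objective equal to its adjacent-L1 dissimilarity (call
    :func:`order_profiles` to optimise it).
    """
    o_groups, _ = _split_groups(graph, part)
    oi = {g: i for i, g in enumerate(o_groups)}
    rows: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for rid in graph.respondents:
        edges = graph.opinions_of(rid)
        if not edges:
            excluded.append(rid)
            continue
        vec = np.zeros(len(o_groups))
        for oid in edges:
            vec[oi[part.group_of[oid]]] += 1
        rows[rid] = vec / vec.sum()
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=[f"G{g}" for g in o_groups])
    ordering = list(profiles.index)
    return PaletteProfileSet(
        profiles=profiles,
        ordering=ordering,
        objective_value=_path_length(profiles.to_numpy(), np.arange(len(ordering))),
        excluded=excluded,
    )


def _path_length(X: np.ndarray, order: np.ndarray) -> float:
    if len(order) < 2:
        return 0.0
    P = X[order]
    return float(np.abs(np.diff(P, axis=0)).sum())


def order_profiles(
    profiles: pd.DataFrame | PaletteProfileSet,
    seed: int = 0,
    max_rounds: int | None = None,
) -> tuple[list[str], float]:
    """Seriation of the profiles: minimise total adjacent L1 dissimilarity.

    Greedy nearest-neighbour construction from a seeded random start, then
    2-opt segment reversals until no improving reversal exists (or
    ``max_rounds`` passes).  The result is never worse than the input order.
    """
    if isinstance(profiles, PaletteProfileSet):
        profiles = profiles.profiles
    ids = list(profiles.index)
    X = profiles.to_numpy()
    n = len(ids)
    if n <= 2:
        return ids, _path_length(X, np.arange(n))

    D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    rng = np.random.default_rng(seed)
    starts = list(range(n)) if n <= 12 else [int(rng.integers(n))]
    if max_rounds is None:
        max_rounds = 10_000 if n <= 64 else 150

    best_order, best_len = np.arange(n), _path_length(X, np.arange(n))
    for start in starts:
        order = _greedy_path(D, start)
        order = _two_opt(D, order, max_rounds)
        length = _path_length(X, order)
        if length < best_len - 1e-15:
            best_order, best_len = order, length
    return [ids[k] for k in best_order], best_len


def _greedy_path(D: np.ndarray, start: int) -> np.ndarray:
    n = D.shape[0]
    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(n - 1):
        d = D[order[-1]].copy()
        d[visited] = np.inf
        nxt = int(np.argmin(d))
        order.append(nxt)
        visited[nxt] = True
    return np.array(order)


def _two_opt(D: np.ndarray, order: np.ndarray, max_rounds: int) -> np.ndarray:
    """Best-improvement 2-opt on an open path until no reversal helps."""
    n = len(order)
    for _ in range(max_rounds):
        P = order
        de = D[P[:-1], P[1:]]
        # gain[i, j] of reversing P[i..j], 1 <= i <= j <= n-2:
        # new edges (i-1 -> j) and (i -> j+1) replace (i-1 -> i), (j -> j+1)
        i_idx = np.arange(1, n - 1)
        j_idx = np.arange(1, n - 1)
        M1 = D[np.ix_(P[i_idx - 1], P[j_idx])]
        M2 = D[np.ix_(P[i_idx], P[j_idx + 1])]
        gain = M1 + M2 - de[i_idx - 1, None] - de[None, j_idx]
        gain[np.tril_indices(n - 2, k=-1)] = np.inf
        k = int(np.argmin(gain))
        i, j = divmod(k, n - 2)
        if gain[i, j] >= -1e-12:
            break
        ii, jj = i_idx[i], j_idx[j]
        order = np.concatenate([order[:ii], order[ii : jj + 1][::-1], order[jj + 1 :]])
    return order


def render_outputs(
    matrix: PropensityMatrix,
    palette: PaletteProfileSet,
    out_dir: str | Path,
    image_format: str = "png",
) -> dict[str, Path]:
    """Write propensity.csv, profiles.csv, ordering.csv and the palette image.

    CSV content is deterministic for identical inputs.  The palette diagram
    is a stacked-area chart with one vertical slice per respondent in the
    optimised order.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["propensity"] = out_dir / "propensity.csv"
    matrix.to_frame().to_csv(paths["propensity"], float_format="%.10g")

    paths["profiles"] = out_dir / "profiles.csv"
    palette.profiles.to_csv(paths["profiles"], float_format="%.10g")

    paths["ordering"] = out_dir / "ordering.csv"
    pd.DataFrame(
        {"position": range(len(palette.ordering)), "respondent_id": palette.ordering}
    ).to_csv(paths["ordering"], index=False)

    ordered = palette.profiles.loc[palette.ordering]
    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(ordered))
    ax.stackplot(x, ordered.to_numpy().T, labels=list(ordered.columns), lw=0)
    ax.set_xlim(0, max(len(ordered) - 1, 1))
    ax.set_ylim(0, 1)
    ax.set_xlabel("respondents (seriated)")
    ax.set_ylabel("propensity")
    ax.legend(loc="upper right", fontsize=6, ncol=2)
    paths["palette"] = out_dir / f"palette.{image_format}"
    fig.savefig(paths["palette"], dpi=120)
    plt.close(fig)
    return paths
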