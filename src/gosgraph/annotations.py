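"""Annotation labels, per-vertex prior vectors, and inter-annotator agreement.

Opinions are hand-coded by a small set of annotators into ten fixed
categories.  Annotators work independently and disagree, so instead of fusing
their labels we keep every distinct ``(annotator, category)`` pair as its own
dimension: with three annotators the label space has at most K = 30
dimensions.  Each opinion vertex then receives a K-dimensional prior
probability vector over these labels — a large element eta on each label the
vertex actually holds and a small element epsilon elsewhere, normalised to
one; unannotated vertices get the uniform vector.  These priors are what the
block-model inference consumes to sharpen the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "CATEGORIES",
    "AnnotationSet",
    "LabelSpace",
    "PriorVectors",
    "build_label_space",
    "build_prior_vectors",
    "pairwise_agreement",
]

#: The ten fixed coding categories for opinions.
CATEGORIES: tuple[str, ...] = (
    "infection risk",
    "social pressure & future prospect",
    "financial issues",
    "travel",
    "government policies",
    "mask (shortage)",
    "mask (discomfort)",
    "other issues",
    "no concerns",
    "invalid responses",
)

_CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


class AnnotationError(ValueError):
    """An annotation record violates the label contract."""


@dataclass
class AnnotationSet:
    """Per-opinion category labels from up to a few annotators.

    At most one record per ``(opinion_id, annotator_id)``; categories must be
    among the ten fixed names.  Opinions an annotator could not place in a
    single category are simply absent from that annotator's records.
    """

    records: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, opinion_id: str, annotator_id: str, category: str) -> None:
        if category not in _CATEGORY_INDEX:
            raise AnnotationError(f"unknown category {category!r}")
        key = (opinion_id, annotator_id)
        if key in self.records:
            raise AnnotationError(f"duplicate annotation for {key}")
        self.records[key] = category

    @property
    def annotators(self) -> list[str]:
        return sorted({a for (_, a) in self.records})

    @property
    def opinion_ids(self) -> set[str]:
        return {o for (o, _) in self.records}

    def labels_of(self, opinion_id: str) -> list[tuple[str, str]]:
        """All (annotator, category) labels held by one opinion."""
        return [
            (a, c) for (o, a), c in self.records.items() if o == opinion_id
        ]

    def by_annotator(self, annotator_id: str) -> dict[str, str]:
        return {o: c for (o, a), c in self.records.items() if a == annotator_id}

    def __len__(self) -> int:
        return len(self.records)

    # -------------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"opinion_id": o, "annotator_id": a, "category": c}
            for (o, a), c in sorted(self.records.items())
        ]
        return pd.DataFrame(rows, columns=["opinion_id", "annotator_id", "category"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationSet":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        ann = cls()
        for row in df.itertuples(index=False):
            ann.add(row.opinion_id, row.annotator_id, row.category)
        return ann


@dataclass(frozen=True)
class LabelSpace:
    """Ordered list of the (annotator, category) pairs actually in use."""

    labels: tuple[tuple[str, str], ...]

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def is_empty(self) -> bool:
        """True when no annotations exist at all (K = 0)."""
        return not self.labels

    def index(self, annotator_id: str, category: str) -> int:
        return self.labels.index((annotator_id, category))

    def header_names(self) -> list[str]:
        return [f"{a}:{c}" for a, c in self.labels]


def build_label_space(ann: AnnotationSet, n_annotators: int | None = None) -> LabelSpace:
    """Collect the realized label space from an annotation set.

    Ordering is deterministic: annotators sorted by id, categories in their
    fixed listing order.  K never exceeds ``n_annotators * 10``.
    """
    used = {(a, c) for (_, a), c in ann.records.items()}
    labels = tuple(
        sorted(used, key=lambda ac: (ac[0], _CATEGORY_INDEX[ac[1]]))
    )
    space = LabelSpace(labels)
    if n_annotators is not None and space.K > n_annotators * len(CATEGORIES):
        raise AnnotationError(
            f"K={space.K} exceeds {n_annotators} annotators x {len(CATEGORIES)} categories"
        )
    return space


class PriorVectors(dict):
    """Mapping ``opinion_id -> K-vector`` of prior probabilities.

    Also records the label space used and which vertices were flagged as
    degenerate (they hold every label, so the prior collapses to uniform).
    """

    def __init__(self, space: LabelSpace):
        super().__init__()
        self.space = space
        self.degenerate: set[str] = set()

    def log_prior_matrix(self, opinion_ids: Iterable[str]) -> np.ndarray:
        """Stack log-priors for the given opinions; rows of zeros for absentees."""
        K = self.space.K
        out = np.zeros((len(list(opinion_ids := list(opinion_ids))), K))
        for i, oid in enumerate(opinion_ids):
            if oid in self:
                out[i] = np.log(self[oid])
        return out

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame.from_dict(
            {oid: vec for oid, vec in self.items()}, orient="index",
            columns=self.space.header_names(),
        )
        df.index.name = "opinion_id"
        df.sort_index().to_csv(path)


def build_prior_vectors(
    ann: AnnotationSet,
    space: LabelSpace,
    mass_on_labels: float = 0.99,
    opinion_ids: Iterable[str] | None = None,
) -> PriorVectors:
    """Build the per-opinion prior vectors over the realized label space.

    A vertex holding ``m >= 1`` of the K labels gets ``mass_on_labels / m``
    (eta) on each held label and ``(1 - mass_on_labels) / (K - m)`` (epsilon)
    elsewhere, so the vector sums to one with eta >> epsilon.  A vertex with
    no labels gets the uniform vector 1/K.  A vertex holding *all* K labels is
    forced uniform and flagged as degenerate.

    Parameters
    ----------
    opinion_ids
        When given, uniform vectors are also emitted for listed opinions that
        carry no annotation; otherwise only annotated opinions appear.
    """
    if space.K < 1:
        raise AnnotationError("no annotations: label space is empty")
    if not 0.5 < mass_on_labels < 1.0:
        raise ValueError("mass_on_labels must lie in (0.5, 1)")
    K = space.K
    label_idx = {lab: k for k, lab in enumerate(space.labels)}

    held: dict[str, list[int]] = {}
    for (oid, a), c in ann.records.items():
        held.setdefault(oid, []).append(label_idx[(a, c)])

    out = PriorVectors(space)
    for oid, idxs in held.items():
        m = len(idxs)
        if m == K:
            out[oid] = np.full(K, 1.0 / K)
            out.degenerate.add(oid)
            continue
        vec = np.full(K, (1.0 - mass_on_labels) / (K - m))
        vec[idxs] = mass_on_labels / m
        out[oid] = vec
    if opinion_ids is not None:
        for oid in opinion_ids:
            if oid not in out:
                out[oid] = np.full(K, 1.0 / K)
    return out


def pairwise_agreement(ann: AnnotationSet) -> pd.DataFrame:
    """Raw agreement and Cohen's kappa for every annotator pair.

    Computed only over opinions both annotators labeled.  Pairs with no
    jointly annotated opinion get status ``"no overlap"`` and NaN statistics.
    """
    annotators = ann.annotators
    if len(annotators) < 2:
        raise AnnotationError("pairwise agreement needs at least two annotators")
    rows = []
    for i, a in enumerate(annotators):
        for b in annotators[i + 1 :]:
            la, lb = ann.by_annotator(a), ann.by_annotator(b)
            shared = sorted(la.keys() & lb.keys())
            if not shared:
                rows.append(
                    {"annotator_a": a, "annotator_b": b, "n_shared": 0,
                     "agreement": np.nan, "kappa": np.nan, "status": "no overlap"}
                )
                continue
            xa = [la[o] for o in shared]
            xb = [lb[o] for o in shared]
            agree = float(np.mean([p == q for p, q in zip(xa, xb)]))
            # kappa is undefined when either rater uses a single category on
            # every shared item and they fully agree; report 1.0 there
            if agree == 1.0 and len(set(xa)) == 1:
                kappa = 1.0
            else:
                kappa = float(cohen_kappa_score(xa, xb))
            rows.append(
                {"annotator_a": a, "annotator_b": b, "n_shared": len(shared),
                 "agreement": agree, "kappa": kappa, "status": "ok"}
            )
    return pd.DataFrame(rows)
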