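"""Within-community annotation coherence versus a random-grouping null.

A community partition is deemed coherent with respect to an annotation
(meridian or property label sets for herbs; SMILES strings or protein-target
sets for ingredients) when members of the same community are more similar to
each other than entities grouped at random.  For each cluster with at least
two annotated members the mean pairwise similarity is computed; the null
distribution pools the same per-cluster means over ``n_replicates`` uniform
permutations of the entity -> cluster assignment (cluster sizes preserved);
the two samples are compared with a two-sided Wilcoxon rank-sum test.

Similarity of set-valued annotations defaults to the overlap coefficient
|A&B| / min(|A|,|B|), with Jaccard as an alternative; strings are tokenized
into character-bigram sets and compared with the Dice index
2|A&B| / (|A|+|B|).  The tokenizer is pluggable (e.g. chemical fingerprints).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .community import Partition
from .errors import AnnotationError, ParseError, ValidationError
from .estimators import CoherenceValidator, rank_sum_test

logger = logging.getLogger(__name__)

KINDS = ("label_set", "string", "id_set")

# default set metric for set-valued kinds; strings always use Dice on tokens
DEFAULT_METRIC = {"label_set": "overlap", "id_set": "overlap", "string": "dice"}

__all__ = [
    "AnnotationTable",
    "ClusterSimilarity",
    "ValidationReport",
    "bigram_tokenizer",
    "pair_similarity",
    "cluster_similarity",
    "random_grouping_null",
    "rank_sum_test",
    "validate",
]


def bigram_tokenizer(s: str) -> frozenset[str]:
    """Character-bigram set of a string; a 1-character string is its own token."""
    if not s:
        return frozenset()
    if len(s) < 2:
        return frozenset({s})
    return frozenset(s[i : i + 2] for i in range(len(s) - 1))


@dataclass
class AnnotationTable:
    """Entity -> annotation payload, typed by kind.

    ``kind`` is one of ``label_set`` (e.g. meridians, properties), ``string``
    (SMILES) or ``id_set`` (protein targets).  Payloads must be non-empty;
    entities without an annotation are simply absent from ``payload`` and
    are flagged by downstream consumers rather than silently dropped.
    """

    kind: str
    payload: dict[str, frozenset | str]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise AnnotationError(f"unknown annotation kind {self.kind!r}")
        for entity, value in self.payload.items():
            if self.kind == "string":
                if not isinstance(value, str) or not value:
                    raise AnnotationError(f"empty string payload for {entity!r}")
            else:
                value = frozenset(value)
                if not value:
                    raise AnnotationError(f"empty set payload for {entity!r}")
                self.payload[entity] = value

    def __len__(self) -> int:
        return len(self.payload)

    def write(self, path: str | Path, delimiter: str = "\t", sep: str = "|") -> None:
        with open(path, "w") as fh:
            fh.write(f"entity_id{delimiter}payload\n")
            for entity in sorted(self.payload):
                value = self.payload[entity]
                text = value if isinstance(value, str) else sep.join(sorted(value))
                fh.write(f"{entity}{delimiter}{text}\n")

    @classmethod
    def read(
        cls, path: str | Path, kind: str, delimiter: str = "\t", sep: str = "|"
    ) -> "AnnotationTable":
        path = Path(path)
        if not path.exists():
            raise ParseError(f"annotation file not found: {path}")
        payload: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split(delimiter)
                if lineno == 1 and fields[0].lower() == "entity_id":
                    continue
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise ParseError(
                        f"{path}:{lineno}: expected entity_id and payload"
                    )
                entity, raw = fields[0].strip(), fields[1].strip()
                payload[entity] = (
                    raw if kind == "string" else frozenset(raw.split(sep))
                )
        return cls(kind=kind, payload=payload)


@dataclass
class ClusterSimilarity:
    """Mean pairwise annotation similarity of one cluster."""

    cluster: int
    n_members: int
    n_annotated: int
    mean_similarity: float


@dataclass
class ValidationReport:
    """Observed vs null coherence of a partition for one annotation kind."""

    kind: str
    metric: str
    observed: list[ClusterSimilarity]
    null_values: list[float]
    observed_median: float
    null_median: float
    statistic: float
    p_value: float
    n_replicates: int
    seed: int | None
    n_unannotated: int = 0
    excluded_clusters: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_values_tsv(self, path: str | Path) -> None:
        """Long-format observed/null values for external plotting."""
        with open(path, "w") as fh:
            fh.write("group\tvalue\n")
            for cs in self.observed:
                fh.write(f"observed\t{cs.mean_similarity:.10g}\n")
            for v in self.null_values:
                fh.write(f"null\t{v:.10g}\n")


def _tokenize(
    value, kind: str, tokenizer: Callable[[str], Iterable] | None
) -> frozenset:
    if kind == "string":
        return frozenset((tokenizer or bigram_tokenizer)(value))
    return frozenset(value)


def pair_similarity(
    a,
    b,
    kind: str,
    metric: str | None = None,
    tokenizer: Callable[[str], Iterable] | None = None,
) -> float:
    """Similarity in [0, 1] of two annotation payloads.

    Set kinds use the overlap coefficient by default (``metric="jaccard"``
    selects Jaccard); strings are tokenized (character bigrams by default)
    and compared with the Dice index.
    """
    if kind not in KINDS:
        raise AnnotationError(f"unknown annotation kind {kind!r}")
    metric = metric or DEFAULT_METRIC[kind]
    ta, tb = _tokenize(a, kind, tokenizer), _tokenize(b, kind, tokenizer)
    if not ta or not tb:
        raise AnnotationError("cannot compare empty annotation payloads")
    inter = len(ta & tb)
    if metric == "overlap":
        return inter / min(len(ta), len(tb))
    if metric == "jaccard":
        return inter / len(ta | tb)
    if metric == "dice":
        return 2.0 * inter / (len(ta) + len(tb))
    raise ValueError(f"unknown similarity metric {metric!r}")


def _indicator_matrix(
    entities: list[str],
    ann: AnnotationTable,
    tokenizer: Callable[[str], Iterable] | None,
) -> np.ndarray:
    """Binary entity x token matrix over the union of observed tokens."""
    tokensets = [_tokenize(ann.payload[e], ann.kind, tokenizer) for e in entities]
    universe = sorted(set().union(*tokensets))
    col = {t: j for j, t in enumerate(universe)}
    X = np.zeros((len(entities), len(universe)))
    for i, ts in enumerate(tokensets):
        for t in ts:
            X[i, col[t]] = 1.0
    return X


def _prepare(p: Partition, ann: AnnotationTable, tokenizer):
    """Align a partition with an annotation table.

    Returns annotated entities (sorted), their labels, the indicator matrix,
    and the count of partition entities lacking an annotation.
    """
    entities = sorted(e for e in p.assignment if e in ann.payload)
    n_unannotated = len(p.assignment) - len(entities)
    if n_unannotated:
        logger.info(
            "validation: %d of %d entities lack a %s annotation and are excluded",
            n_unannotated, len(p.assignment), ann.kind,
        )
    if len(entities) < 2:
        raise ValidationError("fewer than two annotated entities; nothing to compare")
    labels = np.array([p.assignment[e] for e in entities])
    X = _indicator_matrix(entities, ann, tokenizer)
    return entities, labels, X, n_unannotated


def cluster_similarity(
    p: Partition,
    ann: AnnotationTable,
    metric: str | None = None,
    tokenizer: Callable[[str], Iterable] | None = None,
) -> list[ClusterSimilarity]:
    """Per-cluster mean pairwise similarity over annotated members.

    Clusters with fewer than two annotated members are excluded (and
    logged).  Raises if no cluster is evaluable.
    """
    metric = metric or DEFAULT_METRIC[ann.kind]
    entities, labels, X, _ = _prepare(p, ann, tokenizer)
    sizes = {lab: members for lab, members in p.communities.items()}
    uniq, counts = np.unique(labels, return_counts=True)
    evaluable = uniq[counts >= 2]
    if evaluable.size == 0:
        raise ValidationError("no cluster has two or more annotated members")
    skipped = [lab for lab in sizes if lab not in set(evaluable.tolist())]
    if skipped:
        logger.info("cluster_similarity: excluded clusters %s (<2 annotated)", skipped)
    from .estimators import pairwise_similarity_matrix, _cluster_means

    S = pairwise_similarity_matrix(X, metric)
    order = np.argsort(labels, kind="stable")
    means = _cluster_means(S, order, counts.tolist())
    out = []
    for lab, n_ann, m in zip(evaluable, counts[counts >= 2], means):
        out.append(
            ClusterSimilarity(
                cluster=int(lab),
                n_members=len(sizes[int(lab)]),
                n_annotated=int(n_ann),
                mean_similarity=float(m),
            )
        )
    return out


def random_grouping_null(
    p: Partition,
    ann: AnnotationTable,
    n_replicates: int = 100,
    seed: int | None = None,
    metric: str | None = None,
    tokenizer: Callable[[str], Iterable] | None = None,
) -> np.ndarray:
    """Pooled per-cluster mean similarities under random regrouping.

    Each replicate permutes the entity -> cluster assignment uniformly at
    random, preserving the multiset of cluster sizes, and recomputes the
    per-cluster means of evaluable clusters; values are pooled across
    replicates.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    metric = metric or DEFAULT_METRIC[ann.kind]
    entities, labels, X, _ = _prepare(p, ann, tokenizer)
    from .estimators import pairwise_similarity_matrix, _cluster_means

    S = pairwise_similarity_matrix(X, metric)
    _, counts = np.unique(labels, return_counts=True)
    rng = np.random.default_rng(seed)
    n = len(entities)
    null = [
        _cluster_means(S, rng.permutation(n), counts.tolist())
        for _ in range(n_replicates)
    ]
    return np.concatenate(null)


def validate(
    p: Partition,
    ann: AnnotationTable,
    n_replicates: int = 100,
    seed: int | None = None,
    metric: str | None = None,
    tokenizer: Callable[[str], Iterable] | None = None,
) -> ValidationReport:
    """Full coherence test: observed vs random-grouping null, rank-sum p.

    Composes :func:`cluster_similarity`, :func:`random_grouping_null` and
    :func:`rank_sum_test`; reports both medians and the two-sided p-value.
    """
    metric = metric or DEFAULT_METRIC[ann.kind]
    entities, labels, X, n_unannotated = _prepare(p, ann, tokenizer)
    est = CoherenceValidator(
        metric=metric, n_replicates=n_replicates, random_state=seed
    ).fit(X, labels)
    sizes = p.communities
    observed = [
        ClusterSimilarity(
            cluster=int(lab),
            n_members=len(sizes[int(lab)]),
            n_annotated=int(n_ann),
            mean_similarity=float(m),
        )
        for lab, n_ann, m in zip(est.cluster_ids_, est.cluster_sizes_, est.observed_)
    ]
    excluded = sorted(set(sizes) - {cs.cluster for cs in observed})
    if excluded:
        logger.info("validate: excluded clusters %s (<2 annotated members)", excluded)
    return ValidationReport(
        kind=ann.kind,
        metric=metric,
        observed=observed,
        null_values=[float(v) for v in est.null_values_],
        observed_median=est.observed_median_,
        null_median=est.null_median_,
        statistic=est.statistic_,
        p_value=est.p_value_,
        n_replicates=n_replicates,
        seed=seed,
        n_unannotated=n_unannotated,
        excluded_clusters=excluded,
    )
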