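"""Supervised training-set construction for the patch scorer.

Each antibody-antigen complex contributes:

* the real epitope-paratope pair (target 1);
* up to 10 non-redundant Monte Carlo patches with overlap target > 0.0075,
  Hobohm-1 reduced (<60% residue overlap) after sorting by target;
* up to 50 non-redundant patches with target <= 0.0075, unsorted;
* 10 mis-paired examples (the real epitope with paratopes of antibodies from
  other antibody clusters, target 0).

The overlap target of a patch is precision x recall against the true epitope
residue set, so it is 1 for a perfect patch and 0 for a disjoint one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .features import PatchDescriptor
from .structure_io import Patch

__all__ = [
    "POSITIVE_TARGET_THRESHOLD",
    "HOBOHM_OVERLAP",
    "TrainingExample",
    "PartitionScheme",
    "ComplexData",
    "target_value",
    "hobohm_reduce",
    "build_training_set",
    "make_mispairs",
    "greedy_cluster",
    "merge_clusters",
    "assign_partitions",
]

logger = logging.getLogger(__name__)

POSITIVE_TARGET_THRESHOLD = 0.0075  # strictly above -> positive band
HOBOHM_OVERLAP = 0.60  # accept iff overlap fraction < 0.60
MAX_POSITIVES = 10
MAX_BACKGROUND = 50
N_MISPAIRS = 10


@dataclass
class TrainingExample:
    """One supervised example: an antigen patch paired with a paratope."""

    antigen_desc: PatchDescriptor
    paratope_desc: PatchDescriptor
    target: float
    provenance: str  # real | mc_overlap | mc_background | mispair
    complex_id: str
    partition: int
    patch: Patch | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target <= 1.0:
            raise ValueError("target must be in [0, 1]")
        if self.provenance == "mispair" and self.target != 0.0:
            raise ValueError("mis-pair target must be 0")
        if self.provenance == "real" and self.target != 1.0:
            raise ValueError("real-pair target must be 1")


@dataclass
class PartitionScheme:
    """Complex -> cross-validation partition map plus cluster bookkeeping."""

    partition_of: dict[str, int]
    cluster_of: dict[str, int]  # merged antigen-antibody cluster per complex
    independent_test: set[str] = field(default_factory=set)

    def partitions(self) -> list[int]:
        return sorted(set(self.partition_of.values()))

    def validate(self) -> None:
        """Clusters must never span two partitions."""
        seen: dict[int, int] = {}
        for cid, cluster in self.cluster_of.items():
            if cid in self.independent_test:
                continue
            part = self.partition_of[cid]
            if cluster in seen and seen[cluster] != part:
                raise ValueError(f"cluster {cluster} spans partitions")
            seen[cluster] = part


@dataclass
class ComplexData:
    """Everything the training-set builder needs about one complex."""

    complex_id: str
    epitope: Patch
    paratope_desc: PatchDescriptor
    epitope_desc: PatchDescriptor
    mc_patches: list[Patch]
    antibody_cluster: int
    antigen_cluster: int
    partition: int
    featurize: Callable[[Patch], PatchDescriptor]


# ---------------------------------------------------------------------------
# targets and redundancy reduction
# ---------------------------------------------------------------------------

def target_value(patch: Patch, epitope: Patch) -> float:
    """Precision x recall of a patch's residue set against the true epitope."""
    if len(patch) == 0 or len(epitope) == 0:
        raise ValueError("patch and epitope must be non-empty")
    if patch.role != epitope.role:
        raise ValueError("patch and epitope must be on the same molecule")
    inter = len(patch.residue_set & epitope.residue_set)
    precision = inter / len(patch)
    recall = inter / len(epitope)
    return precision * recall


def _overlap_fraction(candidate: frozenset, accepted: frozenset, mode: str) -> float:
    inter = len(candidate & accepted)
    if mode == "candidate":
        denom = len(candidate)
    elif mode == "smaller":
        denom = min(len(candidate), len(accepted))
    elif mode == "union":
        denom = len(candidate | accepted)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return inter / denom if denom else 0.0


def hobohm_reduce(
    patches: Sequence[tuple[Patch, float]],
    overlap_threshold: float = HOBOHM_OVERLAP,
    sort_by_score: bool = True,
    overlap_mode: str = "candidate",
) -> list[tuple[Patch, float]]:
    """Greedy Hobohm-1 style redundancy reduction.

    Iterates the patches (sorted by score descending when ``sort_by_score``,
    else in input order) and accepts a patch iff its residue-overlap fraction
    with every previously accepted patch is strictly below the threshold.
    """
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValueError("overlap threshold must be in (0, 1]")
    items = list(patches)
    if sort_by_score:
        items.sort(key=lambda ps: -ps[1])
    accepted: list[tuple[Patch, float]] = []
    for patch, score in items:
        cand = patch.residue_set
        if all(_overlap_fraction(cand, acc.residue_set, overlap_mode) < overlap_threshold
               for acc, _ in accepted):
            accepted.append((patch, score))
    return accepted


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

def make_mispairs(
    complex_data: ComplexData,
    antibody_pool: Sequence[tuple[PatchDescriptor, int, str]],
    n: int = N_MISPAIRS,
    rng: np.random.Generator | None = None,
) -> list[TrainingExample]:
    """Pair the real epitope with paratopes from other antibody clusters.

    ``antibody_pool`` holds ``(paratope_desc, antibody_cluster, complex_id)``
    tuples; ``n`` draws without replacement among entries whose antibody
    cluster differs from the query's.
    """
    rng = rng or np.random.default_rng()
    eligible = [entry for entry in antibody_pool
                if entry[1] != complex_data.antibody_cluster]
    if not eligible:
        warnings.warn(f"{complex_data.complex_id}: no eligible mis-pair paratopes")
        return []
    k = min(n, len(eligible))
    if k < n:
        logger.info("%s: mis-pair pool smaller than %d (%d)",
                    complex_data.complex_id, n, k)
    picks = rng.choice(len(eligible), size=k, replace=False)
    out = []
    for i in picks:
        para, _, _src = eligible[int(i)]
        out.append(TrainingExample(
            antigen_desc=complex_data.epitope_desc,
            paratope_desc=para,
            target=0.0,
            provenance="mispair",
            complex_id=complex_data.complex_id,
            partition=complex_data.partition,
        ))
    return out


def build_training_set(
    complexes: Sequence[ComplexData],
    rng: np.random.Generator | None = None,
    max_positives: int = MAX_POSITIVES,
    max_background: int = MAX_BACKGROUND,
    n_mispairs: int = N_MISPAIRS,
) -> list[TrainingExample]:
    """Assemble the full training set across complexes."""
    rng = rng or np.random.default_rng()
    pool = [(c.paratope_desc, c.antibody_cluster, c.complex_id) for c in complexes]
    examples: list[TrainingExample] = []
    for c in complexes:
        examples.append(TrainingExample(
            antigen_desc=c.epitope_desc,
            paratope_desc=c.paratope_desc,
            target=1.0,
            provenance="real",
            complex_id=c.complex_id,
            partition=c.partition,
            patch=c.epitope,
        ))
        scored = [(p, target_value(p, c.epitope)) for p in c.mc_patches]
        positives = [(p, t) for p, t in scored if t > POSITIVE_TARGET_THRESHOLD]
        background = [(p, t) for p, t in scored if t <= POSITIVE_TARGET_THRESHOLD]
        kept_pos = hobohm_reduce(positives, sort_by_score=True)[:max_positives]
        kept_bg = hobohm_reduce(background, sort_by_score=False)[:max_background]
        if not kept_pos:
            logger.info("%s: no epitope-overlapping patches above %.4f",
                        c.complex_id, POSITIVE_TARGET_THRESHOLD)
        for kept, tag in ((kept_pos, "mc_overlap"), (kept_bg, "mc_background")):
            for patch, t in kept:
                examples.append(TrainingExample(
                    antigen_desc=c.featurize(patch),
                    paratope_desc=c.paratope_desc,
                    target=t,
                    provenance=tag,
                    complex_id=c.complex_id,
                    partition=c.partition,
                    patch=patch,
                ))
        examples.extend(make_mispairs(c, pool, n=n_mispairs, rng=rng))
    return examples


# ---------------------------------------------------------------------------
# clustering and partitioning
# ---------------------------------------------------------------------------

def _pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def greedy_cluster(sequences: Sequence[str], identity_threshold: float) -> list[int]:
    """Greedy length-sorted clustering by representative identity.

    A sequence joins the first existing cluster whose representative it
    matches at >= the identity threshold, else founds a new cluster.
    Returns a cluster id per input sequence.
    """
    if any(not s for s in sequences):
        raise ValueError("empty sequence")
    order = sorted(range(len(sequences)), key=lambda i: -len(sequences[i]))
    reps: list[str] = []
    labels = [0] * len(sequences)
    for i in order:
        seq = sequences[i]
        for cid, rep in enumerate(reps):
            if _pairwise_identity(seq, rep) >= identity_threshold:
                labels[i] = cid
                break
        else:
            labels[i] = len(reps)
            reps.append(seq)
    return labels


def merge_clusters(
    antibody_clusters: Sequence[int], antigen_clusters: Sequence[int]
) -> list[int]:
    """Union-find merge: complexes sharing either cluster share a merged id."""
    n = len(antibody_clusters)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_ab: dict[int, int] = {}
    by_ag: dict[int, int] = {}
    for i in range(n):
        if antibody_clusters[i] in by_ab:
            union(by_ab[antibody_clusters[i]], i)
        else:
            by_ab[antibody_clusters[i]] = i
        if antigen_clusters[i] in by_ag:
            union(by_ag[antigen_clusters[i]], i)
        else:
            by_ag[antigen_clusters[i]] = i
    roots = {find(i) for i in range(n)}
    relabel = {r: k for k, r in enumerate(sorted(roots))}
    return [relabel[find(i)] for i in range(n)]


def assign_partitions(
    merged_clusters: Sequence[int],
    n_partitions: int = 5,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Randomly split merged clusters into partitions; clusters stay intact."""
    rng = rng or np.random.default_rng()
    unique = sorted(set(merged_clusters))
    shuffled = list(rng.permutation(unique))
    part_of_cluster = {c: (i % n_partitions) + 1 for i, c in enumerate(shuffled)}
    return [part_of_cluster[c] for c in merged_clusters]
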