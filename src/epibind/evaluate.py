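"""Ranking benchmarks: F_rank, epitope ranking, antibody/antigen pairing.

F_rank of a target among decoys is the fraction of decoys scored above it
(ties count half), so 0 is a perfect prediction and 0.5 a random one. The
pairing benchmarks rank the true paratope among alternative paratopes (and
symmetrically the true epitope among alternative epitopes), optionally
restricted to paratopes of similar shape (K-means on the paratope principal
components) and optionally scoring candidates through the mean of the top 5
Monte Carlo patch predictions instead of the true epitope patch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import PatchDescriptor
from .structure_io import Patch, ResidueId

__all__ = [
    "RankReport",
    "StructureRecord",
    "f_rank",
    "epitope_rank_benchmark",
    "pairing_ranks",
    "residue_sum_patch_score",
    "reduce_patches_for_docking_comparison",
    "HO_TARGET_THRESHOLD",
]

logger = logging.getLogger(__name__)

HO_TARGET_THRESHOLD = 0.25  # target value above which a patch is "highly overlapping"
DOCKING_SHARE_THRESHOLD = 0.35


@dataclass
class RankReport:
    """Per-structure rank fractions plus their summary statistics."""

    per_structure: pd.DataFrame
    summary: dict[str, float]

    def to_json_dict(self) -> dict:
        return {"summary": self.summary,
                "per_structure": self.per_structure.to_dict(orient="records")}


@dataclass
class StructureRecord:
    """One test-set complex with its candidate patches, ready for ranking."""

    complex_id: str
    cluster: int
    epitope_desc: PatchDescriptor
    paratope_desc: PatchDescriptor
    mc_descs: list[PatchDescriptor]
    mc_targets: list[float]


def f_rank(target_score: float, decoy_scores: Sequence[float], ties: str = "half") -> float:
    """Fraction of decoys scoring above the target (ties count half by default)."""
    decoys = np.asarray(decoy_scores, dtype=float)
    if decoys.size == 0:
        raise ValueError("f_rank needs at least one decoy")
    higher = np.sum(decoys > target_score)
    tied = np.sum(decoys == target_score)
    if ties == "half":
        return float((higher + 0.5 * tied) / decoys.size)
    if ties == "strict":
        return float((higher + tied) / decoys.size)
    raise ValueError(f"unknown tie mode {ties!r}")


def epitope_rank_benchmark(
    score_fn: Callable[[PatchDescriptor, PatchDescriptor], float],
    structures: Sequence[StructureRecord],
) -> RankReport:
    """Epitope Rank and First HO Rank per structure.

    Epitope Rank is the F_rank of the real epitope-paratope pair against the
    structure's Monte Carlo patches. First HO Rank is the F_rank of the best-
    scoring highly overlapping patch (target > 0.25) against the remaining
    patches; it is missing when no HO patch was generated.
    """
    rows = []
    for s in structures:
        mc_scores = np.array([score_fn(d, s.paratope_desc) for d in s.mc_descs])
        epi_score = score_fn(s.epitope_desc, s.paratope_desc)
        row = {
            "complex_id": s.complex_id,
            "epitope_score": epi_score,
            "epitope_rank": f_rank(epi_score, mc_scores),
        }
        ho = [i for i, t in enumerate(s.mc_targets) if t > HO_TARGET_THRESHOLD]
        if ho:
            best = max(ho, key=lambda i: mc_scores[i])
            others = np.delete(mc_scores, best)
            row["first_ho_rank"] = f_rank(mc_scores[best], others) if others.size else 0.0
        else:
            row["first_ho_rank"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    ho = df["first_ho_rank"].dropna()
    summary = {
        "epitope_rank_mean": float(df["epitope_rank"].mean()),
        "epitope_rank_median": float(df["epitope_rank"].median()),
        "first_ho_rank_mean": float(ho.mean()) if len(ho) else float("nan"),
        "first_ho_rank_median": float(ho.median()) if len(ho) else float("nan"),
        "n_structures": int(len(df)),
    }
    return RankReport(per_structure=df, summary=summary)


def _top_m_mean(scores: np.ndarray, m: int) -> float:
    top = np.sort(scores)[::-1][:m]
    return float(top.mean())


def pairing_ranks(
    score_fn: Callable[[PatchDescriptor, PatchDescriptor], float],
    pool: Sequence[StructureRecord],
    mode: str = "antibody",
    k_clusters: int = 5,
    top_m: int = 5,
    seed: int = 0,
) -> RankReport:
    """Rank the true partner of each complex within a candidate pool.

    Modes: ``antibody`` ranks the true paratope among paratopes of complexes
    from other clusters, paired with the query's epitope; ``antigen`` is the
    symmetric epitope ranking against the true paratope; ``similar_antibody``
    restricts the antibody mode to the query's K-means cluster of paratope
    principal components; ``mc_antibody`` / ``mc_antigen`` score a candidate
    by the mean of its top ``top_m`` Monte Carlo patch predictions before
    ranking, restricted to the same PC cluster.
    """
    if mode not in ("antibody", "antigen", "similar_antibody", "mc_antibody", "mc_antigen"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    if len(pool) < 2:
        raise ValueError("pairing needs a pool of at least 2 complexes")

    pc_cluster = None
    if mode in ("similar_antibody", "mc_antibody", "mc_antigen"):
        from sklearn.cluster import KMeans

        pcs = np.array([s.paratope_desc.pc for s in pool])
        k = min(k_clusters, len(pool))
        pc_cluster = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pcs)

    rows = []
    for qi, query in enumerate(pool):
        candidates = []
        for ci, cand in enumerate(pool):
            if ci == qi:
                continue
            if mode in ("antibody", "antigen", "similar_antibody") and cand.cluster == query.cluster:
                continue  # "different epitopes": other merged clusters only
            if pc_cluster is not None and pc_cluster[ci] != pc_cluster[qi]:
                continue
            candidates.append((ci, cand))
        if not candidates:
            logger.info("%s: singleton pool in mode %s, skipped", query.complex_id, mode)
            continue

        if mode in ("antibody", "similar_antibody"):
            true_score = score_fn(query.epitope_desc, query.paratope_desc)
            decoys = [score_fn(query.epitope_desc, c.paratope_desc) for _, c in candidates]
        elif mode == "antigen":
            true_score = score_fn(query.epitope_desc, query.paratope_desc)
            decoys = [score_fn(c.epitope_desc, query.paratope_desc) for _, c in candidates]
        elif mode == "mc_antibody":
            mc = query.mc_descs
            true_score = _top_m_mean(
                np.array([score_fn(d, query.paratope_desc) for d in mc]), top_m)
            decoys = [
                _top_m_mean(np.array([score_fn(d, c.paratope_desc) for d in mc]), top_m)
                for _, c in candidates
            ]
        else:  # mc_antigen
            true_score = _top_m_mean(
                np.array([score_fn(d, query.paratope_desc) for d in query.mc_descs]), top_m)
            decoys = [
                _top_m_mean(
                    np.array([score_fn(d, query.paratope_desc) for d in c.mc_descs]), top_m)
                for _, c in candidates
            ]
        rows.append({
            "complex_id": query.complex_id,
            "true_score": true_score,
            "n_candidates": len(candidates),
            "rank": f_rank(true_score, decoys),
        })
    df = pd.DataFrame(rows)
    summary = {
        "rank_mean": float(df["rank"].mean()) if len(df) else float("nan"),
        "rank_median": float(df["rank"].median()) if len(df) else float("nan"),
        "n_queries": int(len(df)),
        "mode": mode,
    }
    return RankReport(per_structure=df, summary=summary)


def residue_sum_patch_score(
    residue_scores: dict[ResidueId, float], patch: Patch
) -> float:
    """Sum of per-residue scores over patch residues (adapter for tools that
    score residues, not patches); missing residues contribute 0."""
    total = 0.0
    missing = 0
    for rid in patch.residues:
        if rid in residue_scores:
            total += residue_scores[rid]
        else:
            missing += 1
    if missing:
        warnings.warn(f"{missing} patch residues missing from the score table")
    return total


def reduce_patches_for_docking_comparison(
    scored_patches: Sequence[tuple[Patch, float]],
    share_threshold: float = DOCKING_SHARE_THRESHOLD,
) -> list[tuple[Patch, float]]:
    """Greedy reduction of a prediction-sorted patch list: drop any patch
    sharing >= 35% of its residues with a better-scoring kept patch."""
    ordered = sorted(scored_patches, key=lambda ps: -ps[1])
    kept: list[tuple[Patch, float]] = []
    for patch, score in ordered:
        cand = patch.residue_set
        share = max(
            (len(cand & acc.residue_set) / len(cand) for acc, _ in kept),
            default=0.0,
        )
        if share < share_threshold:  # >= threshold is excluded
            kept.append((patch, score))
    return kept
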