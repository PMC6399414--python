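"""Paratope-conditioned Metropolis Monte Carlo generation of surface patches.

Candidate epitope patches are grown on the antigen surface graph by a
simulated-annealing Metropolis walk. Each move adds a residue neighboring the
patch, removes a patch residue, or swaps one for a neighbor, and is accepted
with probability ``min(exp(-dE/T), 1)``. The energy measures how far six
patch/paratope ratio features deviate from their values on real
epitope-paratope pairs:

    E = sum_i ((X_i - mean_i) / sigma_i)^2

where the X_i are the PC1, PC2, PC3 ratios (patch : paratope), the size
ratio, the summed-surface-area ratio, and the density ratio (paratope :
patch, as stated). The temperature starts at 20 and is multiplied by 0.985
after every one of the 500 steps (final T ~ 0.01045); 300 independent
simulations per antigen each contribute their final patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import PatchDescriptor
from .structure_io import Patch, ResidueId, StructureModel, SurfaceGraph

__all__ = [
    "ENERGY_FEATURES",
    "EnergyStats",
    "MCConfig",
    "MCState",
    "fit_energy_stats",
    "energy_features",
    "patch_energy",
    "metropolis_accept",
    "mc_step",
    "generate_patches",
]

ENERGY_FEATURES = (
    "pc1_ratio", "pc2_ratio", "pc3_ratio",
    "size_ratio", "surface_ratio", "density_ratio",
)

_SIGMA_FLOOR = 1e-6
_DENSITY_FLOOR = 1e-3  # a 1-residue patch has density 0; keep the ratio finite


@dataclass
class EnergyStats:
    """Per-feature mean and s.d. of the six epitope/paratope ratio features."""

    means: np.ndarray  # (6,)
    sigmas: np.ndarray  # (6,)
    provenance: tuple = ()

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.maximum(np.asarray(self.sigmas, dtype=float), _SIGMA_FLOOR)
        if self.means.shape != (6,) or self.sigmas.shape != (6,):
            raise ValueError("EnergyStats requires 6 features")

    @classmethod
    def default(cls) -> "EnergyStats":
        """Uninformed prior for single-complex runs: ratios ~ 1 +/- 0.25."""
        return cls(means=np.ones(6), sigmas=np.full(6, 0.25))


@dataclass
class MCConfig:
    """Annealing schedule and run size."""

    t0: float = 20.0
    cooling: float = 0.985
    iterations: int = 500
    patches: int = 300
    seed: int = 0

    @property
    def final_temperature(self) -> float:
        return self.t0 * self.cooling ** self.iterations


@dataclass
class MCState:
    """Current patch, its energy, temperature and step counter."""

    patch: set[int]  # residue indices into the antigen surface arrays
    energy: float
    temperature: float
    iteration: int = 0
    move_log: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def _paratope_summary(paratope_desc: PatchDescriptor) -> np.ndarray:
    vals = np.array([
        paratope_desc.pc[0], paratope_desc.pc[1], paratope_desc.pc[2],
        paratope_desc.size, paratope_desc.total_sasa, paratope_desc.density,
    ], dtype=float)
    if np.any(vals[:5] <= 0):
        raise ValueError("zero-valued paratope denominator in energy features")
    return vals


def energy_features(
    pcs: np.ndarray,
    size: float,
    surface: float,
    density: float,
    paratope: np.ndarray,
) -> np.ndarray:
    """The six ratio features of a patch summary against a paratope summary."""
    return np.array([
        pcs[0] / paratope[0],
        pcs[1] / paratope[1],
        pcs[2] / paratope[2],
        size / paratope[3],
        surface / paratope[4],
        paratope[5] / max(density, _DENSITY_FLOOR),  # paratope : patch
    ])


def patch_energy(
    patch: Patch,
    model: StructureModel,
    graph: SurfaceGraph,
    paratope_desc: PatchDescriptor,
    stats: EnergyStats,
) -> float:
    """Energy of an explicit Patch object (reference implementation)."""
    from .features import geometry_features

    pc1, pc2, pc3, size, density = geometry_features(patch, model, graph)
    surface = float(sum(model.residue_sasa(rid) for rid in patch.residues))
    x = energy_features(np.array([pc1, pc2, pc3]), size, surface, density,
                        _paratope_summary(paratope_desc))
    z = (x - stats.means) / stats.sigmas
    return float(np.sum(z * z))


def fit_energy_stats(real_pairs, heldout_partition=None) -> EnergyStats:
    """Mean/sigma of the six ratio features over real epitope-paratope pairs.

    ``real_pairs`` is an iterable of ``(epitope_desc, paratope_desc,
    partition_id)``; pairs from ``heldout_partition`` are excluded so patch
    generation for a partition never uses its own complexes.
    """
    rows = []
    used = []
    for epi, para, part in real_pairs:
        if heldout_partition is not None and part == heldout_partition:
            continue
        x = energy_features(epi.pc, epi.size, epi.total_sasa, epi.density,
                            _paratope_summary(para))
        rows.append(x)
        used.append(part)
    if len(rows) < 2:
        raise ValueError("need at least 2 real pairs outside the held-out partition")
    arr = np.asarray(rows)
    return EnergyStats(
        means=arr.mean(axis=0),
        sigmas=arr.std(axis=0, ddof=0),
        provenance=tuple(used),
    )


# ---------------------------------------------------------------------------
# Metropolis dynamics
# ---------------------------------------------------------------------------

def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(exp(-dE/T), 1)."""
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


class _AntigenSurface:
    """Indexed arrays of the antigen's exposed residues for fast energy evaluation."""

    def __init__(self, model: StructureModel, graph: SurfaceGraph):
        antigen_nodes = [rid for rid in graph.nodes
                         if model.role_of_chain(rid.chain) == "antigen"]
        if not antigen_nodes:
            raise ValueError("antigen has no exposed residues")
        self.rids: list[ResidueId] = antigen_nodes
        index = {rid: i for i, rid in enumerate(antigen_nodes)}
        self.ca = model.ca_coordinates(antigen_nodes)
        self.res_sasa = np.array([model.residue_sasa(rid) for rid in antigen_nodes])
        self.adj: list[set[int]] = [
            {index[n] for n in graph.neighbors(rid) if n in index}
            for rid in antigen_nodes
        ]

    def energy(self, members: set[int], paratope: np.ndarray, stats: EnergyStats) -> float:
        idx = list(members)
        ca = self.ca[idx]
        if len(idx) >= 2:
            centered = ca - ca.mean(axis=0)
            cov = centered.T @ centered / len(idx)
            eig = np.sqrt(np.maximum(np.linalg.eigvalsh(cov), 0.0))[::-1]
        else:
            eig = np.zeros(3)
        size = float(len(idx))
        surface = float(self.res_sasa[idx].sum())
        density = float(np.mean([len(self.adj[i] & members) for i in idx]))
        x = energy_features(eig, size, surface, density, paratope)
        z = (x - stats.means) / stats.sigmas
        return float(np.sum(z * z))

    def boundary(self, members: set[int]) -> set[int]:
        out: set[int] = set()
        for i in members:
            out |= self.adj[i]
        return out - members


def mc_step(
    state: MCState,
    surface: _AntigenSurface,
    paratope: np.ndarray,
    stats: EnergyStats,
    rng: np.random.Generator,
    cooling: float,
    log_moves: bool = False,
) -> MCState:
    """One Metropolis move with cooling applied afterwards (even on rejection)."""
    members = state.patch
    boundary = surface.boundary(members)
    legal = []
    if boundary:
        legal.append("add")
    if len(members) > 1:
        legal.append("remove")
    if boundary and members:
        legal.append("swap")
    move = legal[rng.integers(len(legal))] if legal else None

    proposal = set(members)
    added = removed = None
    if move == "add":
        added = sorted(boundary)[rng.integers(len(boundary))]
        proposal.add(added)
    elif move == "remove":
        removed = sorted(members)[rng.integers(len(members))]
        proposal.discard(removed)
    elif move == "swap":
        removed = sorted(members)[rng.integers(len(members))]
        added = sorted(boundary)[rng.integers(len(boundary))]
        proposal.discard(removed)
        proposal.add(added)

    accepted = False
    if move is not None:
        e_new = surface.energy(proposal, paratope, stats)
        delta = e_new - state.energy
        if metropolis_accept(delta, state.temperature, rng):
            state.patch = proposal
            state.energy = e_new
            accepted = True
    if log_moves:
        state.move_log.append((move, added, removed, accepted))
    state.temperature *= cooling
    state.iteration += 1
    return state


def generate_patches(
    model: StructureModel,
    graph: SurfaceGraph,
    paratope_desc: PatchDescriptor,
    stats: EnergyStats,
    config: MCConfig | None = None,
    log_moves: bool = False,
) -> list[Patch]:
    """Run ``config.patches`` independent annealing simulations on the antigen
    surface; each starts from a random exposed residue and contributes its
    final patch."""
    config = config or MCConfig()
    surface = _AntigenSurface(model, graph)
    paratope = _paratope_summary(paratope_desc)
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=config.patches)

    patches: list[Patch] = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        start = int(rng.integers(len(surface.rids)))
        members = {start}
        state = MCState(
            patch=members,
            energy=surface.energy(members, paratope, stats),
            temperature=config.t0,
        )
        if log_moves:
            state.move_log.append(("start", start, None, True))
        for _ in range(config.iterations):
            mc_step(state, surface, paratope, stats, rng, config.cooling, log_moves)
        rids = tuple(sorted(surface.rids[i] for i in state.patch))
        p = Patch("antigen", rids)
        if log_moves:
            p = (p, state.move_log)  # type: ignore[assignment]
        patches.append(p)
    return patches
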