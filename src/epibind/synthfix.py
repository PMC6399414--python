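"""Deterministic synthetic antibody-antigen pseudo-complexes.

Each pseudo-complex is two hollow shells of 5-heavy-atom pseudo-residues
(N, CA, C, O, CB) facing each other across a >6 A gap, with a planted
interface: designated residue pairs are pulled into the gap so that their
CB atoms sit 3.2-3.8 A apart while every other cross-chain atom pair stays
clearly above the 4 A contact cutoff. The planted residue sets are the
ground-truth epitope and paratope, so the whole pipeline (parsing, SASA,
interface extraction, patch generation, training, ranking) can be exercised
and verified without any real structure.

Interface residues are drawn from an aromatic/charged-biased amino-acid
composition, mimicking the enrichment seen at real antibody interfaces and
giving the scorer a learnable compositional signal; the rest of the surface
uses a uniform composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import InterfacePair, Patch, ResidueId

__all__ = ["FixtureSpec", "make_complex", "make_score_table"]

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# target mean spacing of ~5 A between neighboring pseudo-residues on the shell
_AREA_PER_RESIDUE = 21.65
_GAP = 10.0  # shell-to-shell gap along z; non-planted cross atoms stay > 6 A apart

INTERFACE_COMPOSITION = {"W": 0.30, "Y": 0.25, "R": 0.25, "F": 0.20}


@dataclass
class FixtureSpec:
    """Sizes, geometry and randomness of one pseudo-complex."""

    antigen_size: int = 60
    antibody_size: int = 40
    interface_size: int = 8  # epitope residues
    interface_size_ab: int | None = None  # paratope residues; default: same
    geometry: str = "sphere-shell"
    seed: int = 0
    noise: float = 0.15  # A, Gaussian jitter on shell positions
    interface_composition: dict[str, float] = field(
        default_factory=lambda: dict(INTERFACE_COMPOSITION))

    def __post_init__(self) -> None:
        if self.interface_size_ab is None:
            self.interface_size_ab = self.interface_size
        if min(self.antigen_size, self.antibody_size) < 5:
            raise ValueError("chain sizes must be >= 5")
        if self.interface_size > self.antigen_size or self.interface_size_ab > self.antibody_size:
            raise ValueError("interface larger than a chain")
        if self.geometry != "sphere-shell":
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _fibonacci_shell(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _residue_atoms(ca: np.ndarray, outward: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Five heavy atoms with approximate backbone geometry around a CA."""
    outward = outward / np.linalg.norm(outward)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(outward @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(outward, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(outward, t1)
    return [
        ("N", "N", ca + 1.46 * t1),
        ("CA", "C", ca),
        ("C", "C", ca + 1.52 * t2),
        ("O", "O", ca + 1.52 * t2 - 1.23 * outward),  # tucked inward
        ("CB", "C", ca + 1.53 * outward),
    ]


def _draw_letters(rng, n, composition=None):
    if composition is None:
        letters = sorted(_AA3)
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        letters = sorted(composition)
        probs = np.array([composition[l] for l in letters], dtype=float)
        probs /= probs.sum()
    return [letters[i] for i in rng.choice(len(letters), size=n, p=probs)]


def _format_atom(serial, name, resname, chain, resseq, xyz, element) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {pad_name} {resname:3s} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def make_complex(spec: FixtureSpec) -> tuple[str, InterfacePair]:
    """Build one pseudo-complex; returns (pdb_text, ground-truth interface)."""
    rng = np.random.default_rng(spec.seed)
    n_ag, n_ab = spec.antigen_size, spec.antibody_size
    n_if_ag, n_if_ab = spec.interface_size, spec.interface_size_ab

    r_ag = math.sqrt(n_ag * _AREA_PER_RESIDUE / (4.0 * math.pi))
    r_ab = math.sqrt(n_ab * _AREA_PER_RESIDUE / (4.0 * math.pi))
    ag_center = np.zeros(3)
    ab_center = np.array([0.0, 0.0, r_ag + _GAP + r_ab])
    mid_z = r_ag + _GAP / 2.0

    ag_pos = _fibonacci_shell(n_ag, r_ag) + ag_center
    ab_pos = _fibonacci_shell(n_ab, r_ab) + ab_center
    ag_pos += rng.normal(0.0, spec.noise, ag_pos.shape)
    ab_pos += rng.normal(0.0, spec.noise, ab_pos.shape)

    # Planted interface: the residues nearest the partner are pulled into the
    # gap onto a ring whose radius grows with the interface size. The two
    # sides may have different residue counts; pairing cycles over the slots
    # so every planted residue gets a CB-CB contact in [3.3, 3.7] A, solved
    # for the vertical offset after a small independent lateral jitter per
    # side. Epitope and paratope are therefore similar in shape but not
    # identical, like real interfaces.
    ag_if = list(np.argsort(-ag_pos[:, 2])[:n_if_ag])
    ab_if = list(np.argsort(ab_pos[:, 2])[:n_if_ab])
    n_pairs = max(n_if_ag, n_if_ab)
    ring_r = 0.0 if n_pairs == 1 else 0.75 * 2.63 * math.sqrt(n_pairs)
    up = np.array([0.0, 0.0, 1.0])
    outward_ag = {}
    outward_ab = {}
    placed_ag: dict[int, np.ndarray] = {}  # CB position per placed residue
    placed_ab: dict[int, np.ndarray] = {}
    for j in range(n_pairs):
        ia = ag_if[j % n_if_ag]
        ib = ab_if[j % n_if_ab]
        ang = 2.0 * math.pi * j / n_pairs
        base = np.array([ring_r * math.cos(ang), ring_r * math.sin(ang), 0.0])
        target = float(rng.uniform(3.3, 3.7))
        if ia not in placed_ag and ib not in placed_ab:
            cb_ag = base + np.array([*rng.uniform(-0.3, 0.3, 2),
                                     mid_z - 1.7 + rng.uniform(-0.15, 0.15)])
            placed_ag[ia] = cb_ag
            lat = np.array([*rng.uniform(-0.3, 0.3, 2), 0.0])
            dz = math.sqrt(target ** 2 - float(lat[0] ** 2 + lat[1] ** 2))
            placed_ab[ib] = cb_ag + lat + np.array([0.0, 0.0, dz])
        elif ib not in placed_ab:  # antigen slot reused: hang ab off it
            cb_ag = placed_ag[ia]
            lat = np.array([*rng.uniform(-0.3, 0.3, 2), 0.0])
            dz = math.sqrt(target ** 2 - float(lat[0] ** 2 + lat[1] ** 2))
            placed_ab[ib] = cb_ag + lat + np.array([0.0, 0.0, dz])
        elif ia not in placed_ag:  # antibody slot reused: hang ag off it
            cb_ab = placed_ab[ib]
            lat = np.array([*rng.uniform(-0.3, 0.3, 2), 0.0])
            dz = math.sqrt(target ** 2 - float(lat[0] ** 2 + lat[1] ** 2))
            placed_ag[ia] = cb_ab + lat - np.array([0.0, 0.0, dz])
    # CB = CA + 1.53 * outward, so back the CA off along the contact axis
    for ia, cb in placed_ag.items():
        ag_pos[ia] = cb - 1.53 * up
        outward_ag[ia] = up
    for ib, cb in placed_ab.items():
        ab_pos[ib] = cb + 1.53 * up
        outward_ab[ib] = -up

    ag_letters = _draw_letters(rng, n_ag)
    ab_letters = _draw_letters(rng, n_ab)
    if_ag_letters = _draw_letters(rng, n_if_ag, spec.interface_composition)
    if_ab_letters = _draw_letters(rng, n_if_ab, spec.interface_composition)
    for k, ia in enumerate(ag_if):
        ag_letters[ia] = if_ag_letters[k]
    for k, ib in enumerate(ab_if):
        ab_letters[ib] = if_ab_letters[k]

    lines = []
    serial = 1
    for chain, positions, letters, center, special in (
        ("A", ag_pos, ag_letters, ag_center, outward_ag),
        ("H", ab_pos, ab_letters, ab_center, outward_ab),
    ):
        for i, ca in enumerate(positions):
            outward = special.get(i)
            if outward is None:
                outward = ca - center
            resname = _AA3[letters[i]]
            for name, element, xyz in _residue_atoms(ca, outward):
                lines.append(_format_atom(serial, name, resname, chain, i + 1, xyz, element))
                serial += 1
        lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    epitope = Patch("antigen", tuple(sorted(
        ResidueId("A", int(i) + 1, "") for i in ag_if)))
    paratope = Patch("antibody", tuple(sorted(
        ResidueId("H", int(i) + 1, "") for i in ab_if)))
    return pdb_text, InterfacePair(epitope=epitope, paratope=paratope, cutoff=4.0)


def make_score_table(
    n: int, distribution: str = "uniform", seed: int = 0,
    planted_target: str | None = None,
) -> np.ndarray:
    """Reproducible score vectors for ranking null tests."""
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        scores = rng.uniform(0.0, 1.0, size=n)
    elif distribution == "normal":
        scores = rng.normal(0.0, 1.0, size=n)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    if planted_target == "max":
        scores[0] = scores.max() + 1.0
    return scores
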