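"""Parsing of antibody-antigen PDB structures and surface geometry.

This module turns a PDB file into a heavy-atom :class:`StructureModel` with a
declared antigen/antibody chain split, computes per-atom solvent accessibility
with a Shrake-Rupley rolling probe, identifies exposed residues, extracts the
epitope/paratope interface, and builds the exposed-residue neighbor graph that
the patch features and the Monte Carlo sampler operate on.

Conventions
-----------
* Only heavy atoms are kept: hydrogens/deuteriums, waters and HETATM ligands
  are dropped at parse time (selenomethionine is mapped to methionine).
* A residue is *exposed* when at least one of its heavy atoms has strictly
  more than ``2.5`` A^2 of solvent-accessible area.
* Interface residues are exposed residues with any heavy atom strictly closer
  than ``4.0`` A to the other molecule.
* Surface neighbors are exposed residues whose minimal heavy-atom distance is
  at most ``6.0`` A (inclusive).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ResidueId",
    "Patch",
    "InterfacePair",
    "SurfaceGraph",
    "StructureModel",
    "parse_structure",
    "compute_accessibility",
    "exposed_residues",
    "extract_interface",
    "surface_neighbor_graph",
    "write_interface_tsv",
    "ATOM_AREA_THRESHOLD",
    "CONTACT_CUTOFF",
    "NEIGHBOR_RADIUS",
]

ATOM_AREA_THRESHOLD = 2.5  # A^2, strict ">"
CONTACT_CUTOFF = 4.0  # A, strict "<"
NEIGHBOR_RADIUS = 6.0  # A, inclusive "<="
PROBE_RADIUS = 1.4  # A, water probe
N_SPHERE_POINTS = 960

RESIDUE_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
# MODRES-style mapping for common modified residues.
MODIFIED_RESIDUES = {"MSE": "MET"}

# van der Waals radii (A) by element; unknown elements fall back to carbon.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


class ResidueId(NamedTuple):
    """(chain, resseq, icode) triple identifying a residue, PDB numbering."""

    chain: str
    resseq: int
    icode: str


@dataclass(frozen=True)
class Patch:
    """An ordered set of exposed residues on one molecule."""

    role: str  # "antigen" | "antibody"
    residues: tuple[ResidueId, ...]

    def __post_init__(self) -> None:
        if self.role not in ("antigen", "antibody"):
            raise ValueError(f"unknown patch role {self.role!r}")

    @property
    def residue_set(self) -> frozenset[ResidueId]:
        return frozenset(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InterfacePair:
    """Epitope/paratope residue sets extracted from one complex."""

    epitope: Patch
    paratope: Patch
    cutoff: float

    @property
    def has_interface(self) -> bool:
        return len(self.epitope) > 0 and len(self.paratope) > 0


@dataclass
class SurfaceGraph:
    """Symmetric adjacency between exposed residues within the radius."""

    nodes: tuple[ResidueId, ...]
    adjacency: dict[ResidueId, set[ResidueId]]
    radius: float

    def neighbors(self, rid: ResidueId) -> set[ResidueId]:
        return self.adjacency.get(rid, set())


@dataclass
class StructureModel:
    """Heavy-atom structure with chain roles and per-atom accessibility."""

    coords: np.ndarray  # (N, 3) float64
    elements: np.ndarray  # (N,) str
    atom_names: np.ndarray  # (N,) str
    atom_residue: np.ndarray  # (N,) int index into `residues`
    residues: list[ResidueId]
    residue_names: list[str]  # 3-letter codes
    antigen_chains: frozenset[str]
    antibody_chains: frozenset[str]
    sasa: np.ndarray | None = None
    sasa_context: str | None = None
    _rid_index: dict[ResidueId, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._rid_index:
            self._rid_index = {rid: i for i, rid in enumerate(self.residues)}

    # -- basic queries ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_index(self, rid: ResidueId) -> int:
        return self._rid_index[rid]

    def atoms_of_residue(self, rid: ResidueId) -> np.ndarray:
        return np.flatnonzero(self.atom_residue == self._rid_index[rid])

    def residue_name(self, rid: ResidueId) -> str:
        return self.residue_names[self._rid_index[rid]]

    def residue_letter(self, rid: ResidueId) -> str:
        return RESIDUE_3TO1[self.residue_name(rid)]

    def role_of_chain(self, chain: str) -> str:
        if chain in self.antigen_chains:
            return "antigen"
        if chain in self.antibody_chains:
            return "antibody"
        raise KeyError(chain)

    def atom_mask_for_role(self, role: str) -> np.ndarray:
        chains = self.antigen_chains if role == "antigen" else self.antibody_chains
        res_mask = np.array([rid.chain in chains for rid in self.residues])
        return res_mask[self.atom_residue]

    def chain_sequence(self, chain: str) -> str:
        return "".join(
            RESIDUE_3TO1[name]
            for rid, name in zip(self.residues, self.residue_names)
            if rid.chain == chain
        )

    def ca_coordinates(self, rids: Iterable[ResidueId]) -> np.ndarray:
        """C-alpha coordinates for the given residues (atom centroid fallback)."""
        out = []
        for rid in rids:
            idx = self.atoms_of_residue(rid)
            names = self.atom_names[idx]
            ca = idx[names == "CA"]
            if len(ca):
                out.append(self.coords[ca[0]])
            else:  # pragma: no cover - malformed residues
                out.append(self.coords[idx].mean(axis=0))
        return np.asarray(out, dtype=float)

    # -- accessibility-derived queries ------------------------------------
    def _require_sasa(self) -> np.ndarray:
        if self.sasa is None:
            raise ValueError("sasa not computed")
        return self.sasa

    def residue_sasa(self, rid: ResidueId) -> float:
        sasa = self._require_sasa()
        return float(sasa[self.atoms_of_residue(rid)].sum())

    def max_atom_sasa(self, rid: ResidueId) -> float:
        sasa = self._require_sasa()
        return float(sasa[self.atoms_of_residue(rid)].max())


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _pick_altloc(atom):
    """Highest occupancy wins; ties broken alphabetically by altloc id."""
    if not atom.is_disordered():
        return atom
    alts = atom.disordered_get_list()
    return min(alts, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))


def parse_structure(
    pdb_text: str,
    antigen_chains: Iterable[str],
    antibody_chains: Iterable[str],
) -> StructureModel:
    """Parse PDB text into a heavy-atom model restricted to the named chains.

    Hydrogens, waters and HETATM ligands are excluded; MSE is mapped to MET;
    for alternate locations the highest-occupancy conformer is kept. Only the
    first MODEL of a multi-model file is read.
    """
    from Bio.PDB import PDBParser

    antigen_chains = frozenset(antigen_chains)
    antibody_chains = frozenset(antibody_chains)
    overlap = antigen_chains & antibody_chains
    if overlap:
        raise ValueError(f"ambiguous role: chains {sorted(overlap)} assigned to both sides")

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", io.StringIO(pdb_text))
    try:
        model0 = next(structure.get_models())
    except StopIteration:
        raise ValueError("parse error: no ATOM records") from None

    wanted = antigen_chains | antibody_chains
    coords, elements, atom_names, atom_residue = [], [], [], []
    residues: list[ResidueId] = []
    residue_names: list[str] = []
    seen_chains: set[str] = set()

    for chain in model0:
        if chain.id not in wanted:
            continue
        seen_chains.add(chain.id)
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            if hetflag != " ":
                if resname in MODIFIED_RESIDUES:
                    resname = MODIFIED_RESIDUES[resname]
                else:
                    continue  # waters, ligands, unknown modifications
            elif resname in MODIFIED_RESIDUES:
                resname = MODIFIED_RESIDUES[resname]
            if resname not in RESIDUE_3TO1:
                warnings.warn(f"dropping non-standard residue {resname} {chain.id}{resseq}")
                continue
            rid = ResidueId(chain.id, int(resseq), icode.strip() or "")
            atom_rows = []
            for atom in residue:
                best = _pick_altloc(atom)
                element = (best.element or "").strip().upper()
                if element in ("H", "D", ""):
                    if element == "":
                        element = best.get_name().strip()[:1].upper()
                        if element == "H":
                            continue
                    else:
                        continue
                xyz = np.asarray(best.get_coord(), dtype=float)
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite coordinates at {rid}")
                atom_rows.append((xyz, element, best.get_name().strip()))
            if not atom_rows:
                continue
            ridx = len(residues)
            residues.append(rid)
            residue_names.append(resname)
            for xyz, element, name in atom_rows:
                coords.append(xyz)
                elements.append(element)
                atom_names.append(name)
                atom_residue.append(ridx)

    missing = wanted - seen_chains
    if missing:
        raise ValueError(f"chain not found: {sorted(missing)}")
    if not coords:
        raise ValueError("parse error: no ATOM records with heavy atoms")

    return StructureModel(
        coords=np.asarray(coords, dtype=float),
        elements=np.asarray(elements, dtype="U2"),
        atom_names=np.asarray(atom_names, dtype="U4"),
        atom_residue=np.asarray(atom_residue, dtype=int),
        residues=residues,
        residue_names=residue_names,
        antigen_chains=antigen_chains,
        antibody_chains=antibody_chains,
    )


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), _DEFAULT_RADIUS)


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom SASA (A^2) of a set of spheres, rolling-probe test points."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sphere = _fibonacci_sphere(n_points)
    extended = radii + probe
    tree = cKDTree(coords)
    rmax = float(extended.max())
    sasa = np.zeros(len(coords))
    for i in range(len(coords)):
        r_i = extended[i]
        nbrs = tree.query_ball_point(coords[i], r_i + rmax)
        nbrs = [j for j in nbrs if j != i]
        pts = coords[i] + r_i * sphere
        if nbrs:
            nb = np.asarray(nbrs, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (extended[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = frac * 4.0 * math.pi * r_i * r_i
    return sasa


def compute_accessibility(
    model: StructureModel,
    context: str = "isolated",
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> StructureModel:
    """Fill per-atom SASA on the model and return it.

    ``context="isolated"`` (default) computes each molecule's accessibility
    with the partner removed, so interface residues keep the exposure they
    have on the unbound surface. ``context="complex"`` computes it on the
    assembled complex.
    """
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    if context not in ("isolated", "complex"):
        raise ValueError(f"unknown exposure context {context!r}")
    radii = np.array([vdw_radius(e) for e in model.elements])
    sasa = np.zeros(model.n_atoms)
    if context == "complex":
        sasa[:] = shrake_rupley_sasa(model.coords, radii, probe, n_points)
    else:
        for role in ("antigen", "antibody"):
            mask = model.atom_mask_for_role(role)
            if mask.any():
                sasa[mask] = shrake_rupley_sasa(
                    model.coords[mask], radii[mask], probe, n_points
                )
    model.sasa = sasa
    model.sasa_context = context
    return model


def exposed_residues(
    model: StructureModel, atom_area_threshold: float = ATOM_AREA_THRESHOLD
) -> set[ResidueId]:
    """Residues with at least one atom whose SASA strictly exceeds the threshold."""
    sasa = model._require_sasa()
    out: set[ResidueId] = set()
    ridx = model.atom_residue
    best = np.zeros(model.n_residues)
    np.maximum.at(best, ridx, sasa)
    for rid, b in zip(model.residues, best):
        if b > atom_area_threshold:
            out.add(rid)
    return out


# ---------------------------------------------------------------------------
# interface & neighbor graph
# ---------------------------------------------------------------------------

def extract_interface(model: StructureModel, cutoff: float = CONTACT_CUTOFF) -> InterfacePair:
    """Exposed residues of each side with a heavy atom strictly under `cutoff`
    from the other side."""
    model._require_sasa()
    ag_mask = model.atom_mask_for_role("antigen")
    ab_mask = model.atom_mask_for_role("antibody")
    if not ag_mask.any() or not ab_mask.any():
        raise ValueError("both chain groups must be present")
    exposed = exposed_residues(model)

    ag_idx = np.flatnonzero(ag_mask)
    ab_idx = np.flatnonzero(ab_mask)
    tree_ag = cKDTree(model.coords[ag_idx])
    tree_ab = cKDTree(model.coords[ab_idx])
    pairs = tree_ag.query_ball_tree(tree_ab, cutoff)

    epi: set[ResidueId] = set()
    para: set[ResidueId] = set()
    for i, hits in enumerate(pairs):
        if not hits:
            continue
        a = ag_idx[i]
        for j in hits:
            b = ab_idx[j]
            d = float(np.linalg.norm(model.coords[a] - model.coords[b]))
            if d < cutoff:  # strict
                epi.add(model.residues[model.atom_residue[a]])
                para.add(model.residues[model.atom_residue[b]])

    epi &= exposed
    para &= exposed
    pair = InterfacePair(
        epitope=Patch("antigen", tuple(sorted(epi))),
        paratope=Patch("antibody", tuple(sorted(para))),
        cutoff=cutoff,
    )
    if not pair.has_interface:
        warnings.warn("no interface: no exposed cross-chain contacts under cutoff")
    return pair


def surface_neighbor_graph(
    model: StructureModel, radius: float = NEIGHBOR_RADIUS
) -> SurfaceGraph:
    """Adjacency of exposed residues with minimal heavy-atom distance <= radius."""
    exposed = exposed_residues(model)
    nodes = tuple(rid for rid in model.residues if rid in exposed)
    adjacency: dict[ResidueId, set[ResidueId]] = {rid: set() for rid in nodes}
    if nodes:
        node_set = set(nodes)
        keep = np.array([model.residues[r] in node_set for r in model.atom_residue])
        idx = np.flatnonzero(keep)
        tree = cKDTree(model.coords[idx])
        for a_loc, b_loc in tree.query_pairs(radius):
            ra = model.residues[model.atom_residue[idx[a_loc]]]
            rb = model.residues[model.atom_residue[idx[b_loc]]]
            if ra == rb:
                continue
            # surface neighborhoods live within one molecule
            if model.role_of_chain(ra.chain) != model.role_of_chain(rb.chain):
                continue
            adjacency[ra].add(rb)
            adjacency[rb].add(ra)
    return SurfaceGraph(nodes=nodes, adjacency=adjacency, radius=radius)


def write_interface_tsv(pair: InterfacePair, path) -> None:
    """Write interface residues as TSV: chain, resseq, icode, role."""
    with open(path, "w") as fh:
        fh.write("chain\tresseq\ticode\trole\n")
        for patch, role in ((pair.epitope, "epitope"), (pair.paratope, "paratope")):
            for rid in patch.residues:
                fh.write(f"{rid.chain}\t{rid.resseq}\t{rid.icode}\t{role}\n")
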