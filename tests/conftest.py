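"""Shared fixtures: one parsed synthetic complex and helpers to craft
minimal PDB texts and stub patch descriptors."""

from __future__ import annotations

import numpy as np
import pytest

from epibind.features import PatchDescriptor
from epibind.pipeline import prepare_complex
from epibind.synthfix import FixtureSpec, make_complex


@pytest.fixture(scope="session")
def complex_bundle():
    """A default pseudo-complex parsed end to end, with its ground truth."""
    pdb_text, truth = make_complex(FixtureSpec(seed=11))
    prep = prepare_complex(pdb_text, {"A"}, {"H"}, complex_id="bundle")
    return {"pdb_text": pdb_text, "truth": truth, "prep": prep}


@pytest.fixture(scope="session")
def model(complex_bundle):
    return complex_bundle["prep"].model


@pytest.fixture(scope="session")
def graph(complex_bundle):
    return complex_bundle["prep"].graph


@pytest.fixture(scope="session")
def interface(complex_bundle):
    return complex_bundle["prep"].interface


def mini_pdb(residues):
    """PDB text from [(chain, resseq, resname, [(atom, element, xyz), ...])]."""
    lines = []
    serial = 1
    for chain, resseq, resname, atoms in residues:
        for name, element, xyz in atoms:
            pad = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad} {resname:3s} {chain}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def single_atom_residue(chain, resseq, resname, xyz, atom="CA", element="C"):
    return (chain, resseq, resname, [(atom, element, xyz)])


def stub_descriptor(
    rng: np.random.Generator,
    role: str = "antigen",
    size: float | None = None,
    pc: np.ndarray | None = None,
    density: float | None = None,
    total_sasa: float | None = None,
) -> PatchDescriptor:
    """Random but well-formed PatchDescriptor for descriptor-level tests."""
    comp = rng.random(20)
    comp /= comp.sum()
    triads = rng.random(196)
    triads /= triads.sum()
    pcs = np.sort(rng.uniform(0.5, 5.0, 3))[::-1] if pc is None else np.asarray(pc, float)
    desc = PatchDescriptor(
        role=role,
        aa_composition=comp,
        donors=float(rng.integers(0, 15)),
        acceptors=float(rng.integers(0, 15)),
        hydrophobicity=float(rng.integers(0, 20)),
        aromatic=float(rng.integers(0, 5)),
        positive=float(rng.integers(0, 5)),
        negative=float(rng.integers(0, 5)),
        pc=pcs,
        size=float(rng.integers(5, 15)) if size is None else float(size),
        density=float(rng.uniform(1.0, 6.0)) if density is None else float(density),
        triads=triads,
        zernike=rng.random(7) * 0.1,
        total_sasa=float(rng.uniform(200, 800)) if total_sasa is None else float(total_sasa),
    )
    if role == "antigen":
        r = np.sort(rng.uniform(0.1, 1.0, 3))
        desc.rsa_min, desc.rsa_mean, desc.rsa_max = float(r[0]), float(r[1]), float(r[2])
    return desc
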