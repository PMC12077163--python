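"""Minimal structure utilities for dimer-interface residue contacts.

Reads a complex coordinate file (PDB or mmCIF), and measures residue-residue
polar contacts: a 'hydrogen bond' is operationalized as the minimum distance
between polar heavy atoms (N, O; backbone included, so glycine participates
through its backbone) of the two residues — no hydrogen placement and no
angle criterion, matching the single printed interface distance the check is
built for (the VelB G240 - VosA S110 contact at 3.5 A).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd


class StructureError(ValueError):
    """Raised for unreadable files or missing chains/residues."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    number: int
    name: str
    atoms: tuple[Atom, ...]


@dataclass
class StructureComplex:
    """Chains of residues with heavy-atom coordinates (waters and hydrogens
    removed, altlocs resolved to the highest-occupancy conformer)."""

    chains: dict  # chain id -> {residue number -> Residue}

    def residue(self, chain: str, number: int) -> Residue:
        try:
            ch = self.chains[chain]
        except KeyError:
            raise StructureError(f"chain {chain!r} not in structure") from None
        try:
            return ch[number]
        except KeyError:
            raise StructureError(f"residue {number} not in chain {chain!r}") from None

    def chain(self, chain: str) -> dict:
        try:
            return self.chains[chain]
        except KeyError:
            raise StructureError(f"chain {chain!r} not in structure") from None


_WATER = {"HOH", "WAT", "DOD"}


def read_structure(path: str | Path, format: str | None = None) -> StructureComplex:
    """Read a PDB or mmCIF file (first model; hydrogens/waters excluded)."""
    path = Path(path)
    fmt = format or ("mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.remove_alternative_conformations()  # keeps the highest-occupancy altloc
    st.remove_hydrogens()
    model = st[0]
    chains: dict = {}
    for chain in model:
        residues = {}
        for res in chain:
            if res.name in _WATER:
                continue
            atoms = tuple(
                Atom(a.name, a.element.name.upper(), (a.pos.x, a.pos.y, a.pos.z))
                for a in res
                if a.element.name.upper() not in {"H", "D"}
            )
            if atoms:
                residues[res.seqid.num] = Residue(res.seqid.num, res.name, atoms)
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise StructureError(f"{path}: no residues after filtering")
    return StructureComplex(chains)


def write_structure(c: StructureComplex, path: str | Path) -> None:
    """Write the complex back out as PDB (coordinates at PDB precision)."""
    st = gemmi.Structure()
    st.name = "archscan"
    model = gemmi.Model("1")
    for chain_id, residues in c.chains.items():
        chain = gemmi.Chain(chain_id)
        for num in sorted(residues):
            res = residues[num]
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(num, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                ga.occ = 1.0
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_POLAR = {"N", "O"}


@dataclass(frozen=True)
class PolarDistance:
    angstrom: float   # rounded to one decimal (as reported)
    raw: float


def min_polar_distance(
    c: StructureComplex, chain_a: str, res_a: int, chain_b: str, res_b: int
) -> PolarDistance:
    """Minimum distance between polar heavy atoms (N, O) of the two residues.

    Symmetric in its arguments; a residue against itself is 0.0.
    """
    ra = c.residue(chain_a, res_a)
    rb = c.residue(chain_b, res_b)
    if chain_a == chain_b and res_a == res_b:
        return PolarDistance(0.0, 0.0)
    pa = [a.xyz for a in ra.atoms if a.element in _POLAR]
    pb = [a.xyz for a in rb.atoms if a.element in _POLAR]
    if not pa or not pb:
        raise StructureError(
            f"no polar heavy atoms on {chain_a}/{res_a} or {chain_b}/{res_b}"
        )
    raw = min(math.dist(x, y) for x in pa for y in pb)
    return PolarDistance(round(raw, 1), raw)


def _min_heavy_distance(ra: Residue, rb: Residue) -> float:
    xa = np.array([a.xyz for a in ra.atoms])
    xb = np.array([a.xyz for a in rb.atoms])
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min()))


def interface_contacts(
    c: StructureComplex, chain_a: str, chain_b: str, cutoff: float
) -> pd.DataFrame:
    """Cross-chain residue pairs with minimum heavy-atom distance <= cutoff,
    sorted by distance."""
    if cutoff <= 0:
        if cutoff < 0:
            raise StructureError(f"cutoff must be positive, got {cutoff}")
        return pd.DataFrame(
            columns=["res_a", "name_a", "res_b", "name_b", "distance"]
        )
    ca = c.chain(chain_a)
    cb = c.chain(chain_b)
    records = []
    for na, ra in sorted(ca.items()):
        for nb, rb in sorted(cb.items()):
            d = _min_heavy_distance(ra, rb)
            if d <= cutoff:
                records.append(
                    {
                        "res_a": na,
                        "name_a": ra.name,
                        "res_b": nb,
                        "name_b": rb.name,
                        "distance": d,
                    }
                )
    df = pd.DataFrame.from_records(
        records, columns=["res_a", "name_a", "res_b", "name_b", "distance"]
    )
    return df.sort_values("distance", kind="stable").reset_index(drop=True)


def synthetic_interface_fixture(path: str | Path, distance: float = 3.50) -> None:
    """Write a small synthetic two-chain PDB fixture (not a real structure).

    Chain A carries a glycine numbered 240 and chain B a serine numbered 110,
    with the glycine backbone N and the serine OG placed exactly ``distance``
    angstroms apart — a stand-in for the dimer-interface hydrogen bond used
    by the structure-contact check.
    """
    gly = Residue(
        240,
        "GLY",
        (
            Atom("N", "N", (0.0, 0.0, 0.0)),
            Atom("CA", "C", (1.458, 0.0, 0.0)),
            Atom("C", "C", (2.0, 1.4, 0.0)),
            Atom("O", "O", (1.4, 2.4, 0.2)),
        ),
    )
    ser = Residue(
        110,
        "SER",
        (
            Atom("N", "N", (-1.0, -4.8, 1.2)),
            Atom("CA", "C", (0.2, -5.3, 0.6)),
            Atom("C", "C", (1.2, -5.9, 1.6)),
            Atom("O", "O", (1.1, -7.1, 1.9)),
            Atom("CB", "C", (-0.2, -6.3, -0.5)),
            Atom("OG", "O", (0.0, -float(distance), 0.0)),
        ),
    )
    write_structure(StructureComplex({"A": {240: gly}, "B": {110: ser}}), path)
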