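"""Atom typing, local frames, databank construction and density transfer.

An atom type is a deliberately simple chemical descriptor: the element plus
the sorted multiset of bonded-neighbour elements (bonds detected at 1.3x
the covalent-radius sum).  Each type carries a local-frame definition: a Z
reference neighbour, an XZ-plane reference, right handed.  Bank entries
store the type-averaged multipole density expressed in the local frame;
transfer hands every structure atom its type's density plus its own frame
matrix M (rows = local axes), so the downstream form factor for reciprocal
vector S is evaluated at M.S.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .density import DensitySpec, atomic_density_on_grid
from .errors import BankError, InvalidParameterError, ParseError
from .harmonics import lm_order
from .multipole import MultipoleDensity, project_multipoles, resample_radial
from .quadrature import (angular_grid, atomic_grid, element_radial_scale,
                         mura_knowles_radial)

__all__ = ["covalent_radius", "detect_bonds", "LocalFrameDef", "AtomType",
           "DatabankEntry", "derive_atom_types", "assign_atom_types",
           "resolve_frame_refs", "local_frame", "build_bank", "write_bank",
           "read_bank", "transfer", "TransferredAtom"]

log = logging.getLogger(__name__)

# single-bond covalent radii (A), Cordero-style consensus values
_COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_ATOMIC_NUMBER = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Br": 35, "I": 53,
}

BOND_FACTOR = 1.3
MIN_DISTANCE = 0.4  # A; closer atoms are considered overlapping


def covalent_radius(element: str) -> float:
    try:
        return _COVALENT_RADII[element]
    except KeyError:
        raise InvalidParameterError(f"no covalent radius for element "
                                    f"{element!r}") from None


def atomic_number(element: str) -> int:
    try:
        return _ATOMIC_NUMBER[element]
    except KeyError:
        raise InvalidParameterError(f"unknown element {element!r}") from None


def detect_bonds(elements, positions) -> list[list[int]]:
    """Symmetric adjacency by the covalent-radius criterion.

    Atoms a, b are bonded iff |r_a - r_b| < 1.3 (r_cov(a) + r_cov(b)).
    Distances below 0.4 A raise (overlapping atoms).
    """
    pos = np.asarray(positions, float).reshape(-1, 3)
    n = len(pos)
    radii = np.array([covalent_radius(e) for e in elements])
    adjacency = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < MIN_DISTANCE:
                raise InvalidParameterError(
                    f"atoms {i} and {j} overlap (distance {d:.3f} A)")
            if d < BOND_FACTOR * (radii[i] + radii[j]):
                adjacency[i].append(j)
                adjacency[j].append(i)
    return adjacency


@dataclass(frozen=True)
class LocalFrameDef:
    """Neighbour selectors defining the local axes (right handed).

    ``z_ref`` selects the Z-axis neighbour by element; ``xz_ref`` selects a
    second reference atom fixing the XZ plane, searched first among the
    atom's own bonded neighbours and then among the Z atom's neighbours.
    """
    z_ref: str
    xz_ref: str


@dataclass(frozen=True)
class AtomType:
    label: str
    element: str
    neighbor_signature: tuple  # sorted element symbols of bonded neighbours
    frame: LocalFrameDef

    def __post_init__(self):
        object.__setattr__(self, "neighbor_signature",
                           tuple(self.neighbor_signature))
        if not self.neighbor_signature:
            raise BankError(f"type {self.label}: empty neighbour signature")


@dataclass(frozen=True)
class DatabankEntry:
    atom_type: AtomType
    density: MultipoleDensity   # in the type's local frame
    n_instances: int
    provenance: str = ""

    def __post_init__(self):
        if self.n_instances < 1:
            raise BankError("entry must average at least one instance")
        z = atomic_number(self.atom_type.element)
        pop = self.density.population
        if not 0.2 * z <= pop <= 1.8 * z:
            raise BankError(
                f"entry {self.atom_type.label}: population {pop:.3f} e "
                f"outside [0.2, 1.8] x Z={z}")


def _priority(element: str) -> tuple:
    # heavier elements first, deterministic tie-break on the symbol
    return (-atomic_number(element), element)


def _type_label(element: str, signature) -> str:
    return f"{element}({''.join(signature)})"


def derive_atom_types(elements, adjacency) -> dict[str, AtomType]:
    """Atom types occurring in a structure, with default frame definitions.

    Z reference: the heaviest bonded neighbour element.  XZ reference: the
    heaviest remaining neighbour element, or, for terminal atoms, the
    heaviest element among the Z atom's other neighbours.
    """
    types: dict[str, AtomType] = {}
    for i, el in enumerate(elements):
        nbrs = adjacency[i]
        if not nbrs:
            raise BankError(f"atom {i} ({el}) has no bonded neighbours; "
                            "cannot define an atom type and local frame")
        sig = tuple(sorted(elements[j] for j in nbrs))
        label = _type_label(el, sig)
        if label in types:
            continue
        by_prio = sorted((elements[j] for j in nbrs), key=_priority)
        z_ref = by_prio[0]
        if len(by_prio) > 1:
            xz_ref = by_prio[1]
        else:
            z_idx = min((j for j in nbrs if elements[j] == z_ref),
                        key=lambda j: j)
            second = [elements[j] for j in adjacency[z_idx] if j != i]
            if not second:
                raise BankError(
                    f"atom {i} ({el}): no second reference atom for the "
                    "local frame (isolated diatomic environment)")
            xz_ref = sorted(second, key=_priority)[0]
        types[label] = AtomType(label=label, element=el,
                                neighbor_signature=sig,
                                frame=LocalFrameDef(z_ref=z_ref,
                                                    xz_ref=xz_ref))
    return types


def assign_atom_types(elements, adjacency, bank_types) -> list[str | None]:
    """Map each atom to the unique bank type matching (element, signature).

    Returns per-atom labels; unmatched atoms get None.  Two bank types with
    identical (element, signature) raise a bank-validation error.
    """
    keyed: dict[tuple, AtomType] = {}
    for t in bank_types:
        key = (t.element, t.neighbor_signature)
        if key in keyed and keyed[key].label != t.label:
            raise BankError(f"ambiguous bank: types {keyed[key].label!r} and "
                            f"{t.label!r} share signature {key}")
        keyed[key] = t
    labels: list[str | None] = []
    for i, el in enumerate(elements):
        sig = tuple(sorted(elements[j] for j in adjacency[i]))
        t = keyed.get((el, sig))
        labels.append(t.label if t is not None else None)
    return labels


def resolve_frame_refs(elements, positions, adjacency, atom_index: int,
                       frame_def: LocalFrameDef) -> tuple[int, int]:
    """Resolve a frame definition to concrete (z_atom, xz_atom) indices.

    Candidates are ranked by distance (then index) for determinism.  The XZ
    reference is searched among the atom's own neighbours first (excluding
    the Z atom) and then among the Z atom's neighbours.
    """
    pos = np.asarray(positions, float).reshape(-1, 3)

    def nearest(cands):
        return min(cands,
                   key=lambda j: (float(np.linalg.norm(pos[j]
                                                       - pos[atom_index])),
                                  j))

    z_cands = [j for j in adjacency[atom_index]
               if elements[j] == frame_def.z_ref]
    if not z_cands:
        raise BankError(
            f"atom {atom_index}: no bonded {frame_def.z_ref!r} neighbour "
            "for the Z axis")
    z_idx = nearest(z_cands)
    # XZ reference: preferred element among own neighbours, then among the
    # Z atom's neighbours; if the preferred element is absent in this
    # instance's environment, fall back to any reference atom in the same
    # search order (the type selector is a preference, not a guarantee,
    # since second shells may differ between occurrences of a type)
    tiers = [
        [j for j in adjacency[atom_index]
         if elements[j] == frame_def.xz_ref and j != z_idx],
        [j for j in adjacency[z_idx]
         if elements[j] == frame_def.xz_ref and j not in (atom_index,
                                                          z_idx)],
        [j for j in adjacency[atom_index] if j != z_idx],
        [j for j in adjacency[z_idx] if j not in (atom_index, z_idx)],
    ]
    for tier, xz_cands in enumerate(tiers):
        if xz_cands:
            if tier >= 2:
                log.debug("atom %d: preferred XZ reference %r absent; "
                          "using fallback atom %d", atom_index,
                          frame_def.xz_ref, nearest(xz_cands))
            return z_idx, nearest(xz_cands)
    raise BankError(
        f"atom {atom_index}: no reference atom available for the XZ plane")


def local_frame(positions, atom_index: int, z_index: int,
                xz_index: int) -> np.ndarray:
    """Right-handed orthonormal frame matrix M (rows = X, Y, Z axes).

    Z points from the atom to the Z reference; Y is perpendicular to Z in
    the (atom, z_ref, xz_ref) plane; X = Y x Z, giving det(M) = +1.
    """
    pos = np.asarray(positions, float).reshape(-1, 3)
    if len({atom_index, z_index, xz_index}) != 3:
        raise InvalidParameterError("frame reference atoms must be distinct")
    z = pos[z_index] - pos[atom_index]
    v = pos[xz_index] - pos[atom_index]
    nz, nv = np.linalg.norm(z), np.linalg.norm(v)
    if nz == 0 or nv == 0:
        raise InvalidParameterError("coincident frame reference atoms")
    z = z / nz
    cosang = float(np.clip(np.dot(z, v) / nv, -1.0, 1.0))
    if abs(cosang) > np.cos(np.radians(1.0)):
        raise BankError(
            f"frame references for atom {atom_index} are collinear "
            f"(atoms {z_index} and {xz_index}, angle "
            f"{np.degrees(np.arccos(abs(cosang))):.3f} deg)")
    y = v - np.dot(v, z) * z
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    return np.array([x, y, z])


@dataclass(frozen=True)
class TransferredAtom:
    label: str
    density: MultipoleDensity
    frame: np.ndarray  # M, rows = local axes


def _grids_for_element(element: str, n_rad: int, n_ang: int):
    rad = mura_knowles_radial(n_rad, element_radial_scale(element))
    return atomic_grid(rad, angular_grid(n_ang))


def build_bank(specs, types=None, l_max: int = 7, n_rad: int = 75,
               n_ang: int = 590, provenance: str = "") -> list[DatabankEntry]:
    """Build databank entries by per-type averaging over model densities.

    For every occurrence of each type: the Hirshfeld atomic density is
    sampled on a grid oriented by the atom's local frame, projected onto
    spherical harmonics, resampled to the type's canonical radial grid and
    averaged coefficient-wise.  Fewer than 3 instances logs a warning (the
    averages are then poorly representative of the type).
    """
    if isinstance(specs, DensitySpec):
        specs = [specs]
    if types is None:
        merged: dict[str, AtomType] = {}
        for spec in specs:
            adj = detect_bonds(spec.elements, spec.positions)
            for label, t in derive_atom_types(spec.elements, adj).items():
                merged.setdefault(label, t)
        types = list(merged.values())
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    grids: dict[str, object] = {}
    by_label = {t.label: t for t in types}
    for spec in specs:
        adj = detect_bonds(spec.elements, spec.positions)
        labels = assign_atom_types(spec.elements, adj, types)
        for i, label in enumerate(labels):
            if label is None:
                continue
            t = by_label[label]
            z_idx, xz_idx = resolve_frame_refs(spec.elements, spec.positions,
                                               adj, i, t.frame)
            M = local_frame(spec.positions, i, z_idx, xz_idx)
            grid = grids.setdefault(label,
                                    _grids_for_element(t.element, n_rad,
                                                       n_ang))
            values = atomic_density_on_grid(spec, i, grid, M)
            md = project_multipoles(values, grid, l_max)
            md = resample_radial(md, grid.radial)
            sums[label] = sums.get(label, 0.0) + md.coefficients
            counts[label] = counts.get(label, 0) + 1
    entries = []
    for t in types:
        if t.label not in counts:
            raise BankError(f"type {t.label}: no instance found in the "
                            "provided specs")
        n = counts[t.label]
        if n < 3:
            log.warning("type %s averaged over only %d instance(s); 3 or "
                        "more are preferred", t.label, n)
        md = MultipoleDensity(l_max=l_max,
                              radial_grid=grids[t.label].radial,
                              coefficients=sums[t.label] / n)
        entries.append(DatabankEntry(atom_type=t, density=md, n_instances=n,
                                     provenance=provenance))
    return entries


# ---------------------------------------------------------------------------
# Text databank format
# ---------------------------------------------------------------------------
_BANK_HEADER = "THAM-BANK v1"


def write_bank(entries, path) -> None:
    """Write databank entries to the versioned text format (UTF-8, LF)."""
    lines = [_BANK_HEADER]
    for e in entries:
        t = e.atom_type
        lines.append("")
        lines.append(f"TYPE {t.label}")
        lines.append(f"ELEMENT {t.element}")
        lines.append(f"SIGNATURE {' '.join(t.neighbor_signature)}")
        lines.append(f"FRAME z={t.frame.z_ref} xz={t.frame.xz_ref}")
        lines.append(f"LMAX {e.density.l_max}")
        lines.append(f"NRAD {e.density.radial_grid.n_points} "
                     f"SCALE {e.density.radial_grid.scale:.17g}")
        lines.append(f"NINSTANCES {e.n_instances}")
        if e.provenance:
            lines.append(f"PROVENANCE {e.provenance}")
        for (l, m), row in zip(lm_order(e.density.l_max),
                               e.density.coefficients):
            vals = " ".join(f"{v:.17g}" for v in row)
            lines.append(f"{l} {m} {vals}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bank(path) -> list[DatabankEntry]:
    """Read a text databank; round-trips write_bank to stored precision."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _BANK_HEADER:
        raise ParseError(f"missing or unsupported header (expected "
                         f"{_BANK_HEADER!r})", path=str(path), line=1)
    entries: list[DatabankEntry] = []
    block: dict | None = None
    coeff_rows: list[tuple[int, int, np.ndarray]] = []

    def finish(lineno):
        nonlocal block, coeff_rows
        if block is None:
            return
        for key in ("element", "signature", "frame", "lmax", "nrad"):
            if key not in block:
                raise ParseError(f"entry {block.get('label')}: missing "
                                 f"{key.upper()}", path=str(path),
                                 line=lineno)
        l_max = block["lmax"]
        n_lm = (l_max + 1) ** 2
        if len(coeff_rows) != n_lm:
            raise ParseError(
                f"entry {block['label']}: expected {n_lm} coefficient rows, "
                f"got {len(coeff_rows)}", path=str(path), line=lineno)
        coeffs = np.empty((n_lm, block["nrad"]))
        order = {lm: k for k, lm in enumerate(lm_order(l_max))}
        for l, m, row in coeff_rows:
            if (l, m) not in order:
                raise ParseError(f"entry {block['label']}: unexpected "
                                 f"(l,m)=({l},{m})", path=str(path),
                                 line=lineno)
            coeffs[order[(l, m)]] = row
        rad = mura_knowles_radial(block["nrad"], block["scale"])
        t = AtomType(label=block["label"], element=block["element"],
                     neighbor_signature=block["signature"],
                     frame=block["frame"])
        entries.append(DatabankEntry(
            atom_type=t,
            density=MultipoleDensity(l_max=l_max, radial_grid=rad,
                                     coefficients=coeffs),
            n_instances=block.get("ninstances", 1),
            provenance=block.get("provenance", "")))
        block, coeff_rows = None, []

    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            if line.startswith("TYPE "):
                finish(lineno)
                block = {"label": line[5:].strip()}
            elif block is None:
                raise ParseError("content before first TYPE block",
                                 path=str(path), line=lineno)
            elif line.startswith("ELEMENT "):
                block["element"] = line.split(None, 1)[1]
            elif line.startswith("SIGNATURE"):
                block["signature"] = tuple(line.split()[1:])
            elif line.startswith("FRAME "):
                m = re.fullmatch(r"FRAME\s+z=(\S+)\s+xz=(\S+)", line)
                if not m:
                    raise ParseError("malformed FRAME line", path=str(path),
                                     line=lineno)
                block["frame"] = LocalFrameDef(z_ref=m.group(1),
                                               xz_ref=m.group(2))
            elif line.startswith("LMAX "):
                block["lmax"] = int(line.split()[1])
            elif line.startswith("NRAD "):
                parts = line.split()
                block["nrad"] = int(parts[1])
                if len(parts) < 4 or parts[2] != "SCALE":
                    raise ParseError("NRAD line must carry SCALE",
                                     path=str(path), line=lineno)
                block["scale"] = float(parts[3])
            elif line.startswith("NINSTANCES "):
                block["ninstances"] = int(line.split()[1])
            elif line.startswith("PROVENANCE"):
                block["provenance"] = line.split(None, 1)[1] \
                    if " " in line else ""
            else:
                parts = line.split()
                l, m = int(parts[0]), int(parts[1])
                row = np.array([float(v) for v in parts[2:]])
                if len(row) != block["nrad"]:
                    raise ParseError(
                        f"coefficient row ({l},{m}) has {len(row)} values, "
                        f"expected {block['nrad']}", path=str(path),
                        line=lineno)
                coeff_rows.append((l, m, row))
        except ParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise ParseError(f"cannot parse line: {exc}", path=str(path),
                             line=lineno) from None
    finish(len(lines) + 1)
    labels = [e.atom_type.label for e in entries]
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate type labels in bank", path=str(path))
    return entries


def transfer(entries, elements, positions,
             policy: str = "strict") -> list[TransferredAtom | None]:
    """Assign every structure atom its bank density and local frame.

    policy='strict' raises on untyped atoms; policy='skip' returns None for
    them (they will be omitted from downstream tables, with a warning).
    """
    if policy not in ("strict", "skip"):
        raise InvalidParameterError("policy must be 'strict' or 'skip'")
    adj = detect_bonds(elements, positions)
    types = [e.atom_type for e in entries]
    by_label = {e.atom_type.label: e for e in entries}
    labels = assign_atom_types(elements, adj, types)
    out: list[TransferredAtom | None] = []
    for i, label in enumerate(labels):
        if label is None:
            sig = tuple(sorted(elements[j] for j in adj[i]))
            msg = (f"atom {i} ({elements[i]}, signature {sig}) matches no "
                   "bank type")
            if policy == "strict":
                raise BankError(msg)
            log.warning("%s; skipped", msg)
            out.append(None)
            continue
        e = by_label[label]
        z_idx, xz_idx = resolve_frame_refs(elements, positions, adj, i,
                                           e.atom_type.frame)
        M = local_frame(positions, i, z_idx, xz_idx)
        out.append(TransferredAtom(label=label, density=e.density, frame=M))
    return out
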