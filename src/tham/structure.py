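"""Crystal structure input, reciprocal-space utilities and ADP conversion.

Supports a minimal CIF subset (P1 cell, fractional coordinates, optional
anisotropic U loop) parsed with gemmi, and a plain XYZ file whose comment
line carries ``cell: a b c alpha beta gamma``.  The orthogonalization
convention is fixed: a along x, b in the xy plane; the same convention is
used for Cartesian ADPs, so CIF aniso tensors are converted consistently.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from gemmi import cif as gemmi_cif

from .errors import InvalidParameterError, ParseError

__all__ = ["UnitCell", "SiteAtom", "CrystalStructure", "read_structure",
           "write_cif", "generate_hkl", "ReflectionList", "u_cif_to_cartesian"]


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0  # degrees
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidParameterError("cell lengths must be positive")
        if self.volume <= 0:
            raise InvalidParameterError("cell volume must be positive")

    @property
    def orthogonalization(self) -> np.ndarray:
        """Matrix A with cell vectors as columns (a || x, b in xy plane)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
        czz2 = 1.0 - cb ** 2 - ((ca - cb * cg) / sg) ** 2
        if czz2 <= 0:
            raise InvalidParameterError("degenerate cell angles")
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * np.sqrt(czz2)],
        ])

    @property
    def volume(self) -> float:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos(al), np.cos(be), np.cos(ga)
        arg = 1 - ca ** 2 - cb ** 2 - cg ** 2 + 2 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return float(self.a * self.b * self.c * np.sqrt(arg))

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """Matrix B with reciprocal vectors a*, b*, c* as columns (A^-1)."""
        return np.linalg.inv(self.orthogonalization).T

    def s_vector(self, hkl) -> np.ndarray:
        """Cartesian S = h a* + k b* + l c* for one or many hkl triples."""
        hkl = np.asarray(hkl, float)
        return hkl @ self.reciprocal_matrix.T


@dataclass(frozen=True)
class SiteAtom:
    label: str
    element: str
    frac: np.ndarray
    u_cif: np.ndarray | None = None  # crystallographic aniso U tensor

    def __post_init__(self):
        object.__setattr__(self, "frac", np.asarray(self.frac, float))
        if not np.all(np.isfinite(self.frac)):
            raise InvalidParameterError(f"atom {self.label}: non-finite "
                                        "fractional coordinates")


@dataclass(frozen=True)
class CrystalStructure:
    cell: UnitCell
    atoms: tuple
    spacegroup: str = "P 1"

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("atom labels must be unique")

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    @property
    def cartesian(self) -> np.ndarray:
        A = self.cell.orthogonalization
        frac = np.array([a.frac for a in self.atoms])
        return frac @ A.T

    def u_cartesian(self, index: int) -> np.ndarray | None:
        a = self.atoms[index]
        if a.u_cif is None:
            return None
        return u_cif_to_cartesian(self.cell, a.u_cif)


def u_cif_to_cartesian(cell: UnitCell, u_cif) -> np.ndarray:
    """Convert a crystallographic aniso U tensor to Cartesian (A^2).

    U_cart = (A D) U_cif (A D)^T with A the orthogonalization matrix and
    D = diag(a*, b*, c*) the reciprocal cell lengths.
    """
    U = np.asarray(u_cif, float)
    A = cell.orthogonalization
    recip_len = np.linalg.norm(cell.reciprocal_matrix, axis=0)
    AD = A @ np.diag(recip_len)
    return AD @ U @ AD.T


def _require_p1(name: str | None, path):
    if name is None:
        return
    clean = name.strip().strip("'\"")
    if clean not in ("P 1", "P1"):
        raise ParseError(f"only space group P 1 is supported, got {clean!r}",
                         path=str(path))


_KNOWN_ELEMENTS = {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl",
                   "Br", "I"}


def _check_element(symbol: str, label: str, path):
    if symbol not in _KNOWN_ELEMENTS:
        raise ParseError(f"atom {label}: unknown element {symbol!r}",
                         path=str(path))


def read_structure(path) -> CrystalStructure:
    """Read a minimal CIF (.cif) or XYZ-with-cell (.xyz) structure file."""
    path = str(path)
    if path.lower().endswith(".xyz"):
        return _read_xyz(path)
    return _read_cif(path)


def _read_cif(path) -> CrystalStructure:
    try:
        doc = gemmi_cif.read_file(path)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"CIF parse failure: {exc}", path=path) from None
    block = doc.sole_block()

    def need(tag):
        v = block.find_value(tag)
        if v is None:
            raise ParseError(f"missing {tag}", path=path)
        return gemmi_cif.as_number(v)

    cell = UnitCell(a=need("_cell_length_a"), b=need("_cell_length_b"),
                    c=need("_cell_length_c"),
                    alpha=need("_cell_angle_alpha"),
                    beta=need("_cell_angle_beta"),
                    gamma=need("_cell_angle_gamma"))
    for tag in ("_symmetry_space_group_name_H-M",
                "_space_group_name_H-M_alt"):
        _require_p1(block.find_value(tag), path)

    table = block.find("_atom_site_", ["label", "type_symbol", "fract_x",
                                       "fract_y", "fract_z"])
    if len(table) == 0:
        raise ParseError("no _atom_site_ loop with fractional coordinates",
                         path=path)
    atoms = {}
    order = []
    for row in table:
        label = row[0]
        _check_element(row[1], label, path)
        frac = [gemmi_cif.as_number(row[k]) for k in (2, 3, 4)]
        atoms[label] = {"element": row[1], "frac": frac, "u": None}
        order.append(label)

    aniso = block.find("_atom_site_aniso_",
                       ["label", "U_11", "U_22", "U_33", "U_12", "U_13",
                        "U_23"])
    for row in aniso:
        label = row[0]
        if label not in atoms:
            raise ParseError(f"aniso loop references unknown atom "
                             f"{label!r}", path=path)
        u11, u22, u33, u12, u13, u23 = (gemmi_cif.as_number(row[k])
                                        for k in range(1, 7))
        atoms[label]["u"] = np.array([[u11, u12, u13],
                                      [u12, u22, u23],
                                      [u13, u23, u33]])
    site_atoms = [SiteAtom(label=lb, element=atoms[lb]["element"],
                           frac=atoms[lb]["frac"], u_cif=atoms[lb]["u"])
                  for lb in order]
    return CrystalStructure(cell=cell, atoms=site_atoms)


def _read_xyz(path) -> CrystalStructure:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ParseError("truncated XYZ file", path=path, line=1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first line must hold the atom count", path=path,
                         line=1) from None
    comment = lines[1]
    if "cell:" not in comment:
        raise ParseError("XYZ comment line must carry 'cell: a b c alpha "
                         "beta gamma'", path=path, line=2)
    try:
        vals = [float(v) for v in
                comment.split("cell:", 1)[1].split()[:6]]
        cell = UnitCell(*vals)
    except (ValueError, TypeError, IndexError):
        raise ParseError("malformed cell specification", path=path,
                         line=2) from None
    if len(lines) < 2 + n:
        raise ParseError(f"expected {n} atom lines", path=path,
                         line=len(lines))
    Ainv = np.linalg.inv(cell.orthogonalization)
    atoms = []
    for k, line in enumerate(lines[2:2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError("atom line needs: element x y z", path=path,
                             line=3 + k)
        el = parts[0]
        _check_element(el, f"{el}{k + 1}", path)
        cart = np.array([float(v) for v in parts[1:4]])
        atoms.append(SiteAtom(label=f"{el}{k + 1}", element=el,
                              frac=Ainv @ cart))
    return CrystalStructure(cell=cell, atoms=atoms)


def write_cif(structure: CrystalStructure, path, title="tham") -> None:
    """Write the minimal CIF subset this package reads."""
    cell = structure.cell
    lines = [f"data_{title}",
             "_symmetry_space_group_name_H-M   'P 1'",
             f"_cell_length_a   {cell.a:.9g}",
             f"_cell_length_b   {cell.b:.9g}",
             f"_cell_length_c   {cell.c:.9g}",
             f"_cell_angle_alpha   {cell.alpha:.9g}",
             f"_cell_angle_beta   {cell.beta:.9g}",
             f"_cell_angle_gamma   {cell.gamma:.9g}",
             "loop_",
             "_atom_site_label",
             "_atom_site_type_symbol",
             "_atom_site_fract_x",
             "_atom_site_fract_y",
             "_atom_site_fract_z"]
    for a in structure.atoms:
        lines.append(f"{a.label} {a.element} {a.frac[0]:.9f} "
                     f"{a.frac[1]:.9f} {a.frac[2]:.9f}")
    aniso = [a for a in structure.atoms if a.u_cif is not None]
    if aniso:
        lines += ["loop_", "_atom_site_aniso_label", "_atom_site_aniso_U_11",
                  "_atom_site_aniso_U_22", "_atom_site_aniso_U_33",
                  "_atom_site_aniso_U_12", "_atom_site_aniso_U_13",
                  "_atom_site_aniso_U_23"]
        for a in aniso:
            u = a.u_cif
            lines.append(f"{a.label} {u[0, 0]:.9g} {u[1, 1]:.9g} "
                         f"{u[2, 2]:.9g} {u[0, 1]:.9g} {u[0, 2]:.9g} "
                         f"{u[1, 2]:.9g}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ReflectionList:
    """Integer hkl triples with their Cartesian S vectors (A^-1)."""
    hkl: np.ndarray         # (n, 3) int
    s_vectors: np.ndarray   # (n, 3) float

    def __post_init__(self):
        hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        object.__setattr__(self, "hkl", hkl)
        object.__setattr__(self, "s_vectors",
                           np.asarray(self.s_vectors, float).reshape(-1, 3))
        seen = {tuple(row) for row in hkl}
        if len(seen) != len(hkl):
            raise InvalidParameterError("duplicate hkl entries")

    @property
    def n_reflections(self) -> int:
        return len(self.hkl)

    @property
    def s_magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.s_vectors, axis=1)


def generate_hkl(cell: UnitCell, d_min: float, friedel: bool = False,
                 max_reflections: int = 10_000_000) -> ReflectionList:
    """All reflections with |S| <= 1/d_min, origin excluded.

    ``friedel=True`` keeps one member of each Friedel pair (the one whose
    first nonzero index is positive); f(-S) = f*(S) recovers the rest.
    """
    if not d_min > 0:
        raise InvalidParameterError("d_min must be positive")
    s_max = 1.0 / d_min
    est = 4.0 / 3.0 * np.pi * s_max ** 3 * cell.volume
    if est > max_reflections:
        raise InvalidParameterError(
            f"resolution {d_min} A would generate about {est:.2e} "
            f"reflections (> {max_reflections:.0e}); raise d_min or the "
            "limit")
    # |h| = |S . a| <= s_max |a|, likewise for k, l
    A = cell.orthogonalization
    lengths = np.linalg.norm(A, axis=0)
    hmax, kmax, lmax = (int(np.floor(s_max * L)) for L in lengths)
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    S = cell.s_vector(hkl)
    keep = (np.linalg.norm(S, axis=1) <= s_max + 1e-12) \
        & np.any(hkl != 0, axis=1)
    hkl, S = hkl[keep], S[keep]
    if friedel:
        sel = []
        for idx, trip in enumerate(hkl):
            nz = trip[np.nonzero(trip)[0]]
            if nz[0] > 0:
                sel.append(idx)
        hkl, S = hkl[sel], S[sel]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return ReflectionList(hkl=hkl[order], s_vectors=S[order])
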