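"""Computation and text I/O of .tsc form-factor tables.

A tsc table lists, per reflection hkl, the complex static form factor of
every scatterer in structure order.  Positional phases and thermal motion
are applied downstream by the refinement program, not here.  The dialect
written is: ``TITLE:``, ``SYMM: expanded``, ``SCATTERERS:`` with
space-separated labels, ``DATA:`` followed by ``h k l re,im re,im ...``
rows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .databank import transfer
from .errors import InvalidParameterError, ParseError
from .scattering import form_factor_multipole
from .structure import CrystalStructure, ReflectionList

__all__ = ["TscTable", "compute_tsc", "write_tsc", "read_tsc"]


@dataclass(frozen=True)
class TscTable:
    title: str
    labels: tuple                 # scatterer labels, structure order
    hkl: np.ndarray               # (n, 3) int
    form_factors: np.ndarray      # (n, n_scatterers) complex

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "hkl",
                           np.asarray(self.hkl, int).reshape(-1, 3))
        ff = np.asarray(self.form_factors, complex)
        if ff.size == 0:
            ff = ff.reshape(len(self.hkl), len(self.labels))
        object.__setattr__(self, "form_factors", ff)
        if ff.shape != (len(self.hkl), len(self.labels)):
            raise InvalidParameterError(
                f"form factor array shape {ff.shape} does not match "
                f"{len(self.hkl)} reflections x {len(self.labels)} "
                "scatterers")
        if not np.all(np.isfinite(ff.view(float))):
            raise InvalidParameterError("non-finite form factor values")


def compute_tsc(structure: CrystalStructure, bank_entries,
                reflections: ReflectionList, l_max: int | None = None,
                policy: str = "strict", title: str = "tham") -> TscTable:
    """Transfer bank densities onto the structure and tabulate form factors.

    Per reflection and atom: f_a(S) = f_bank(M_a S) with M_a the atom's
    local frame.  Untyped atoms follow ``policy`` ('strict' raises; 'skip'
    omits the atom from the table with a warning).
    """
    transferred = transfer(bank_entries, structure.elements,
                           structure.cartesian, policy=policy)
    kept = [(i, t) for i, t in enumerate(transferred) if t is not None]
    labels = [structure.labels[i] for i, _ in kept]
    S = reflections.s_vectors
    ff = np.empty((len(S), len(kept)), complex)
    for col, (_, t) in enumerate(kept):
        ff[:, col] = form_factor_multipole(t.density, S @ t.frame.T,
                                           l_max=l_max)
    return TscTable(title=title, labels=labels, hkl=reflections.hkl,
                    form_factors=ff)


def write_tsc(table: TscTable, path) -> None:
    """Write a tsc table; complex values as ``re,im`` with 10 significant
    digits."""
    lines = [f"TITLE: {table.title}",
             "SYMM: expanded",
             "SCATTERERS: " + " ".join(table.labels),
             "DATA:"]
    for trip, row in zip(table.hkl, table.form_factors):
        vals = " ".join(f"{v.real:.10g},{v.imag:.10g}" for v in row)
        lines.append(f"{trip[0]} {trip[1]} {trip[2]} {vals}".rstrip())
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_tsc(path) -> TscTable:
    """Read a tsc table written by :func:`write_tsc`."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    title, labels = None, None
    data_start = None
    for k, line in enumerate(lines):
        if line.startswith("TITLE:"):
            title = line[6:].strip()
        elif line.startswith("SCATTERERS:"):
            labels = tuple(line.split()[1:])
        elif line.strip() == "DATA:":
            data_start = k + 1
            break
        elif line.startswith("SYMM:"):
            pass
        elif line.strip():
            raise ParseError(f"unexpected header line {line!r}",
                             path=str(path), line=k + 1)
    if title is None or labels is None or data_start is None:
        raise ParseError("incomplete tsc header (need TITLE:, SCATTERERS:, "
                         "DATA:)", path=str(path))
    hkl, rows = [], []
    for k, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3 + len(labels):
            raise ParseError(
                f"expected {3 + len(labels)} fields, got {len(parts)}",
                path=str(path), line=k)
        try:
            hkl.append([int(v) for v in parts[:3]])
            row = []
            for field in parts[3:]:
                re_s, im_s = field.split(",")
                row.append(complex(float(re_s), float(im_s)))
            rows.append(row)
        except ValueError as exc:
            raise ParseError(f"malformed data field: {exc}", path=str(path),
                             line=k) from None
    return TscTable(title=title, labels=labels,
                    hkl=np.array(hkl, int).reshape(-1, 3),
                    form_factors=np.array(rows, complex).reshape(
                        len(hkl), len(labels)))
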