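"""Compute a .tsc form-factor table for a P1 crystal of the water fixture.

Generates reflections to 1 A resolution, transfers the databank onto the
structure and writes/reads the tsc text table.
"""
import tempfile
from pathlib import Path

import numpy as np

from tham import (CrystalStructure, SiteAtom, UnitCell, build_bank,
                  compute_tsc, generate_hkl, make_fixture, read_tsc,
                  write_tsc)

spec = make_fixture("water-like", seed=0)
cell = UnitCell(10, 10, 10)
Ainv = np.linalg.inv(cell.orthogonalization)
atoms = [SiteAtom(label=f"{el}{i + 1}", element=el,
                  frac=Ainv @ (spec.positions[i] + 5.0))
         for i, el in enumerate(spec.elements)]
structure = CrystalStructure(cell=cell, atoms=atoms)

bank = build_bank([spec])
refl = generate_hkl(cell, d_min=1.0)
print(f"{refl.n_reflections} reflections to 1.0 A resolution")

table = compute_tsc(structure, bank, refl)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "water.tsc"
    write_tsc(table, path)
    table = read_tsc(path)
    print(f"tsc table: {len(table.labels)} scatterers x "
          f"{len(table.hkl)} reflections")

i = int(np.argmin(np.linalg.norm(refl.s_vectors, axis=1)))
h, k, l = table.hkl[i]
print(f"lowest-angle reflection ({h} {k} {l}):")
for label, f in zip(table.labels, table.form_factors[i]):
    print(f"  {label:4s} f = {f.real:+.5f}{f.imag:+.5f}i electrons")
print("each column is one atom's static aspherical form factor; the "
      "refinement program adds positional phases and thermal smearing")
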