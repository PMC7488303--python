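"""Build the deformable ultrastructure models: a bead chain and a bead mesh.

A filament is a line of touching beads bonded consecutively; a membrane is
a rectangular bead mesh with axial and diagonal bonds.  Bond stiffness is
high (inextensible) while angle stiffness is zero (free bending) — the
bond-degree pattern printed below is what encodes each deformability.
"""

from tomopack import build_filament, build_membrane

fil = build_filament(9)
print(f"filament: {fil.n_balls} balls (diameter 40), {fil.topology.n_bonds} bonds, "
      f"{len(fil.topology.angles)} free angles")
print("  bond degrees along the chain:", fil.topology.degrees(fil.n_balls).tolist())

mem = build_membrane(5, 5)
deg = mem.topology.degrees(mem.n_balls)
print(f"membrane: 5x5 = {mem.n_balls} balls (diameter 80), {mem.topology.n_bonds} bonds")
print("  degree grid (corners 3, edges 5, interior 8):")
for row in deg.reshape(5, 5):
    print("   ", row.tolist())
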