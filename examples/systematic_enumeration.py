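"""Enumerate the preconditioned systematic guess pool for sp3 chains.

Each backbone torsion of an alkanol-like chain has three chemically
intuitive positions (anti 180, gauche+ 60, gauche- 300), so a chain with
t target torsions yields K1 = 3^t guesses.  A molecule with a plane of
symmetry has conformational enantiomers (phi <-> -phi) of identical
energy, so only one member of each pair needs optimizing: the pool
shrinks to (K1+1)/2, since exactly one grid point (all-anti) is its own
mirror image.
"""

from torsearch import PreconditionedAngles, systematic_pool

print(f"{'t':>2} {'K1 = 3^t':>9} {'reduced (K1+1)/2':>17}")
for t in range(2, 7):
    pre = PreconditionedAngles.sp3_chain(t)
    full = len(systematic_pool(pre, has_sym_plane=False))
    reduced = len(systematic_pool(pre, has_sym_plane=True))
    print(f"{t:>2} {full:>9} {reduced:>17}")

print()
print("Each row: number of trial geometries the systematic phase must")
print("optimize for a chain with t torsions, before and after keeping one")
print("representative per mirror-image pair.")
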