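"""Nanotube geometry: zigzag walls at prescribed diameters.

A zigzag (n, 0) tube has diameter sqrt(3) * a_cc * n / pi; the three-wall
tube stacks the walls coaxially, innermost first, with roughly the
graphitic 0.35 nm gap.
"""
from nanosorb import build_mwcnt, build_zigzag
from nanosorb.cnt import NanotubeSpec

sw = build_zigzag(NanotubeSpec(chirality_n=82, length=20.0))
print(f"single wall: n={sw.spec.chirality_n}, diameter {sw.spec.diameter:.3f} nm, "
      f"{sw.n_rings} rings, {sw.n_atoms} atoms")

walls = build_mwcnt([6.42, 7.12, 7.83], length=20.0)
print("three-wall tube:")
for w in walls:
    print(f"  n={w.spec.chirality_n:>3}: diameter {w.spec.diameter:.3f} nm, "
          f"{w.n_atoms} atoms")
gap = (walls[1].spec.diameter - walls[0].spec.diameter) / 2
print(f"inter-wall gap: {gap:.3f} nm")
print("-> the realized diameters match the requested 6.42 / 7.12 / 7.83 nm "
      "to the rounding of the integer chirality index.")
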