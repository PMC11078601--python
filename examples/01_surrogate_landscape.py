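"""Build the three cation presets and inspect the surrogate landscape.

Prints, per preset, the activation barrier, the site-well depths and the
macrostate classification of a few probe configurations.  The barriers are
ordered OCH3 > H > CF3 (the substituent series), while the long-range
attraction -- which controls the diffusional encounter -- is identical.
"""

from wepath import surrogate as sg

for name in ("OCH3", "H", "CF3"):
    p = sg.make_surrogate(name)
    print(f"{name:5s} barrier = {p.barrier_height:.1f} kT  "
          f"well depths = {p.depths}  attraction = {p.long_range_strength}")

p = sg.make_surrogate("H")
print("\nmacrostate thresholds (reduced Angstrom): >10 unassociated, "
      "5-2.25 ion pair, <1.6 product")
for r in (12.0, 7.0, 3.5, 2.0, 1.2):
    c = sg.Configuration(r)
    print(f"  r = {r:5.2f}  ->  {sg.classify_macrostate(c)!s:14s} "
          f"nearest site = {sg.nearest_site(p, c)}  "
          f"U = {sg.potential(p, c):7.3f} kT")

pmin = sg.product_minimum(p)
print(f"\nproduct minimum at r = {pmin.r:.3f}, "
      f"U = {sg.potential(p, pmin):.2f} kT (global minimum)")
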