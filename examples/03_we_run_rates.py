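"""One weighted-ensemble simulation of the unsubstituted preset, with rates.

Runs 120 WE iterations (tau = 0.5 reduced ps, 5 walkers/bin), then prints
the Hill-relation rate constants for each mechanistic step and the percent
productive collisions.  k_minus1 >> k_2 marks the activation-limited regime:
most ion pairs dissociate instead of reacting.
"""

from wepath import kinetics as kin, surrogate as sg
from wepath.engine import LangevinSystem, default_mapper, run_we

params = sg.make_surrogate("H")
pool = sg.initial_pool(params, 50, seed=1)
system = LangevinSystem(params, pool)
rec = run_we(system, default_mapper(), 120, seed=1)

for name, (src, dst, bimol) in kin.RATE_DEFINITIONS.items():
    f = kin.conditional_flux(rec, src, dst)
    p = kin.steady_state_population(rec, src, versus=dst)
    r = kin.hill_rate(f, p)
    kind = "per (reduced M) per ps" if bimol else "per ps"
    print(f"{name:9s} = {r:.3e}  {kind}   [{src} -> {dst}]")

print(f"\npercent productive collisions = {kin.percent_productive(rec):.1f}%")
print("recycled (reactive) events:", int(sum(it.recycled.sum()
                                             for it in rec.iterations)))
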