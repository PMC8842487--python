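"""Conformational diagnostics of the micelle exit pathway.

Tracks the PO-block radius of gyration and the EO-PO-EO angle of every chain
against the distance of its hydrophobic block from the micelle centre.  A
dip of Rg_PO and of the angle near the core/corona interface is the hairpin
signature: chains crumple their hydrophobic block to minimise solvent
contact while crossing the corona.
"""

import numpy as np

from micellex.analysis import radial_profiles, region_boundaries
from micellex.chain import SEMIFLEXIBLE, DEFAULT_POTENTIAL
from micellex.dynamics import build_micelle_state, run_exchange

state = build_micelle_state(SEMIFLEXIBLE, DEFAULT_POTENTIAL, n_micelle=90, seed=5)
series, diag = run_exchange(state, n_cycles=15000, burn_in=3000, prof_stride=25)
r, rg, ang = diag["profiles"]
print(f"collected {r.size} (chain, frame) samples")

fields = state.field_state()
try:
    b = region_boundaries(fields, state.lattice)
    print(f"core/corona interface at r = {b.r_core_corona:.1f} sigma, "
          f"corona/bulk at r = {b.r_corona_bulk:.1f} sigma")
except Exception as exc:
    print("interface detection:", exc)

bulk = r > diag["r_bound"]
rg_star = float(np.nanmean(rg[bulk])) if np.any(bulk) else None
prof_rg, prof_an = radial_profiles(r, rg, ang, rg_star=rg_star, r_max=24.0, min_count=30)
print(f"bulk PO-block Rg* = {rg_star:.2f} sigma" if rg_star else "no bulk samples")
print("\n  r (sigma)   Rg_PO/Rg*    EO-PO-EO angle (deg)")
for i in range(prof_rg.r_mid.size):
    if prof_rg.defined()[i] or prof_an.defined()[i]:
        print(f"  {prof_rg.r_mid[i]:8.2f}   {prof_rg.mean[i]:9.3f}   {prof_an.mean[i]:12.1f}")
print("\nvalues below 1 in the core mean the hydrophobic block is crumpled;"
      "\nthe ratio returns to 1 once chains reach the bulk solution.")
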