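"""SFS-based sweep scan: CLR, nucleotide diversity, Tajima's D per window.

Simulates polymorphism for one taxon (n = 22 chromosomes) with planted
sweeps in 1% of the 2-kb windows, scans every window, and checks how many
planted sweeps land in the top-1% CLR set.
"""

import numpy as np

from altadapt.core_io import tile_windows
from altadapt.sweepscan import scan_windows, top_outliers, windows_from_sites
from altadapt.synthetic_data import plan_sweep_windows, simulate_polymorphism

rng = np.random.default_rng(4)
contigs = {f"c{i}": 1_000_000 for i in range(1, 5)}    # 2,000 windows
windows = tile_windows(contigs, 2000)
sweeps = plan_sweep_windows(windows, set(), fraction=0.01, rng=rng)
sites, truth = simulate_polymorphism(contigs, windows, sweep_windows=sweeps,
                                     f_s=0.2, w=0.8, rng=rng)
print(f"{len(sites)} segregating sites in {len(windows)} windows; "
      f"{len(sweeps)} planted sweeps")

scan = scan_windows(windows_from_sites(sites, windows))
ok = scan[scan["flag"] == "ok"]
neutral = ok[~ok["window_id"].isin(set(sweeps))]
swept = ok[ok["window_id"].isin(set(sweeps))]
print(f"neutral windows: median CLR {neutral['clr'].median():.2f}, "
      f"median pi {neutral['pi'].median():.4f}, "
      f"median D {neutral['tajimas_d'].median():+.2f}")
print(f"sweep windows:   median CLR {swept['clr'].median():.2f}, "
      f"median pi {swept['pi'].median():.4f}, "
      f"median D {swept['tajimas_d'].median():+.2f}")

selected = top_outliers(scan, 0.01)
hit = len(set(selected["window_id"]) & set(sweeps))
print(f"\ntop-1% CLR set: {len(selected)} windows, {hit} planted sweeps "
      f"recovered ({100 * hit / len(sweeps):.0f}% sensitivity)")
print(
    "\nSwept windows lose most diversity (low pi), skew toward rare"
    "\nalleles (negative D), and rise in CLR; with only ~4 segregating"
    "\nsites left per 2-kb swept window, per-window power is modest."
)
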