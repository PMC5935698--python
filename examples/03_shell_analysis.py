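"""Solvation-shell structure from synthetic configurations.

Generates a ten-temperature toy trajectory with the quadratic Z(T) and
R(T) trends, computes the Xe-O radial distribution function and its
first minimum, per-temperature shell statistics, and refits the trends.
"""

import xecavity as x

spec = x.SyntheticSpec(
    seed=7,
    frames_per_temperature=100,
    z_source=x.Z_TREND_MD,
    r_source=x.R_TREND_MD,
)
traj = x.gen_trajectory(spec)

rdf = x.compute_rdf(traj[278.0], bin_width=0.05, max_radius=6.5)
r1 = x.find_first_minimum(rdf)
print(f"RDF first minimum r1 = {r1:.2f} Å (bounds the first shell)")

print("\nT (K)   Z (mean ± SEM)      R (Å, mean ± SEM)")
stats = []
for T in sorted(traj):
    s = x.shell_statistics(traj[T], 5.5)
    stats.append(s)
    print(f"{T:5.0f}   {s.z_mean:6.2f} ± {s.z_sem:.3f}   {s.r_mean:8.4f} ± {s.r_sem:.4f}")

zmodel, rmodel = x.fit_structural_trends(stats)
print(f"\nfitted Z(T): vertex {zmodel.z0:.3f} at {zmodel.t_max:.1f} K "
      f"(generator: 21.989 at 260.6 K)")
print(f"fitted R(T): vertex {rmodel.r0:.4f} Å at {rmodel.t_min:.1f} K "
      f"(generator: 4.2675 Å at 292.3 K)")
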