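"""Convert a proliferation index into per-capita rates and pull-through.

The Ki-67 proliferation index I is the fraction of cells in cycle; with a
cell-cycle time T (hours) the per-capita daily net gain rate is
beta = 24 I / T.  Combined with the fitted dimensionless gamma_GZ and the
measured CZ radius, this yields the pull-through parameter
k* = beta r_CZ / gamma_GZ in mm/day.
"""

from optlens import beta_from_index, estimate_k_star

index, t_hours = 0.005, 40.0  # 0.5% of cells in a 40 h cycle
beta = beta_from_index(index, t_hours)
print(f"I = {index:.1%}, T = {t_hours:.0f} h  ->  beta = {beta:.4g} per day")

gamma_gz, r_cz = 5.13, 4.0  # consensus fit; bovine-scale CZ radius in mm
k_star = estimate_k_star(gamma_gz, index, t_hours, r_cz)
print(f"gamma_GZ = {gamma_gz}, r_CZ = {r_cz} mm  ->  k* = {k_star:.4g} mm/day")
print("k* is the speed at which the ordered exit into the lens body pulls")
print("epithelial cells radially outward.")
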