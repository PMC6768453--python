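"""Convert measured K_i values to binding free energies and score two models.

Takes the measured inhibition constants of six receptor ligands, converts
them to experimental binding free energies via dG_exp = kT ln K_i, and
summarises the accuracy (RMSE, Pearson r) of calculated binding free
energies from two model variants: with and without the enclosed-hydration
correction.
"""

from hydrabind import accuracy_summary, ki_to_dg

compounds = ["1a", "1b", "1c", "1d", "1e", "1f"]
ki_nm = [40.0, 46.0, 51.0, 33.0, 26.0, 86.0]
dg_calc_without = [-2.2, -2.3, -1.8, -0.3, -3.9, -3.1]
dg_calc_with = [-8.8, -10.4, -11.5, -10.6, -12.5, -8.9]

dg_exp = [ki_to_dg(k, 298.15, unit="nM") for k in ki_nm]
print(f"{'cmpd':>5} {'Ki (nM)':>8} {'dG_exp':>7} {'calc w/o':>9} {'calc w/':>8}")
for c, k, e, wo, w in zip(compounds, ki_nm, dg_exp, dg_calc_without, dg_calc_with):
    print(f"{c:>5} {k:>8.1f} {e:>7.2f} {wo:>9.1f} {w:>8.1f}")

without = accuracy_summary(zip(dg_exp, dg_calc_without))
with_hyd = accuracy_summary(zip(dg_exp, dg_calc_with))
print(f"\nwithout enclosed hydration: RMSE = {without.rmse:.1f} kcal/mol, "
      f"r = {without.pearson_r:.2f} (n={without.n})")
print(f"with    enclosed hydration: RMSE = {with_hyd.rmse:.1f} kcal/mol, "
      f"r = {with_hyd.pearson_r:.2f} (n={with_hyd.n})")
# Including the enclosed-hydration term shrinks the error by a factor of ~6:
# the binding affinity of these ligands is dominated by the displacement of
# frustrated water from the binding site.
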