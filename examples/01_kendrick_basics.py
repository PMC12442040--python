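"""Kendrick projection of a published triacylglyceride series.

Computes Kendrick mass (KM) and ceiling-mode Kendrick mass defect
(KMD) for the sodiated TG 50:3 / 52:3 / 54:3 homologous series.  The
three ions differ by exact CH2 multiples, so their KMDs coincide to
within float precision — the property that makes homologous families
fall on horizontal lines in a KMD vs m/z plot.
"""

from kmdmsi import ion_mz, kendrick_mass, kmd_of_mz, ppm_error

series = [("TG 50:3", "C53H96O6"), ("TG 52:3", "C55H100O6"), ("TG 54:3", "C57H104O6")]
observed = [851.7103, 879.7418, 907.7737]  # experimental values from the study

print(f"{'species':9s} {'m/z the':>9s} {'m/z exp':>9s} {'dM ppm':>7s} {'KM':>10s} {'KMD':>8s}")
for (name, formula), mz_exp in zip(series, observed):
    theo = ion_mz(formula, "[M+Na]+")
    print(
        f"{name:9s} {theo:9.4f} {mz_exp:9.4f} {ppm_error(mz_exp, theo):7.1f} "
        f"{kendrick_mass(theo):10.4f} {kmd_of_mz(theo):8.5f}"
    )

print(
    "\nThe KMD column is constant across the series (same lipid family, "
    "growing CH2 count); the dM column is the experimental mass error in ppm."
)
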