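"""Recompute the published annotation tables from elemental compositions.

Loads the bundled fixture of the study's three annotation tables and
re-derives every theoretical m/z (additive monoisotopic masses, minus
one electron for the +1 charge) and every |ΔM|.  Prints how many rows
agree to the printed precision and lists the documented exceptions.
"""

from kmdmsi import recompute_tables

report = recompute_tables()
strict = report[report["mz_agrees"].notna() & ~report["known_exception"]]
print(f"identified rows checked strictly : {len(strict)}")
print(f"  theoretical m/z to 4 dp        : {int(strict['mz_agrees'].sum())}")
have_ppm = report[report["ppm_agrees"].notna()]
print(f"rows with a printed dM           : {len(have_ppm)}")
print(f"  |dM| within 0.2 ppm            : {int(have_ppm['ppm_agrees'].sum())}")
print("documented exceptions:")
for _, row in report[report["known_exception"]].iterrows():
    print(f"  m/z {row['mz_exp']:.4f}  {row['best_match']:28s} {row['note']}")
print(
    "\nA strict row agrees when the recomputed ion mass matches the printed "
    "theoretical m/z to 4 decimal places; exceptions are curation notes, "
    "not computation failures."
)
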