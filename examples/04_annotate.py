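"""Generate chemical hypotheses for feature masses.

All ions are assumed [M+H]+: the neutral mass is m/z - 1.00728 Da. Each feature
is matched against the bundled compound library at +/-200 ppm, and plausible
elemental compositions are enumerated exhaustively at +/-10 ppm.
"""

from breathsig import enumerate_formulas, match_library, neutral_mass
from breathsig.annotate import default_max_counts

for mz in (69.070, 77.059, 44.991, 63.026):
    print(f"\nfeature m/z {mz}  (neutral {neutral_mass(mz):.5f} Da)")
    for c in match_library(mz, tol_ppm=200):
        print(f"  library : {c.name_or_formula:28s} {c.error_ppm:+8.1f} ppm")
    nm = neutral_mass(mz)
    cands = enumerate_formulas(nm, tol_ppm=10, max_counts=default_max_counts(nm))
    for c in cands[:5]:
        print(f"  formula : {c.name_or_formula:28s} {c.error_ppm:+8.1f} ppm")
    if not cands:
        print("  formula : none within 10 ppm under CHNOPS plausibility rules")
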