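"""Stem-cell transplantation scenario used to calibrate self-renewal.

Counts are read as cells per kg body weight: the graft is 4e6 CD34+
cells/kg of which ~3/4 are myeloid; recovery means 5e8 neutrophils per
liter of blood (5 L / 70 kg).  Clinically, recovery takes 2-3 weeks --
the healthy parameters reproduce that.
"""
from hemaclone import transplant_recovery

days = transplant_recovery()
print(f"neutrophil recovery after transplantation: {days:.1f} days (expect 14-21)")

for dose in (1e6, 3e6, 1e7):
    print(f"  dose c1(0) = {dose:.0e} cells/kg -> recovery in "
          f"{transplant_recovery(initial_mitotic=dose):.1f} days")
print("larger grafts recover faster, as expected.")
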