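"""Demyelination factors from SEM myelin-thickness measurements.

The demyelination factor is the fractional loss of myelin thickness,
gamma = (D0 - D)/D0, against the healthy baseline D0 = 1.79 um.  The mean
thicknesses below are the published values for toad sciatic nerves treated
with crude cobra venom and with the purified PLA2 fraction at three doses;
the printed gammas (0.32...0.50) quantify how much myelin each dose
destroyed.
"""

from demyelin import gamma_from_thickness
from demyelin.quantification import delta_d

D0 = 1.79  # um, normal nerve

treatments = [
    ("crude venom 0.1 ug/ml", 1.22),
    ("crude venom   1 ug/ml", 1.00),
    ("crude venom  10 ug/ml", 0.91),
    ("PLA2        0.1 ug/ml", 1.40),
    ("PLA2          1 ug/ml", 1.12),
    ("PLA2         10 ug/ml", 0.89),
]

print(f"baseline thickness D0 = {D0} um")
print(f"{'treatment':24s} {'D (um)':>7s} {'dD (um)':>8s} {'gamma':>6s}")
for label, d in treatments:
    g = gamma_from_thickness(D0, d)
    print(f"{label:24s} {d:7.2f} {delta_d(D0, d):8.2f} {g:6.2f}")
print()
print("gamma = 0.44 means the 1 ug/ml dose stripped 44% of the myelin.")
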