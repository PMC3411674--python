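"""Activation z-score of a transcriptional regulator from marker directions.

A regulator is summarized by its regulon: target genes with the expected
direction of change (+1 activating, -1 inhibiting) when the regulator is
active. Observed up/down calls for the targets give
z = sum(expected * observed) / sqrt(#observed); |z| >= 2 is flagged.
"""

from vakgbm import Regulon, regulator_z

# a toy tumor-suppressor-like regulon: activates G1..G4, represses G5/G6
regulon = Regulon(
    "TS1",
    [("G1", +1), ("G2", +1), ("G3", +1), ("G4", +1), ("G5", -1), ("G6", -1)],
)

cases = {
    "fully concordant (active)": {"G1": 1, "G2": 1, "G3": 1, "G4": 1, "G5": -1, "G6": -1},
    "fully discordant (inhibited)": {"G1": -1, "G2": -1, "G3": -1, "G4": -1, "G5": 1, "G6": 1},
    "mixed evidence": {"G1": 1, "G2": -1, "G3": 1, "G4": -1},
    "no observed targets": {},
}

for label, observed in cases.items():
    z = regulator_z(regulon, observed)
    if z is None:
        print(f"{label}: z undefined (no observed targets)")
    else:
        flag = " [significant]" if abs(z) >= 2 else ""
        print(f"{label}: z = {z:+.2f}{flag}")

# Positive z: the expression changes look like the regulator is switched on;
# negative z: switched off. |z| grows with the number of concordant targets.
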