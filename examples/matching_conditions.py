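"""Analytic matching conditions for pyruvate SABRE.

Prints, for the published coupling set (J_HH = -10.5 Hz, hydride-carbon
couplings 0.06 and 0 Hz), the continuous-wave settings that close the
relevant level crossings: the on-resonance SLIC amplitude for x-transfer,
the magic-angle (offset, amplitude) pair for z-transfer, and the static
field at which SABRE-SHEATH matches the same crossing without any drive.
"""

import json

import sabrespin as sb

report = sb.matching_report(J_HH=-10.5, J_HC_a=0.06, J_HC_b=0.0)
print(json.dumps(report, indent=2))

print()
print("x-transfer: drive the carbon on resonance at", report["x_matching_amplitude_hz"], "Hz;")
print("the singlet-to-carbon channel is the tiny off-diagonal element",
      report["x_block_off_diagonal_hz"], "Hz = dJ_CH/4.")
print("z-transfer: detune by", round(report["z_matching_offset_hz"], 2),
      "Hz with amplitude", round(report["z_matching_amplitude_hz"], 2),
      "Hz (tilt =", round(report["magic_angle_deg"], 2), "deg).")
print("SABRE-SHEATH: the same crossing opens with no drive at B0 =",
      round(report["sheath_matching_field_ut"], 3), "uT.")
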