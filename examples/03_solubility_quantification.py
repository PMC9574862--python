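"""Shake-flask HPLC-UV quantification and GSK classification.

A calibration line (AUC vs concentration) is inverted for a saturated
sample after dilution correction; the concentration converts to molar
log S via the molecular weight and falls into one of the GSK classes:
low < 30 uM, intermediate 30-200 uM, high > 200 uM."""

from protacsol import fit_calibration, quantify
from protacsol.solubility import finalize_measurement

curve = fit_calibration([(c, 212.0 * c + 1.4) for c in (0.05, 0.1, 0.2, 0.4, 0.8)])
print(f"calibration: AUC = {curve.slope:.1f}*conc + {curve.intercept:.2f} (R2 = {curve.r2:.4f})")

meas = quantify(auc=9.1, curve=curve, dilution_factor=10, compound_id="DEG-X")
finalize_measurement(meas, mw=950.0)  # g/mol
print(f"solubility  = {meas.conc_mg_ml:.3f} mg/mL")
print(f"log S       = {meas.log_s:.2f} (mol/L)  ->  {meas.s_micromolar:.0f} uM")
print(f"GSK class   = {meas.gsk_class.value}")
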