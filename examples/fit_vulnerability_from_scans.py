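"""Optical vulnerability curve from a synthetic leaf scan sequence.

Builds a 120-frame stack in which embolism pixel clusters appear according
to a known vulnerability curve while stem water potential declines, runs
the difference-imaging pipeline (outlier removal, thresholding, cumulative
percentage of embolised pixels) and refits the sigmoid to recover P50 and
the slope, plus the P12/P88 thresholds from their closed forms.
"""

from ideovine.optical import OpticalConfig, quantify_optical_embolism
from ideovine.synth import gen_optical_stack
from ideovine.traits import fit_vulnerability_curve
from ideovine.types import VulnerabilityCurve

truth = VulnerabilityCurve(p50=-1.8, slope=60.0)
dataset = gen_optical_stack(truth, frames=120, seed=3, noise_density=0.001)

pep = quantify_optical_embolism(
    dataset.stack, OpticalConfig(median_size=3, threshold_abs=30.0)
)
curve, p12, p88 = fit_vulnerability_curve(pep["pep"], pep["psi_stem"])

print(f"frames analysed : {len(pep)}")
print(f"P50  = {curve.p50:6.3f} MPa      (truth {truth.p50})")
print(f"slope= {curve.slope:6.1f} % MPa-1  (truth {truth.slope})")
print(f"P12  = {p12:6.3f} MPa, P88 = {p88:6.3f} MPa")
print()
print("P50 is the stem water potential at which half of the leaf xylem has")
print("embolised; P12 marks the onset and P88 near-total loss of conductivity.")
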