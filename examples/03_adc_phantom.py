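"""ADC-distribution analysis of a repeated-scan diffusion-MRI phantom.

Generates a two-well phantom (control-like vs mutant-like organoids with
a 9% higher mean ADC), five consecutive scans with Rician noise and a
common upward drift; fits per-voxel ADC maps, reduces each group to a
denoised 100-bin distribution, locates the 2/3-of-peak maximal-likelihood
position, and reports each scan's relative deviation from control with a
matched t test (the per-scan ratio cancels the drift).
"""

from organoid_mech import adc
from organoid_mech.synth import gen_dwi_phantom

phantom = gen_dwi_phantom(adc_mean={"control": 1.0e-3, "mutant": 1.09e-3},
                          n_scans=5, scan_drift=0.02, snr_b0=30.0, seed=0)

positions = {}
for stack in phantom.stacks:
    tissue = adc.segment_organoids(stack)
    for group in ("control", "mutant"):
        amap = adc.fit_adc_map(stack, mask=phantom.group_mask(group) & tissue)
        pos = adc.scan_ml_position(amap)
        positions.setdefault(group, {})[stack.scan_id] = pos
        print(f"{stack.scan_id} {group:8s} ML position = {pos * 1e3:.4f} "
              f"x 1e-3 mm^2/s")

out = adc.group_comparison(positions, reference_group="control")["mutant"]
print()
print(f"mutant vs control: {out['mean_pct']:.1f} +/- {out['sd_pct']:.1f} % "
      f"(matched t = {out['t']:.2f}, p = {out['p']:.1e}, n = {out['n_scans']} scans)")
print()
print("ML positions creep upward scan by scan (the injected drift), but the")
print("per-scan relative deviation recovers the generated 9% ADC offset.")
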