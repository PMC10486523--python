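"""ADC estimation from a noisy diffusion-weighted phantom.

Simulates monoexponential diffusion decay at b = 0, 100, 800 s/mm^2 with
Rician magnitude noise at SNR 20, fits the ADC map by log-linear least
squares and reports the ROI mean against the known truth. The residual
error illustrates the small Rician bias at this noise level.
"""

from immunomri import FieldParams, PhantomSpec, fit_adc_map, make_dwi_phantom, mean_adc

spec = PhantomSpec(
    grid_shape=(32, 32, 32),
    tumor_radii=(8.0, 9.0, 10.0),
    adc_field=FieldParams(mean=1.0e-3, gradient=(0.0, 0.0, 4e-6)),  # mm^2/s
    s0_background=1000.0,
    noise_model="rician",
    noise_sigma=50.0,  # SNR 20 at b = 0
    seed=7,
)
series, roi, truth = make_dwi_phantom(spec)
adc_map = fit_adc_map(series, roi, with_r2=True)
estimate = mean_adc(adc_map, roi)

print(f"fitted voxels      : {int(adc_map.valid.sum())}")
print(f"ROI mean ADC       : {estimate * 1e3:.4f} x10^-3 mm^2/s")
print(f"true mean ADC      : {truth.mean_adc_true * 1e3:.4f} x10^-3 mm^2/s")
print(f"relative error     : {abs(estimate - truth.mean_adc_true) / truth.mean_adc_true:.2%}")
# Low ADC reflects high cellularity; treatment-induced cell death typically
# raises ADC, so the pre/post difference (post - pre) is the readout.
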