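"""Forward-project a two-tissue phantom and reconstruct it with FBP.

Builds a 128x128 specimen-like phantom (adipose background, fibroglandular
inclusions), computes its 360-view parallel-beam sinogram, reconstructs with
the Shepp-Logan-filtered backprojection, and reports the reconstruction
error.  The RMSE printed is in the same attenuation units as the phantom
(tissue values are 0.2-0.4), so a value of ~0.01 means the dense-view
reconstruction is accurate to a few percent of tissue contrast.
"""

import numpy as np

import sinomar as sm

geometry = sm.ScanGeometry()  # 128x128 grid, 180 bins, 360 views at 1 degree
spec = sm.PhantomSpec(
    background=sm.Ellipse(0.0, 0.0, 48.0, 40.0, 15.0, 0.2),
    tissues=(
        sm.Ellipse(-12.0, 6.0, 14.0, 10.0, 30.0, 0.4),
        sm.Ellipse(16.0, -8.0, 10.0, 8.0, 120.0, 0.38),
        sm.Ellipse(4.0, 18.0, 6.0, 6.0, 0.0, 0.12),
    ),
)
phantom = sm.generate_phantom(spec, geometry)
sinogram = sm.forward_project(phantom)
recon = sm.fbp_reconstruct(sinogram)  # Shepp-Logan filter, cutoff 1.0

print(f"sinogram shape (bins, views): {sinogram.values.shape}")
mass = sinogram.values.sum(axis=0) * geometry.bin_spacing
print(f"mass conservation spread across views: "
      f"{100 * (mass.max() - mass.min()) / mass.mean():.3f}%")
print(f"FBP vs phantom RMSE: {sm.rmse(recon.values, phantom.values):.4f} "
      f"(attenuation units; tissue contrast is 0.2)")
print(f"FBP vs phantom SSIM: {sm.ssim(recon.values, phantom.values):.4f}")
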