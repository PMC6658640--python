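"""Recovery-coefficient curves on the NEMA image-quality phantom.

Builds the six-sphere NEMA IQ phantom (10-37 mm diameters, 10:1
contrast), renders it at three effective resolutions and prints the
max-voxel recovery coefficient per sphere: the fraction of the true
uptake recovered after partial-volume blurring. Smaller spheres and
wider point-spread functions recover less.
"""

from petharmony import (
    ReconProfile,
    build_phantom,
    nema_iq_preset,
    recovery_coefficients,
    simulate_reconstruction,
)

spec = nema_iq_preset(contrast=10.0)
truth, masks = build_phantom(spec)
spheres = {k: v for k, v in masks.items() if k.startswith("sphere")}
uptakes = {k: 10.0 for k in spheres}

diameters = [10, 13, 17, 22, 28, 37]
print("sphere diameter (mm):  " + "  ".join(f"{d:5d}" for d in diameters))
for fwhm in (4.0, 5.0, 7.0):
    profile = ReconProfile("probe", psf_fwhm_mm=fwhm, noise_cv=0.0,
                           matrix=(80, 80), pixel_mm=4.0, slice_mm=4.0)
    recon = simulate_reconstruction(truth, profile, seed=0, grid=truth.geometry)
    rc = recovery_coefficients(recon, spheres, uptakes).set_index("region")
    row = [rc.loc[f"sphere_{i}", "rc_max"] for i in range(1, 7)]
    print(f"RC_max at {fwhm:.0f} mm FWHM:  " + "  ".join(f"{v:5.2f}" for v in row))
print(
    "\nAn accreditation band (per-sphere RC limits) can be supplied via the"
    "\n`limits=` argument to flag spheres outside the harmonized range."
)
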