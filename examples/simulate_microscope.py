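"""Ray-trace the stock ball-lens phone microscope and print its metrics.

The attachment is a 1 mm glass ball (n = 1.5168) and a 0.8 mm field
aperture in front of a phone camera (ideal thin lens, EFL 3.36 mm, sensor
3.55 x 2.68 mm with 2.2 um pixels at the lens's focal plane).
"""

from pocketscope import optics

train = optics.build_iphone2g_microscope()
m = optics.system_metrics(train, wavelength_nm=550.0)

print(f"magnification            : {m.magnification:.2f} x")
print(f"field of view (object)   : {m.field_of_view_diameter_mm:.3f} mm diameter")
print(f"best focus (ball centre) : {m.best_focus_object_distance_mm:.4f} mm")
print(f"best focus (front surf.) : {m.best_focus_from_front_surface_mm:.4f} mm")
print(f"numerical aperture       : {m.numerical_aperture:.3f} "
      f"(raw survival scan {m.numerical_aperture_real:.3f})")
print(f"depth of field           : {m.depth_of_field_um:.2f} um "
      f"(diffraction est. {m.depth_of_field_diffraction_um:.2f} um)")
print(f"Rayleigh resolution      : {m.rayleigh_resolution_um:.3f} um at 550 nm")
print()
print("The magnification is the chief-ray image/object height ratio; the")
print("FOV is sensor-limited; NA is the paraxial marginal-ray sine; the")
print("depth of field is the axial range adding at most one pixel of blur.")
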