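"""Analyze one fundus photograph end to end.

Renders a synthetic fundus image with known vessel geometry (arterioles
7 px, venules 11 px wide), then runs the full chain: vessel extraction,
A* tracking between the annotated segment endpoints, per-pixel caliber,
tortuosity, and the automated disc/ROI/fractal analysis.
"""

from retmorph import pipeline, synthetic

img, truth = synthetic.generate(synthetic.default_image_spec(seed=1))
report = pipeline.analyze_image(img, truth.annotations)

avr = report["avr"]
print(f"arteriole mean width: {avr['arteriole_mean_px']:.2f} px (drawn 7)")
print(f"venule mean width:    {avr['venule_mean_px']:.2f} px (drawn 11)")
print(f"AVR: {avr['avr']:.3f} (drawn ratio 7/11 = {7 / 11:.3f})")
print(f"TI (composite):  {report['tortuosity']['mean_ti_composite']:.2f}")
print(f"TI (arc/chord):  {report['tortuosity']['mean_ti_arc_chord']:.3f}")
disc = report["optic_disc"]
print(f"optic disc: center {tuple(round(v, 1) for v in disc['center'])}, "
      f"radius {disc['radius_px']:.1f} px (drawn {truth.disc_radius})")
print(f"mean-D: {report['fractal']['mean_d']:.3f}")
print()
print("AVR near the drawn 0.636 and a disc radius within a few px of 40")
print("show the measurement chain recovering the generator's ground truth.")
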