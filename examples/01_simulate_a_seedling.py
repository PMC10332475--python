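"""Generate one synthetic potted seedling scene and inspect its ground truth.

The generator builds a curved-stem conifer seedling (bright stem, dim
needles, dense apical canopy) in a flowerpot on a platform, as a ToF camera
would see it.  Every trait the pipeline later estimates is recorded as
ground truth.
"""

import seedlingpheno as sp

spec = sp.PlantSpec(height=0.225, stem_diameter=0.004, seed=7)
plant, truth = sp.generate_plant(spec)
geom = sp.SceneGeometry(dcc=1.35, dcp=0.45)
scene, labels = sp.generate_scene(plant, geom, seed=7, plant_labels=truth.labels)

print(f"plant cloud: {len(plant)} points; full scene: {len(scene)} points")
print(f"true height: {truth.height * 100:.2f} cm  (soil at z = {truth.z_soil} m)")
print(f"true stem diameter: {truth.stem_diameter * 1000:.2f} mm")
print(f"true main stem length: {truth.main_stem_length * 100:.2f} cm")
print(f"needles below the canopy: {truth.leaf_count}")
for r in truth.regions:
    mean = "-" if r.mean_needle_length is None else f"{r.mean_needle_length * 100:.1f} cm"
    print(f"  region {r.index} ({r.arc_range[0] * 100:.0f}-{r.arc_range[1] * 100:.0f} cm "
          f"below canopy): {r.needle_count} needles, mean length {mean}")

# The scene can be written to PLY/PCD for any external viewer:
# sp.write_cloud(scene, "scene.ply")
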