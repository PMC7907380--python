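"""Compute context-standardized movement features for a small herd.

Shows the four feature classes per animal-minute and why contextual
standardization matters: the same speed is unremarkable in open habitat
but anomalous where animals normally move slowly.
"""

from herdwatch import (SimulationConfig, degrade_to_sensor,
                       generate_landscape, preprocess_track, simulate_herds)
from herdwatch.features import (build_feature_matrix, build_reference,
                                feature_report, standardize)

landscape = generate_landscape(seed=1, extent_m=2000.0, cell_m=10.0)
config = SimulationConfig(n_per_species={"zebra": 6, "wildebeest": 6})
tracks = simulate_herds(landscape, config, duration_s=5400.0, seed=7)
regular = [preprocess_track(degrade_to_sensor(t, config, seed=20 + i,
                                              fast_interval_s=120.0),
                            landscape.bbox)
           for i, t in enumerate(tracks)]

matrix = build_feature_matrix(regular, landscape)
print("feature columns per class:")
print(feature_report(matrix).to_string())

reference = build_reference(matrix, "species")
z = standardize(matrix, reference)
speed_z = z["speed__z_species"].dropna()
print(f"\nrows (animal-minutes): {len(matrix)}")
print(f"standardized speed: mean {speed_z.mean():+.3f}, "
      f"sd {speed_z.std():.3f}  (zero/one by construction on this pool)")
fast = z[speed_z > 2].index.get_level_values("animal_id").nunique()
print(f"animals with >2 sd speed excursions: {fast} "
      "(undisturbed herds occasionally sprint; context separates these "
      "from sustained flights)")
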