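"""Generate a synthetic canola plant and count its siliques.

The counting pipeline takes silique-class points, removes sparse noise
with statistical outlier removal (SOR), and clusters with DBSCAN at
eps=0.10, min_samples=5. Without SOR, mislabeled noise clumps appear as
spurious clusters and inflate the count.
"""
from kanglnet import PlantSpec, count_instances, generate_plant

plant = generate_plant(PlantSpec(n_siliques=150, seed=3))
print(f"plant: {len(plant.labeled)} points, true count {plant.true_count}")
with_sor = count_instances(plant.labeled)
without = count_instances(plant.labeled, use_sor=False)
print(f"count with SOR   : {with_sor.count} "
      f"({len(with_sor.sor_removed)} points filtered)")
print(f"count without SOR: {without.count} (noise counted as clusters)")
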