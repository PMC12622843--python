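"""Search DBSCAN parameters against plants with known silique counts.

The grid spans eps in [0.05, 0.20] and min_samples in [1, 15]; the score
is the mean absolute count error. Too small an eps fragments sparse
capsules, too large merges neighbors; the optimum sits near (0.10, 5).
"""
import numpy as np
from kanglnet import PlantSpec, generate_plant, parameter_grid_search

rng = np.random.default_rng(7)
plants = []
for _ in range(3):
    plant = generate_plant(PlantSpec(n_siliques=int(rng.integers(60, 260)),
                                     seed=int(rng.integers(0, 2**31 - 1))))
    plants.append((plant.labeled, plant.true_count))
best, grid = parameter_grid_search(plants)
print(f"best parameters: eps={best.eps:.2f}, min_samples={best.min_samples}")
print(f"mean |count error| at optimum: {grid.min():.2f}")
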