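"""Assemble the environment x covariate matrix and the enviromic
relationship matrix (ERM).

Each trial environment gets 7 monthly weather variables over Oct-Aug plus
7 soil properties (84 covariates); the ERM is a Gaussian kernel on the
scaled EC rows with bandwidth 1 and the mean squared distance as scale.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, STUDY  # noqa: E402

from gxepred import (gaussian_kernel, simulate_dataset,  # noqa: E402
                     standardize_ecs)


def main() -> None:
    ds = simulate_dataset(STUDY)
    scaled = standardize_ecs(ds.environments)
    kernel = gaussian_kernel(scaled)
    kernel.matrix.to_csv(RESULTS / "omega_matrix.csv",
                         float_format="%.6g")

    O = kernel.matrix.to_numpy()
    iu = np.triu_indices(len(O), k=1)
    off = O[iu]
    env_loc = ds.env_table.set_index("environment")["location"]
    envs = kernel.environments
    same_loc = np.array([env_loc[envs[i]] == env_loc[envs[j]]
                         for i, j in zip(*iu)])
    print(f"EC matrix: {ds.environments.shape[0]} environments x "
          f"{ds.environments.shape[1]} covariates "
          f"({scaled.shape[1]} after dropping constant columns)")
    print(f"ERM scale theta = {kernel.theta:.2f} (bandwidth h = "
          f"{kernel.h})")
    print(f"similarity quartiles: "
          f"{np.round(np.quantile(off, [0.25, 0.5, 0.75]), 3)}")
    print(f"mean similarity same-location pairs {off[same_loc].mean():.3f}"
          f" vs different-location pairs {off[~same_loc].mean():.3f}")


if __name__ == "__main__":
    main()
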