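"""Track fibre-point displacements between two load steps with DVC.

Every point of the fibre point cloud is the centre of a 30-voxel spherical
sub-volume whose translation between the reference and deformed volumes is
found by minimising the zero-normalised SSD of 10,000 interior intensity
samples, interpolated tricubically for sub-voxel precision.  Here the
"load step" is a known rigid sub-voxel shift, so the recovered
displacements can be compared with the truth exactly.
"""

import numpy as np

from fibredvc import DvcParams, PhantomConfig, RigidTranslation, correlate_points, deform_volume, generate_volume
from fibredvc.studies import interior_fibre_cloud

config = PhantomConfig(grid_shape=(96, 96, 96), n_lamellae=3, noise_sd=1500.0, depth_margin=10, rng_seed=5)
volume, truth = generate_volume(config)

true_shift = np.array([0.40, 0.30, -0.60])  # voxels
deformed = deform_volume(volume, RigidTranslation(true_shift, volume.shape))

cloud = interior_fibre_cloud(config, truth, volume.shape, max_fibres=10)
records = correlate_points(volume, deformed, cloud, DvcParams(rng_seed=1))

converged = records[records.converged]
recovered = converged[["u", "v", "w"]].mean().to_numpy()
err = np.linalg.norm(converged[["u", "v", "w"]].to_numpy() - true_shift, axis=1)
print(f"tracked {len(records)} points, {records.converged.mean():.0%} converged")
print(f"true shift      : {true_shift}")
print(f"mean recovered  : {np.round(recovered, 4)}")
print(f"mean 3D error   : {err.mean():.4f} voxels ({err.mean() * config.voxel_size * 1000:.0f} nm)")
print(f"median residual : {converged.residual.median():.2e}  (ZNSSD, 0 = perfect match)")
# Interpretation: sub-voxel accuracy of a few hundredths of a voxel means
# displacements of tens of nanometres are resolvable at this voxel size.
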