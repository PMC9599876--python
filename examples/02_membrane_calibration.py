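"""Permeability-to-diffusion calibration of membrane voxels.

A membrane is one voxel thick, so a species' membrane permeability P_m maps
to the voxel diffusion coefficient D_m = P_m * L with L = 1/res_xy.  Myelin
stacks ~10 membrane folds (0.2 µm of myelin at 10 nm per membrane), i.e. 20
membranes in series, cutting permeability 20-fold.
"""

from rosnerve.solver import membrane_diffusion, myelin_folds, myelin_permeability

p_superoxide = 2.1e-2   # µm/s — superoxide barely crosses membranes
p_h2o2 = 20.0           # µm/s — hydrogen peroxide crosses readily

print(f"superoxide D_m at 10 px/µm: {membrane_diffusion(p_superoxide, 10.0):.2e} µm²/s")
print(f"H2O2       D_m at 10 px/µm: {membrane_diffusion(p_h2o2, 10.0):.2e} µm²/s")
print(f"myelin folds (0.2 µm / 10 nm): {myelin_folds(0.2, 0.01):.0f}")
print(f"H2O2 permeability through myelin: {myelin_permeability(p_h2o2):.1f} µm/s "
      f"({p_h2o2 / myelin_permeability(p_h2o2):.0f}x reduction)")
# The superoxide value (2.1e-3 µm²/s) is so small that membranes are
# effectively blocking for it, which is why superoxide runs use D_m = 0.
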