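import numpy as np
import pytest

from rosnerve import geometry as geo


@pytest.fixture(scope="session")
def small_axons():
    """~200 axons in a 10 µm disc with the default diameter laws."""
    return geo.place_axons(10.0, geo.DiameterDistribution.default(), 1)


@pytest.fixture(scope="session")
def small_model(small_axons):
    """Rasterized single-slice model with 4 % axonal mitochondria."""
    model = geo.rasterize_model(small_axons, res_xy=7.0, res_z=1.0, nz=1,
                                nerve_radius_um=10.0)
    return geo.place_mitochondria(model, 4.0, 0.0, 2)


@pytest.fixture()
def uniform_coeffs():
    """Factory for homogeneous coefficient maps on small grids."""
    from rosnerve import solver as sv

    def make(shape, d=2000.0, dz=None, rp=0.0, rs=0.0, res_xy=5.0, res_z=1.0):
        dz = d if dz is None else dz
        return sv.CoefficientMaps(
            dxx=np.full(shape, float(d)), dzz=np.full(shape, float(dz)),
            rp=np.full(shape, float(rp)), rs=np.full(shape, float(rs)),
            res_xy=res_xy, res_z=res_z)

    return make
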