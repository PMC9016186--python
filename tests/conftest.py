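from __future__ import annotations

import numpy as np
import pytest

from rangewedge.grids_io import ImageGrid, StructureMask
from rangewedge.hu_density import default_ct_table, default_rsp_table, rsp_from_density
from rangewedge.proton_sim import (
    PhantomSpec,
    build_wedge_beam,
    compute_beam_dose,
    make_phantom,
    simulate_measurement,
)
from rangewedge.range_eval import central_axis_wepl


def water_grid(shape=(40, 120, 40), spacing=(1.0, 1.0, 1.0), rsp=1.0) -> ImageGrid:
    """Uniform-RSP block, origin at zero."""
    return ImageGrid(origin=(0, 0, 0), spacing=spacing,
                     values=np.full(shape, rsp), quantity="RSP")


def box_mask(grid: ImageGrid, lo, hi, name="target") -> StructureMask:
    i, j, k = np.meshgrid(*(grid.axis_coords(a) for a in range(3)), indexing="ij")
    m = ((i >= lo[0]) & (i <= hi[0]) & (j >= lo[1]) & (j <= hi[1])
         & (k >= lo[2]) & (k <= hi[2]))
    return StructureMask(name, grid, m)


def mini_head_spec(noise_hu: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Scaled-down head phantom for fast tests (same structure as the default;
    central-axis WEPL to the detector ~100 mm)."""
    return PhantomSpec(
        site="head",
        shape=(100, 132, 90),
        body_center=(50.0, 50.0, 45.0),
        body_semiaxes=(44.0, 44.0, 40.0),
        shell_thickness_mm=4.0,
        base_y_range=(94.0, 130.0),
        wedge_u_range=(25.0, 75.0),
        wedge_v_range=(25.0, 65.0),
        wedge_proximal_y=97.0,
        wedge_distal_y_range=(103.0, 118.0),
        wedge_v_slope=0.08,
        detector_depth_mm=114.0,
        noise_hu=noise_hu,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_study():
    """One planned mini head phantom shared across the test session."""
    spec = mini_head_spec()
    ct_table = default_ct_table()
    rsp_table = default_rsp_table()
    ct, rho, wedge, base = make_phantom(spec, ct_table)
    rsp = rsp_from_density(rho, rsp_table)
    beam = build_wedge_beam(wedge, rsp, lateral_pitch_mm=6.0, sigma_lat_mm=5.0,
                            max_opt_samples=2500, seed=11)
    dose = compute_beam_dose(beam, rsp)
    meas = simulate_measurement(dose, spec.detector_depth_mm)
    wepl = central_axis_wepl(rsp, 1, "+", spec.detector_depth_mm,
                             (spec.body_center[0], spec.body_center[2]))
    return {
        "spec": spec, "ct": ct, "rho": rho, "wedge": wedge, "base": base,
        "ct_table": ct_table, "rsp_table": rsp_table, "rsp": rsp,
        "beam": beam, "dose": dose, "meas": meas, "wepl": wepl,
    }
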