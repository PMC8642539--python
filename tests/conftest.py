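"""Shared fixtures: rendered reference spheres and synthetic cohorts.

Session-scoped because rendering + surfacing a full stack takes tens of
seconds; all geometry tests and the acceptance checks reuse the same
reconstruction.
"""

import warnings

import numpy as np
import pytest

from glioquant import geometry as geo
from glioquant.synth3d import DepthLaw, ImagingParams, generate_scene, \
    render_stack
from glioquant.synth_sc import ScDesign, generate_barnyard, \
    generate_cycle_cohort


@pytest.fixture(scope="session")
def sphere_case():
    """R = 100 µm sphere rendered with the default acquisition geometry
    (85 sections, 3 µm z-step), padded, surfaced (both passes), with spots
    detected — the main end-to-end geometry fixture."""
    scene = generate_scene(100.0, None, 60, DepthLaw.exponential(15.0),
                           seed=42)
    stack = render_stack(scene, ImagingParams())
    stack = geo.pad_stack(stack, n_blank=50)
    mesh1 = geo.reconstruct_surface(stack)
    mesh2 = geo.outside_mask_resurface(stack, mesh1)
    spots = geo.detect_spots(stack)
    return {"scene": scene, "stack": stack, "mesh1": mesh1, "mesh2": mesh2,
            "spots": spots}


@pytest.fixture(scope="session")
def large_sphere_case():
    """R = 150 µm sphere: needs a taller stack (110 sections) and a wider
    field of view to be fully imaged."""
    scene = generate_scene(150.0, None, 60, DepthLaw.exponential(15.0),
                           seed=42)
    params = ImagingParams(n_slices=110, n_xy=320)
    stack = geo.pad_stack(render_stack(scene, params), n_blank=50)
    mesh1 = geo.reconstruct_surface(stack)
    mesh2 = geo.outside_mask_resurface(stack, mesh1)
    spots = geo.detect_spots(stack)
    return {"scene": scene, "stack": stack, "mesh1": mesh1, "mesh2": mesh2,
            "spots": spots}


@pytest.fixture(scope="session")
def truncated_case():
    """R = 140 µm organoid imaged with the default 85 sections: the top of
    the organoid lies beyond the acquired volume, as in real stacks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scene = generate_scene(140.0, None, 50, DepthLaw.exponential(15.0),
                               seed=3)
        stack = geo.pad_stack(
            render_stack(scene, ImagingParams(n_xy=300)), n_blank=50)
    mesh1 = geo.reconstruct_surface(stack)
    mesh2 = geo.outside_mask_resurface(stack, mesh1)
    return {"scene": scene, "stack": stack, "mesh1": mesh1, "mesh2": mesh2}


@pytest.fixture(scope="session")
def barnyard_2000():
    """Barnyard capture, n=2000 barcodes, 5% ambient contamination."""
    design = ScDesign(n_cells=2000, ambient_rate=0.05, seed=7)
    return generate_barnyard(design)


@pytest.fixture(scope="session")
def cohort_3000():
    """Two-arm cycle cohort, 1500 cells per arm, fold-effect 4."""
    design = ScDesign(n_cells=1500, fold_effect=4.0, seed=11)
    return generate_cycle_cohort(design)


@pytest.fixture(scope="session")
def icosphere_100():
    import trimesh
    return trimesh.creation.icosphere(subdivisions=3, radius=100.0)


def match_spots_to_truth(spots, scene, max_dist=6.0):
    """Nearest-neighbour matching of detected spots to planted tumor cells."""
    from scipy.spatial import cKDTree

    dist, idx = cKDTree(scene.tumor_positions).query(spots.positions)
    return dist <= max_dist, idx
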