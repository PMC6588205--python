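import numpy as np
import pytest

import tumorflow as tf


@pytest.fixture
def single_vessel():
    """One 10 um x 100 um segment between two boundary nodes."""
    return tf.make_fixture(
        tf.SyntheticNetworkSpec(
            kind="single_vessel", mean_diameter_um=10.0, mean_branch_length_um=100.0
        )
    )


@pytest.fixture
def y_junction():
    return tf.make_fixture(
        tf.SyntheticNetworkSpec(
            kind="y_junction", mean_diameter_um=10.0, mean_branch_length_um=100.0
        )
    )


@pytest.fixture
def lattice():
    """3x3x3 node lattice, 100 um spacing, 10 um diameters."""
    return tf.make_fixture(tf.SyntheticNetworkSpec(kind="lattice3d", lattice_k=3))


@pytest.fixture
def lattice5():
    return tf.make_fixture(tf.SyntheticNetworkSpec(kind="lattice3d", lattice_k=5))


@pytest.fixture(scope="session")
def tumour_net():
    """Small seeded tumour-like network used across modules."""
    spec = tf.SyntheticNetworkSpec(
        seed=7, extent_um=(800.0, 800.0, 800.0), vascular_density_pct=1.5
    )
    net = tf.make_fixture(spec)
    net, report = tf.validate_and_clean(net)
    assert report.empty
    return net


@pytest.fixture(scope="session")
def tumour_hull(tumour_net):
    return tf.compute_hull(tumour_net.coords, subdivision=1)


@pytest.fixture(scope="session")
def tumour_flow(tumour_net, tumour_hull):
    """Estimated flow on the tumour fixture under a seeded boundary draw."""
    policy = tf.BoundaryPolicy(seed=11)
    assignment = tf.assign_boundary_conditions(tumour_net, tumour_hull, policy)
    haemo = tf.HaemodynamicParameters()
    cond = tf.assemble_conductance(tumour_net, haemo)
    flow = tf.estimate_flow(
        tumour_net, cond, assignment.pressure_bcs, haemo, assignment.flux_bcs
    )
    return assignment, cond, flow


@pytest.fixture
def table_params():
    """Baseline interstitial transport parameters."""
    return tf.InterstitialParameters()


def make_sources(positions, r0=10.0, length=50.0, pb=25.0, params=None):
    """Hand-built source set for kernel-level tests."""
    params = params or tf.InterstitialParameters()
    positions = np.atleast_2d(np.asarray(positions, float))
    n = len(positions)
    return tf.SourceSet(
        positions_um=positions,
        r0_um=np.full(n, r0),
        rv_um=np.full(n, r0),
        length_um=np.full(n, length),
        pb_mmHg=np.full(n, pb),
        segment_index=np.zeros(n, dtype=np.int64),
        kappa=np.full(n, params.kappa),
        L_p=np.full(n, params.L_p),
        sigma=np.full(n, params.sigma),
        spacing_um=length,
    )
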