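"""Shared fixtures: the default synthetic cochlea, its 25-fiber set, and the
four fitted electrode arrays (session-scoped; the fits are deterministic)."""

import numpy as np
import pytest

from cochsim import build_geometry, fit_centerline, place_anfs, place_contacts


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def fibers(geometry):
    return place_anfs(geometry)


@pytest.fixture(scope="session")
def fiber_angles(fibers):
    return [f.alpha_deg for f in fibers]


@pytest.fixture(scope="session")
def centerlines(geometry, fibers):
    return {
        f"{style}{scala}": fit_centerline(geometry, fibers, scala, style)
        for scala in ("ST", "SV")
        for style in ("lw", "pm")
    }


@pytest.fixture(scope="session")
def arrays(centerlines, fiber_angles):
    return {
        tag: place_contacts(cl, fiber_angles)
        for tag, cl in centerlines.items()
    }


@pytest.fixture(scope="session")
def uniform_map():
    """Small all-perilymph conductivity map for field-solver oracles."""
    from cochsim.geometry import ConductivityMap, LABEL_INDEX

    n, sp = 41, 100.0
    labels = np.full((n, n, n), LABEL_INDEX["ST"], dtype=np.uint8)
    return ConductivityMap(spacing=sp, origin=np.array([-(n // 2) * sp] * 3),
                           labels=labels)
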