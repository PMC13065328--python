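"""Shared synthetic subjects for the test suite.

All heavyweight fixtures are session-scoped and deterministic.  The mesh
object is shared so that the per-hemisphere geodesic graphs are built once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from phasefield import cortical_geometry as geo
from phasefield import preprocessing as prep
from phasefield import spectral_phase as spp
from phasefield import synthetic as syn
from phasefield.decomposition import PhaseSVD, complex_svd


@dataclass
class Subject:
    """A synthetic implant with geometry and (optionally) phase data."""

    mesh: geo.CorticalMesh
    contacts: pd.DataFrame
    gray_contacts: pd.DataFrame
    recording: prep.RawRecording
    sidecar: dict
    points: geo.SurfacePoints
    distances: np.ndarray
    triangles: geo.TriangleSet
    phase: spp.PhaseMatrix


@pytest.fixture(scope="session")
def mesh():
    return syn.make_spheroid_mesh(radius=0.07, distortion=0.05, subdivisions=4, seed=11)


def _build_subject(mesh, contacts, components, noise_sd, duration, rec_seed, tf=8.0):
    gray_contacts = contacts[contacts["label"] == "gray"].reset_index(drop=True)
    rec, sidecar = syn.make_wave_recording(
        mesh, contacts, components=components, noise_sd=noise_sd,
        fs=500.0, duration=duration, seed=rec_seed,
    )
    gray_sig = prep.white_matter_reference(rec)
    pts = geo.project_to_surface(
        gray_contacts[["x", "y", "z"]].to_numpy(),
        gray_contacts["hemisphere"].to_numpy(),
        mesh,
    )
    D = geo.geodesic_distances(mesh, pts)
    tset = geo.bin_triangles(geo.enumerate_triangles(D, pts.hemisphere))
    phase = spp.morlet_phase(gray_sig, rec.fs, tf)
    return Subject(
        mesh=mesh,
        contacts=contacts,
        gray_contacts=gray_contacts,
        recording=rec,
        sidecar=sidecar,
        points=pts,
        distances=D,
        triangles=tset,
        phase=phase,
    )


@pytest.fixture(scope="session")
def wave9_subject(mesh):
    """~70 gray contacts, one planted traveling wave at 9 cycles/m, 8 Hz."""
    contacts = syn.make_depth_electrodes(
        mesh, n_electrodes=12, contacts_per_electrode=12, seed=3
    )
    comp = [{"tf": 8.0, "sf": 9.0, "direction": "anterior-posterior", "amplitude": 1.0}]
    return _build_subject(mesh, contacts, comp, noise_sd=0.3, duration=3.0, rec_seed=7)


@pytest.fixture(scope="session")
def noise_subject(mesh):
    """Wide-coverage implant recording pure noise (surrogate-injection host)."""
    contacts = syn.make_depth_electrodes(
        mesh, n_electrodes=16, contacts_per_electrode=12, seed=3,
        cluster_fraction=0.5, cluster_cap=0.9,
    )
    return _build_subject(mesh, contacts, [], noise_sd=1.0, duration=3.0, rec_seed=13)


#: SF window over which the multi-scale cascade below is resolvable by the
#: dense-cluster implant (components at 4-11 cycles/m).
CASCADE_RANGE = (3.0, 12.5)


def cascade_components(n_comp: int = 8, alpha: float = 1.5):
    """A 1/xi**alpha mixture of traveling waves, decorrelated in TF."""
    rng = np.random.default_rng(0)
    xis = np.geomspace(4.0, 11.0, n_comp)
    tfs = np.linspace(5.0, 12.0, n_comp)
    rng.shuffle(tfs)
    dirs = ["anterior-posterior", "left-right", "inferior-superior"]
    return [
        {
            "tf": float(tf),
            "sf": float(xi),
            "direction": dirs[i % 3],
            "amplitude": float(xi**-alpha),
            "phase0": float(rng.uniform(0, 2 * np.pi)),
        }
        for i, (xi, tf) in enumerate(zip(xis, tfs))
    ]


@pytest.fixture(scope="session")
def cascade_subject(mesh):
    """Dense-cluster implant carrying the 1/xi**1.5 multi-scale wave field."""
    contacts = syn.make_depth_electrodes(
        mesh, n_electrodes=22, contacts_per_electrode=12, seed=3,
        cluster_fraction=0.75, cluster_cap=0.5,
    )
    return _build_subject(
        mesh, contacts, cascade_components(), noise_sd=0.005, duration=12.0, rec_seed=21
    )


@pytest.fixture(scope="session")
def cascade_svd(cascade_subject) -> PhaseSVD:
    return complex_svd(cascade_subject.phase, rank=8)
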