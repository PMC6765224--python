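import numpy as np
import pytest

from nacscan.synthetic import (
    PlantSchedule,
    decoy_spec,
    default_site,
    generate,
    w1_spec,
    w2_spec,
)


@pytest.fixture
def site():
    return default_site()


@pytest.fixture
def mixed_schedule():
    """Ten frames mixing exact W1/W2 plants, decoys and empty frames."""
    frames = [
        [w1_spec("A"), w2_spec("B", activator_distance=3.0)],
        [w1_spec("A")],
        [decoy_spec("D", "angle")],
        [],
        [w1_spec("A"), w2_spec("B")],
        [decoy_spec("E", "orientation"), decoy_spec("F", "distance")],
        [w1_spec("G", distance=3.2, angle_deg=105.5)],
        [w1_spec("A"), w2_spec("C", distance=3.1)],
        [],
        [w1_spec("A"), w2_spec("B")],
    ]
    return PlantSchedule(n_frames=10, frames=frames, jitter_sigma=0.0, seed=11)


@pytest.fixture
def mixed_trajectory(mixed_schedule):
    return generate(mixed_schedule)


def rigid_transform(rng):
    """A random rotation matrix (QR-based) and translation vector."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    return q, t


def apply_rigid(traj, q, t):
    """Apply one global rotation+translation to every atom of every frame."""
    from nacscan.trajectory import AtomRecord, Frame, Trajectory

    frames = []
    for fr in traj.frames:
        atoms = [
            AtomRecord(
                atom_serial=a.atom_serial,
                atom_name=a.atom_name,
                residue_name=a.residue_name,
                residue_seq=a.residue_seq,
                chain_id=a.chain_id,
                element=a.element,
                position=q @ a.position + t,
            )
            for a in fr.atoms
        ]
        frames.append(Frame(index=fr.index, atoms=atoms, box=fr.box))
    return Trajectory(frames=frames, source=traj.source)
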