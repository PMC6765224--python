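"""Synthetic trajectories with planted near-attack geometries and ground truth.

The generator builds explicit-hydrogen test trajectories around a fixed
carbonyl fragment (C at the origin, carbonyl O at 1.23 Å along +x) with a
small protein shell far from the site.  Waters are constructed by inverse
geometry to hit requested distance / Bürgi–Dunitz angle / orientation values
exactly (before optional jitter), so every planted molecule carries an exact
ground-truth label:

* ``w1`` — an attacking water satisfying all three W1 criteria;
* ``w2`` — an assisting water attached to a W1, donor-oriented by default,
  optionally with a planted protein activator atom at a set distance;
* ``decoy`` — a W1-like water violating exactly one criterion (distance,
  angle, or orientation), for per-criterion specificity tests.

Waters use a rigid 3-site geometry (O–H 0.96 Å, H–O–H 104.5°).  All
scheduled molecules exist in every frame (rigid topology); molecules not
planted in a given frame are parked far outside every cutoff.  Jitter is a
per-frame rigid translation of each water drawn from an isotropic Gaussian;
with the default planted geometries the margin to every criterion boundary
is ~0.5 Å / 1°, so small jitter leaves the labels valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .detector import SiteDefinition, WaterId
from .trajectory import AtomRecord, Frame, Trajectory

__all__ = [
    "PlantSpec",
    "PlantSchedule",
    "FrameLabels",
    "GroundTruth",
    "ScheduleError",
    "generate",
    "default_site",
    "w1_spec",
    "w2_spec",
    "decoy_spec",
]

_O_H = 0.96  # O–H bond length, Å
_HOH_DEG = 104.5  # H–O–H angle, degrees
_CO_BOND = 1.23  # carbonyl C=O, Å
_GOLDEN_DEG = 137.5  # azimuth increment between molecules planted in one frame


class ScheduleError(ValueError):
    """A plant schedule is inconsistent or physically unrealizable."""


@dataclass(frozen=True)
class PlantSpec:
    """One planted molecule in one frame.

    ``distance`` is O(water)–C for W1-like roles and O(W2)–O(W1) for ``w2``.
    ``angle_deg`` is the Bürgi–Dunitz angle (W1-like roles only).
    ``orientation`` is ``oxygen-first``/``hydrogen-first`` for W1-like roles
    and ``donor``/``non-donor`` for ``w2``.  ``violated`` names the single
    criterion a decoy breaks; it is ``none`` for true plants.
    ``water_tag`` names the molecule: specs sharing a tag across frames are
    the same water.  ``partner_tag`` attaches a ``w2`` to a specific W1 in
    the same frame (default: the preceding ``w1`` spec).
    """

    role: Literal["w1", "w2", "decoy"]
    water_tag: str
    distance: float = 3.0
    angle_deg: float = 106.0
    orientation: str = "oxygen-first"
    violated: Literal["none", "distance", "angle", "orientation"] = "none"
    partner_tag: str | None = None
    activator_distance: float | None = None


def w1_spec(tag: str, distance: float = 3.0, angle_deg: float = 106.0) -> PlantSpec:
    return PlantSpec(role="w1", water_tag=tag, distance=distance, angle_deg=angle_deg)


def w2_spec(
    tag: str,
    distance: float = 2.8,
    orientation: str = "donor",
    partner_tag: str | None = None,
    activator_distance: float | None = None,
) -> PlantSpec:
    return PlantSpec(
        role="w2",
        water_tag=tag,
        distance=distance,
        orientation=orientation,
        partner_tag=partner_tag,
        activator_distance=activator_distance,
    )


def decoy_spec(tag: str, violated: str) -> PlantSpec:
    """A W1-like decoy violating exactly the named criterion."""
    if violated == "distance":
        return PlantSpec(role="decoy", water_tag=tag, distance=4.2, violated="distance")
    if violated == "angle":
        return PlantSpec(role="decoy", water_tag=tag, angle_deg=95.0, violated="angle")
    if violated == "orientation":
        return PlantSpec(
            role="decoy", water_tag=tag, orientation="hydrogen-first", violated="orientation"
        )
    raise ScheduleError(f"unknown decoy criterion {violated!r}")


@dataclass
class PlantSchedule:
    """Per-frame plant lists plus jitter and seed.

    ``frames[i]`` lists the molecules planted in frame ``i``; every tag seen
    anywhere in the schedule becomes a water of the shared topology.
    """

    n_frames: int
    frames: list[list[PlantSpec]]
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ScheduleError("schedule needs at least one frame")
        if len(self.frames) != self.n_frames:
            raise ScheduleError(
                f"frames list has {len(self.frames)} entries for n_frames={self.n_frames}"
            )
        if self.jitter_sigma < 0:
            raise ScheduleError("jitter sigma must be non-negative")
        for i, specs in enumerate(self.frames):
            tags = [s.water_tag for s in specs]
            if len(set(tags)) != len(tags):
                raise ScheduleError(f"frame {i}: duplicate water tag")
            for s in specs:
                if s.distance <= 0 or not (0.0 <= s.angle_deg <= 180.0):
                    raise ScheduleError(
                        f"frame {i}: unrealizable geometry for {s.water_tag!r}"
                    )
                if s.role == "w2":
                    partner = s.partner_tag
                    w1_tags = [x.water_tag for x in specs if x.role == "w1"]
                    if partner is None:
                        before = [
                            x.water_tag
                            for x in specs[: specs.index(s)]
                            if x.role == "w1"
                        ]
                        if not before:
                            raise ScheduleError(
                                f"frame {i}: w2 {s.water_tag!r} has no preceding w1"
                            )
                    elif partner not in w1_tags:
                        raise ScheduleError(
                            f"frame {i}: w2 {s.water_tag!r} names absent partner {partner!r}"
                        )
                if s.role == "decoy" and s.violated == "none":
                    raise ScheduleError(f"frame {i}: decoy {s.water_tag!r} violates nothing")
                if s.role != "decoy" and s.violated != "none":
                    raise ScheduleError(f"frame {i}: non-decoy {s.water_tag!r} sets violated")


@dataclass(frozen=True)
class FrameLabels:
    """What the detector must report for one frame under the default site."""

    w1: frozenset[WaterId]
    pairs: frozenset[tuple[WaterId, WaterId]]


@dataclass(frozen=True)
class GroundTruth:
    water_ids: dict[str, WaterId]
    frames: tuple[FrameLabels, ...]

    @property
    def site_waters(self) -> frozenset[WaterId]:
        """Waters expected to pass the at-least-once pre-filter (ever < 3.5 Å of C)."""
        out = set()
        for fl in self.frames:
            out |= fl.w1
        return frozenset(out) | self._near_decoys

    # populated by generate(); decoys that are near C but fail another criterion
    _near_decoys: frozenset[WaterId] = frozenset()


def default_site(**overrides) -> SiteDefinition:
    """The SiteDefinition matching generated trajectories."""
    return SiteDefinition(ligand_resname="LIG", water_resname="SOL", **overrides)


# ---------------------------------------------------------------------------
# geometry construction


def _perp(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _water_atoms(o_pos: np.ndarray, bisector: np.ndarray, side: np.ndarray) -> list[np.ndarray]:
    """Rigid 3-site water: O plus two H at ±(H–O–H)/2 around the bisector."""
    half = np.radians(_HOH_DEG / 2.0)
    b = bisector / np.linalg.norm(bisector)
    t = side / np.linalg.norm(side)
    h1 = o_pos + _O_H * (np.cos(half) * b + np.sin(half) * t)
    h2 = o_pos + _O_H * (np.cos(half) * b - np.sin(half) * t)
    return [o_pos, h1, h2]


def _plant_positions(
    spec: PlantSpec,
    azimuth_deg: float,
    w1_o_positions: dict[str, np.ndarray],
) -> tuple[list[np.ndarray], np.ndarray | None]:
    """Water atom positions (O, H1, H2) and optional activator position."""
    phi = np.radians(azimuth_deg)
    if spec.role in ("w1", "decoy"):
        theta = np.radians(spec.angle_deg)
        # unit approach direction making the requested angle with C->O(=x axis)
        u = np.array(
            [np.cos(theta), np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)]
        )
        o_pos = spec.distance * u
        side = _perp(u)
        if spec.orientation == "oxygen-first":
            atoms = _water_atoms(o_pos, bisector=u, side=side)
        elif spec.orientation == "hydrogen-first":
            atoms = _water_atoms(o_pos, bisector=-u, side=side)
        else:
            raise ScheduleError(f"unknown W1 orientation {spec.orientation!r}")
        return atoms, None

    # w2: built radially outward from its partner W1 oxygen
    partner_o = w1_o_positions[spec.partner_tag]  # type: ignore[index]
    v = partner_o / np.linalg.norm(partner_o)  # outward C->W1 direction
    o_pos = partner_o + spec.distance * v
    side = _perp(v)
    if spec.orientation == "donor":
        atoms = _water_atoms(o_pos, bisector=-v, side=side)  # H toward W1
    elif spec.orientation == "non-donor":
        atoms = _water_atoms(o_pos, bisector=v, side=side)  # H away from W1
    else:
        raise ScheduleError(f"unknown W2 orientation {spec.orientation!r}")
    activator = None
    if spec.activator_distance is not None:
        w = np.cross(v, side)
        w /= np.linalg.norm(w)
        activator = o_pos + spec.activator_distance * w
    return atoms, activator


# ---------------------------------------------------------------------------
# topology layout


def _ligand_atoms() -> list[tuple[str, str, int, str, np.ndarray]]:
    # (atom_name, resname, resseq, element, position)
    return [
        ("C", "LIG", 1, "C", np.zeros(3)),
        ("O", "LIG", 1, "O", np.array([_CO_BOND, 0.0, 0.0])),
        ("CA", "LIG", 1, "C", np.array([-0.76, -1.31, 0.0])),
        ("OS", "LIG", 1, "O", np.array([-0.65, 1.15, 0.0])),
    ]


def _shell_atoms() -> list[tuple[str, str, int, str, np.ndarray]]:
    # inert protein decoy shell, ~14 Å from the site
    base = np.array([8.0, 8.0, 8.0])
    return [
        ("N", "GLY", 90, "N", base + np.array([0.0, 0.0, 0.0])),
        ("CA", "GLY", 90, "C", base + np.array([1.45, 0.0, 0.0])),
        ("C", "GLY", 90, "C", base + np.array([2.2, 1.3, 0.0])),
        ("O", "GLY", 90, "O", base + np.array([3.4, 1.3, 0.2])),
        ("OG", "SER", 91, "O", base + np.array([0.0, 3.0, 1.0])),
    ]


def generate(schedule: PlantSchedule) -> tuple[Trajectory, GroundTruth]:
    """Build the trajectory and its exact labels.

    Deterministic for a fixed schedule (the seed drives all jitter); with
    ``jitter_sigma = 0`` the planted geometries are exact and the labels are
    what any correct detector must return under :func:`default_site`.
    """
    rng = np.random.default_rng(schedule.seed)

    all_tags = sorted({s.water_tag for specs in schedule.frames for s in specs})
    water_ids: dict[str, WaterId] = {
        tag: ("SOL", 101 + k, "") for k, tag in enumerate(all_tags)
    }
    # activator slots: one planted protein oxygen per tag that ever requests one
    activator_tags = sorted(
        {
            s.water_tag
            for specs in schedule.frames
            for s in specs
            if s.activator_distance is not None
        }
    )
    activator_resseq = {tag: 500 + k for k, tag in enumerate(activator_tags)}

    def park_water(k: int) -> np.ndarray:
        return np.array([30.0 + 4.0 * k, 30.0, 30.0])

    def park_activator(k: int) -> np.ndarray:
        return np.array([30.0, 30.0 + 4.0 * k, 50.0])

    frames: list[Frame] = []
    labels: list[FrameLabels] = []
    near_decoys: set[WaterId] = set()

    for fi in range(schedule.n_frames):
        specs = schedule.frames[fi]
        # resolve implicit w2 partners to the preceding w1 in list order
        resolved_specs: list[PlantSpec] = []
        last_w1: str | None = None
        for s in specs:
            if s.role == "w1":
                last_w1 = s.water_tag
                resolved_specs.append(s)
            elif s.role == "w2" and s.partner_tag is None:
                resolved_specs.append(
                    PlantSpec(
                        role="w2",
                        water_tag=s.water_tag,
                        distance=s.distance,
                        orientation=s.orientation,
                        partner_tag=last_w1,
                        activator_distance=s.activator_distance,
                    )
                )
            else:
                resolved_specs.append(s)

        water_pos: dict[str, list[np.ndarray]] = {}
        activator_pos: dict[str, np.ndarray] = {}
        w1_o_positions: dict[str, np.ndarray] = {}
        frame_w1: set[WaterId] = set()
        frame_pairs: set[tuple[WaterId, WaterId]] = set()

        # Labels are evaluated against the default site criteria from the
        # exact planted geometry (pre-jitter), not from role intent: a 'w1'
        # spec placed outside the angle window is simply not labeled.
        crit = default_site()

        def _w1_qualifies(s: PlantSpec) -> bool:
            return (
                s.distance < crit.w1_dist_cutoff
                and crit.bd_window.contains(s.angle_deg)
                and s.orientation == "oxygen-first"
            )

        # plant W1s and decoys first (W2 geometry needs its partner's oxygen)
        slot = 0
        labeled_w1_tags: set[str] = set()
        for s in resolved_specs:
            if s.role == "w2":
                continue
            atoms, _ = _plant_positions(s, azimuth_deg=_GOLDEN_DEG * slot, w1_o_positions={})
            slot += 1
            water_pos[s.water_tag] = atoms
            if s.role == "w1":
                w1_o_positions[s.water_tag] = atoms[0]
            if _w1_qualifies(s):
                labeled_w1_tags.add(s.water_tag)
                frame_w1.add(water_ids[s.water_tag])
            elif s.distance < crit.w1_dist_cutoff:
                near_decoys.add(water_ids[s.water_tag])
        for s in resolved_specs:
            if s.role != "w2":
                continue
            atoms, act = _plant_positions(s, azimuth_deg=0.0, w1_o_positions=w1_o_positions)
            water_pos[s.water_tag] = atoms
            if (
                s.orientation == "donor"
                and s.distance <= crit.w2_dist_cutoff
                and s.partner_tag in labeled_w1_tags
            ):
                frame_pairs.add((water_ids[s.partner_tag], water_ids[s.water_tag]))
            if act is not None:
                activator_pos[s.water_tag] = act

        if schedule.jitter_sigma > 0:
            for tag in water_pos:
                shift = rng.normal(0.0, schedule.jitter_sigma, size=3)
                water_pos[tag] = [p + shift for p in water_pos[tag]]

        records: list[AtomRecord] = []
        serial = 1

        def add(name: str, resname: str, resseq: int, element: str, pos: np.ndarray):
            nonlocal serial
            records.append(
                AtomRecord(
                    atom_serial=serial,
                    atom_name=name,
                    residue_name=resname,
                    residue_seq=resseq,
                    chain_id="",
                    element=element,
                    position=pos,
                )
            )
            serial += 1

        for name, resname, resseq, element, pos in _ligand_atoms():
            add(name, resname, resseq, element, pos)
        for name, resname, resseq, element, pos in _shell_atoms():
            add(name, resname, resseq, element, pos)
        for k, tag in enumerate(all_tags):
            resname, resseq, _ = water_ids[tag]
            if tag in water_pos:
                o, h1, h2 = water_pos[tag]
            else:
                o = park_water(k)
                h1 = o + np.array([_O_H, 0.0, 0.0])
                h2 = o + np.array(
                    [_O_H * np.cos(np.radians(_HOH_DEG)), _O_H * np.sin(np.radians(_HOH_DEG)), 0.0]
                )
            add("OW", resname, resseq, "O", o)
            add("HW1", resname, resseq, "H", h1)
            add("HW2", resname, resseq, "H", h2)
        for k, tag in enumerate(activator_tags):
            pos = activator_pos.get(tag, park_activator(k))
            add("OD1", "ASP", activator_resseq[tag], "O", pos)

        frames.append(Frame(index=fi, atoms=records))
        labels.append(FrameLabels(w1=frozenset(frame_w1), pairs=frozenset(frame_pairs)))

    traj = Trajectory(frames=frames, source="<synthetic>")
    truth = GroundTruth(water_ids=water_ids, frames=tuple(labels))
    object.__setattr__(truth, "_near_decoys", frozenset(near_decoys))
    return traj, truth


# ---------------------------------------------------------------------------
# serialization (CLI support)


def schedule_from_mapping(data: dict, seed: int | None = None) -> PlantSchedule:
    """Build a schedule from a plain mapping (e.g. parsed YAML).

    Expected shape::

        n_frames: 3
        jitter_sigma: 0.0
        seed: 0
        frames:
          - [{role: w1, tag: A}, {role: w2, tag: B, activator_distance: 3.0}]
          - []
          - [{role: decoy, tag: D, violated: angle}]

    Omitted per-spec fields take the planted defaults; a decoy entry may give
    only ``violated`` and receives the canonical single-violation geometry.
    """
    frames: list[list[PlantSpec]] = []
    for raw_specs in data.get("frames", []):
        specs: list[PlantSpec] = []
        for raw in raw_specs:
            role = raw["role"]
            tag = raw.get("tag") or raw["water_tag"]
            if role == "decoy" and set(raw) <= {"role", "tag", "water_tag", "violated"}:
                specs.append(decoy_spec(tag, raw["violated"]))
                continue
            kwargs = dict(role=role, water_tag=tag)
            for key, attr in [
                ("distance", "distance"),
                ("angle", "angle_deg"),
                ("angle_deg", "angle_deg"),
                ("orientation", "orientation"),
                ("violated", "violated"),
                ("partner", "partner_tag"),
                ("partner_tag", "partner_tag"),
                ("activator_distance", "activator_distance"),
            ]:
                if key in raw:
                    kwargs[attr] = raw[key]
            if role == "w2" and "orientation" not in raw:
                kwargs["orientation"] = "donor"
            if role == "w2" and "distance" not in raw:
                kwargs["distance"] = 2.8
            specs.append(PlantSpec(**kwargs))
        frames.append(specs)
    return PlantSchedule(
        n_frames=int(data["n_frames"]),
        frames=frames,
        jitter_sigma=float(data.get("jitter_sigma", 0.0)),
        seed=int(seed if seed is not None else data.get("seed", 0)),
    )


def labels_to_mapping(truth: GroundTruth) -> dict:
    """JSON-ready representation of the ground truth."""

    def wid(ident: WaterId) -> str:
        name, seq, chain = ident
        return f"{name}{seq}" + (f":{chain}" if chain else "")

    return {
        "water_ids": {tag: wid(ident) for tag, ident in sorted(truth.water_ids.items())},
        "frames": [
            {
                "frame": i + 1,
                "w1": sorted(wid(w) for w in fl.w1),
                "pairs": sorted([wid(a), wid(b)] for a, b in fl.pairs),
            }
            for i, fl in enumerate(truth.frames)
        ],
    }
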