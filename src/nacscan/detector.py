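"""Per-frame detection of attacking (W1) and assisting (W2) waters.

The detector screens each trajectory frame for waters in a near-attack
conformation around a ligand carbonyl carbon:

* **W1 (attacking water)** — its oxygen is within ``w1_dist_cutoff`` of the
  carbonyl carbon (strict ``<``), the Bürgi–Dunitz angle Nu···C=O lies inside
  the configured window (closed ``[105, 107]°`` by default), and the water is
  oxygen-first oriented (O strictly the water atom nearest the carbon).
* **W2 (assisting water)** — another water whose oxygen is within
  ``w2_dist_cutoff`` of the W1 oxygen and which donates a hydrogen toward W1
  (some W2 hydrogen strictly closer to O(W1) than O(W2) is).  The donor test
  can be switched off for a distance-only sensitivity analysis.
* **Activators** — protein N/O heavy atoms within ``activator_dist_cutoff``
  of the W2 oxygen, which could polarise or at least anchor the assisting
  water.

Scanning is two-pass, mirroring how pre-filtered MD site extracts are
analysed: first collect the waters that ever come within the W1 cutoff of
the carbonyl carbon, then test only those in every frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import AngleWindow, burgi_dunitz, distance, water_oxygen_first
from .trajectory import AtomRecord, Frame, Trajectory

__all__ = [
    "WaterId",
    "SiteDefinition",
    "W1Hit",
    "W2Hit",
    "ActivatorContact",
    "FrameReport",
    "MissingHydrogensError",
    "SiteResolutionError",
    "select_site_waters",
    "detect_w1",
    "detect_w2",
    "find_activators",
    "scan",
    "reports_to_dataframe",
    "write_report_csv",
    "write_report_json",
]

# water identity: (residue_name, residue_seq, chain_id)
WaterId = tuple[str, int, str]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class MissingHydrogensError(ValueError):
    """A water lacks explicit hydrogens, so orientation tests are undefined."""


class SiteResolutionError(ValueError):
    """The site definition does not resolve to exactly one carbonyl C and O."""


@dataclass(frozen=True)
class SiteDefinition:
    """Names and cutoffs defining the reaction site.

    Parameters
    ----------
    ligand_resname : residue name of the aminoacyl-A76 analog carrying the
        scissile ester carbonyl.
    carbonyl_c, carbonyl_o : atom names of the carbonyl carbon and oxygen
        within the ligand residue.
    water_resname : residue name of solvent waters (``SOL`` for GROMACS
        exports, ``HOH`` for PDB conventions).
    w1_dist_cutoff : O(water)–C distance cutoff in Angstrom, strict ``<``.
    bd_window : Bürgi–Dunitz angular window in degrees, closed by default.
    w2_dist_cutoff : O(W2)–O(W1) cutoff in Angstrom.
    activator_dist_cutoff : protein-atom–O(W2) cutoff in Angstrom.
    activator_elements : element symbols counted as potential activators.
    protein_resnames : residue names treated as protein for activator search.
    require_w2_orientation : when False, W2 is accepted on distance alone.
    on_missing_hydrogens : ``"error"`` (default) or ``"skip"`` a water with no
        explicit hydrogens.
    """

    ligand_resname: str
    carbonyl_c: str = "C"
    carbonyl_o: str = "O"
    ligand_resseq: int | None = None
    water_resname: str = "SOL"
    w1_dist_cutoff: float = 3.5
    bd_window: AngleWindow = field(default_factory=lambda: AngleWindow(105.0, 107.0))
    w2_dist_cutoff: float = 3.5
    activator_dist_cutoff: float = 3.5
    activator_elements: frozenset[str] = frozenset({"N", "O"})
    protein_resnames: frozenset[str] = STANDARD_AMINO_ACIDS
    require_w2_orientation: bool = True
    on_missing_hydrogens: str = "error"
    use_minimum_image: bool = False

    def __post_init__(self) -> None:
        for name in ("w1_dist_cutoff", "w2_dist_cutoff", "activator_dist_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.on_missing_hydrogens not in ("error", "skip"):
            raise ValueError("on_missing_hydrogens must be 'error' or 'skip'")


@dataclass(frozen=True)
class ActivatorContact:
    residue_name: str
    residue_seq: int
    atom_name: str
    distance: float


@dataclass(frozen=True)
class W1Hit:
    frame_index: int
    water: WaterId
    o_c_distance: float
    bd_angle: float
    orientation_ok: bool


@dataclass(frozen=True)
class W2Hit:
    frame_index: int
    w1_water: WaterId
    w2_water: WaterId
    oo_distance: float
    orientation_ok: bool
    activators: tuple[ActivatorContact, ...]


@dataclass(frozen=True)
class FrameReport:
    frame_index: int
    w1_hits: tuple[W1Hit, ...]
    w2_hits: tuple[W2Hit, ...]

    @property
    def has_w1(self) -> bool:
        return len(self.w1_hits) > 0

    @property
    def has_w1w2(self) -> bool:
        return len(self.w2_hits) > 0


# ---------------------------------------------------------------------------
# site resolution helpers


@dataclass(frozen=True)
class _Water:
    ident: WaterId
    o_index: int
    h_indices: tuple[int, ...]


class _ResolvedSite:
    """Topology indices resolved once per trajectory (rigid topology)."""

    def __init__(self, frame: Frame, site: SiteDefinition):
        c_idx = [
            i
            for i, a in enumerate(frame.atoms)
            if a.residue_name == site.ligand_resname
            and a.atom_name == site.carbonyl_c
            and (site.ligand_resseq is None or a.residue_seq == site.ligand_resseq)
        ]
        o_idx = [
            i
            for i, a in enumerate(frame.atoms)
            if a.residue_name == site.ligand_resname
            and a.atom_name == site.carbonyl_o
            and (site.ligand_resseq is None or a.residue_seq == site.ligand_resseq)
        ]
        if len(c_idx) != 1 or len(o_idx) != 1:
            raise SiteResolutionError(
                f"site must resolve exactly one carbonyl C and O; found "
                f"{len(c_idx)} C ({site.carbonyl_c!r}) and {len(o_idx)} O "
                f"({site.carbonyl_o!r}) in ligand {site.ligand_resname!r}"
            )
        self.c_index = c_idx[0]
        self.o_index = o_idx[0]

        groups: dict[WaterId, list[int]] = {}
        for i, a in enumerate(frame.atoms):
            if a.residue_name == site.water_resname:
                groups.setdefault((a.residue_name, a.residue_seq, a.chain_id), []).append(i)
        waters = []
        for ident, indices in groups.items():
            oxygens = [i for i in indices if frame.atoms[i].element == "O"]
            hydrogens = tuple(i for i in indices if frame.atoms[i].element == "H")
            if len(oxygens) != 1:
                raise SiteResolutionError(
                    f"water {ident} has {len(oxygens)} oxygen atoms; expected exactly 1"
                )
            waters.append(_Water(ident=ident, o_index=oxygens[0], h_indices=hydrogens))
        self.waters: dict[WaterId, _Water] = {w.ident: w for w in waters}

        self.activator_indices = tuple(
            i
            for i, a in enumerate(frame.atoms)
            if a.residue_name in site.protein_resnames and a.element in site.activator_elements
        )


def _box(frame: Frame, site: SiteDefinition) -> np.ndarray | None:
    return frame.box if site.use_minimum_image else None


def _check_hydrogens(water: _Water, site: SiteDefinition) -> bool:
    """True if the water is usable; raises or skips when hydrogens are absent."""
    if water.h_indices:
        return True
    if site.on_missing_hydrogens == "error":
        raise MissingHydrogensError(
            f"water {water.ident} has no explicit hydrogens; orientation tests "
            "require an explicit-hydrogen water model (set on_missing_hydrogens"
            "='skip' to ignore such waters)"
        )
    return False


# ---------------------------------------------------------------------------
# operations


def select_site_waters(traj: Trajectory, site: SiteDefinition) -> set[WaterId]:
    """Waters whose oxygen comes within the W1 cutoff of the carbonyl carbon
    in at least one frame.  Downstream scanning considers only these."""
    resolved = _ResolvedSite(traj.frames[0], site)
    hits: set[WaterId] = set()
    for frame in traj.frames:
        c_pos = frame.atoms[resolved.c_index].position
        box = _box(frame, site)
        for ident, water in resolved.waters.items():
            if ident in hits:
                continue
            if distance(c_pos, frame.atoms[water.o_index].position, box=box) < site.w1_dist_cutoff:
                hits.add(ident)
    return hits


def detect_w1(
    frame: Frame,
    site: SiteDefinition,
    candidate_waters: Iterable[WaterId] | None = None,
    _resolved: _ResolvedSite | None = None,
) -> list[W1Hit]:
    """W1 hits in one frame, sorted by O–C distance ascending.

    A water is reported iff all three criteria hold: O–C distance strictly
    below the cutoff, Bürgi–Dunitz angle inside the window, and oxygen-first
    orientation.
    """
    resolved = _resolved if _resolved is not None else _ResolvedSite(frame, site)
    candidates = (
        set(candidate_waters) if candidate_waters is not None else set(resolved.waters)
    )
    c_pos = frame.atoms[resolved.c_index].position
    o_pos = frame.atoms[resolved.o_index].position
    box = _box(frame, site)
    hits: list[W1Hit] = []
    for ident in sorted(candidates):
        water = resolved.waters.get(ident)
        if water is None:
            continue
        w_o = frame.atoms[water.o_index].position
        d = distance(c_pos, w_o, box=box)
        if not d < site.w1_dist_cutoff:
            continue
        bd = burgi_dunitz(w_o, c_pos, o_pos)
        if not site.bd_window.contains(bd):
            continue
        if not _check_hydrogens(water, site):
            continue
        h_pos = [frame.atoms[i].position for i in water.h_indices]
        if not water_oxygen_first(c_pos, w_o, h_pos, box=box):
            continue
        hits.append(
            W1Hit(
                frame_index=frame.index,
                water=ident,
                o_c_distance=d,
                bd_angle=bd,
                orientation_ok=True,
            )
        )
    hits.sort(key=lambda h: (h.o_c_distance, h.water))
    return hits


def find_activators(
    frame: Frame,
    w2_water: WaterId,
    site: SiteDefinition,
    _resolved: _ResolvedSite | None = None,
) -> list[ActivatorContact]:
    """Protein N/O atoms within the activator cutoff of the W2 oxygen,
    distance-sorted.  These are the residues that could activate or at least
    fix the assisting water."""
    resolved = _resolved if _resolved is not None else _ResolvedSite(frame, site)
    water = resolved.waters[w2_water]
    o_pos = frame.atoms[water.o_index].position
    box = _box(frame, site)
    contacts = []
    for i in resolved.activator_indices:
        atom = frame.atoms[i]
        d = distance(o_pos, atom.position, box=box)
        if d <= site.activator_dist_cutoff:
            contacts.append(
                ActivatorContact(
                    residue_name=atom.residue_name,
                    residue_seq=atom.residue_seq,
                    atom_name=atom.atom_name,
                    distance=d,
                )
            )
    contacts.sort(key=lambda c: (c.distance, c.residue_seq, c.atom_name))
    return contacts


def detect_w2(
    frame: Frame,
    w1: W1Hit,
    site: SiteDefinition,
    candidate_waters: Iterable[WaterId] | None = None,
    _resolved: _ResolvedSite | None = None,
) -> list[W2Hit]:
    """Assisting waters for one W1 hit, sorted by O–O distance ascending.

    A W2 candidate qualifies when its oxygen is within ``w2_dist_cutoff`` of
    the W1 oxygen and (unless disabled) it donates a hydrogen toward W1.
    Candidate waters default to every water in the frame: the assisting
    molecule need not ever approach the carbonyl itself.
    """
    if w1.frame_index != frame.index:
        raise ValueError(f"W1 hit belongs to frame {w1.frame_index}, not {frame.index}")
    resolved = _resolved if _resolved is not None else _ResolvedSite(frame, site)
    candidates = (
        set(candidate_waters) if candidate_waters is not None else set(resolved.waters)
    )
    candidates.discard(w1.water)
    w1_o = frame.atoms[resolved.waters[w1.water].o_index].position
    box = _box(frame, site)
    hits: list[W2Hit] = []
    for ident in sorted(candidates):
        water = resolved.waters.get(ident)
        if water is None:
            continue
        w2_o = frame.atoms[water.o_index].position
        d = distance(w1_o, w2_o, box=box)
        if d > site.w2_dist_cutoff:
            continue
        orientation_ok = True
        if site.require_w2_orientation:
            if not _check_hydrogens(water, site):
                continue
            # donor geometry toward W1: some W2 hydrogen strictly closer to
            # O(W1) than O(W2) is
            orientation_ok = any(
                distance(w1_o, frame.atoms[i].position, box=box) < d
                for i in water.h_indices
            )
            if not orientation_ok:
                continue
        hits.append(
            W2Hit(
                frame_index=frame.index,
                w1_water=w1.water,
                w2_water=ident,
                oo_distance=d,
                orientation_ok=orientation_ok,
                activators=tuple(find_activators(frame, ident, site, _resolved=resolved)),
            )
        )
    hits.sort(key=lambda h: (h.oo_distance, h.w2_water))
    return hits


def scan(traj: Trajectory, site: SiteDefinition) -> list[FrameReport]:
    """Full two-pass scan: site-water pre-filter, then per-frame W1/W2 tests.

    Returns one :class:`FrameReport` per frame, in frame order; the scan is
    deterministic and equals the concatenation of per-frame detections.
    """
    resolved = _ResolvedSite(traj.frames[0], site)
    site_waters = select_site_waters(traj, site)
    reports: list[FrameReport] = []
    for frame in traj.frames:
        try:
            w1_hits = detect_w1(frame, site, candidate_waters=site_waters, _resolved=resolved)
            w2_hits: list[W2Hit] = []
            for w1 in w1_hits:
                w2_hits.extend(detect_w2(frame, w1, site, _resolved=resolved))
        except (MissingHydrogensError, SiteResolutionError) as exc:
            raise type(exc)(f"frame {frame.index}: {exc}") from exc
        reports.append(
            FrameReport(
                frame_index=frame.index,
                w1_hits=tuple(w1_hits),
                w2_hits=tuple(w2_hits),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# report writers


def _water_str(ident: WaterId) -> str:
    name, seq, chain = ident
    return f"{name}{seq}" + (f":{chain}" if chain else "")


def reports_to_dataframe(reports: Sequence[FrameReport]) -> pd.DataFrame:
    """Flat per-hit table; frame indices are 1-based for human reading."""
    rows = []
    for rep in reports:
        for hit in rep.w1_hits:
            rows.append(
                {
                    "frame": rep.frame_index + 1,
                    "role": "W1",
                    "water_id": _water_str(hit.water),
                    "partner_id": "",
                    "distance_A": round(hit.o_c_distance, 4),
                    "bd_angle_deg": round(hit.bd_angle, 4),
                    "orientation_ok": hit.orientation_ok,
                    "activators": "",
                }
            )
        for hit in rep.w2_hits:
            rows.append(
                {
                    "frame": rep.frame_index + 1,
                    "role": "W2",
                    "water_id": _water_str(hit.w2_water),
                    "partner_id": _water_str(hit.w1_water),
                    "distance_A": round(hit.oo_distance, 4),
                    "bd_angle_deg": np.nan,
                    "orientation_ok": hit.orientation_ok,
                    "activators": ";".join(
                        f"{a.residue_name}{a.residue_seq}.{a.atom_name}@{a.distance:.2f}"
                        for a in hit.activators
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame",
            "role",
            "water_id",
            "partner_id",
            "distance_A",
            "bd_angle_deg",
            "orientation_ok",
            "activators",
        ],
    )


def write_report_csv(reports: Sequence[FrameReport], path: str | Path) -> None:
    reports_to_dataframe(reports).to_csv(path, index=False)


def write_report_json(reports: Sequence[FrameReport], path: str | Path) -> None:
    payload = []
    for rep in reports:
        payload.append(
            {
                "frame": rep.frame_index + 1,
                "has_w1": rep.has_w1,
                "has_w1w2": rep.has_w1w2,
                "w1": [
                    {
                        "water": _water_str(h.water),
                        "o_c_distance_A": h.o_c_distance,
                        "bd_angle_deg": h.bd_angle,
                        "orientation_ok": h.orientation_ok,
                    }
                    for h in rep.w1_hits
                ],
                "w2": [
                    {
                        "w1_water": _water_str(h.w1_water),
                        "w2_water": _water_str(h.w2_water),
                        "oo_distance_A": h.oo_distance,
                        "orientation_ok": h.orientation_ok,
                        "activators": [
                            {
                                "residue": f"{a.residue_name}{a.residue_seq}",
                                "atom": a.atom_name,
                                "distance_A": a.distance,
                            }
                            for a in h.activators
                        ],
                    }
                    for h in rep.w2_hits
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2))
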