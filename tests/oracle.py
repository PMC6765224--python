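"""Independent brute-force re-implementation of the W1/W2 scan, for tests.

Written with plain python ``math`` over explicit loops, deliberately sharing
no code with the package's geometry or detector modules.  All pairs are
examined in every frame; the pre-filter is a separate full pass.
"""

import math


def _dist(p, q):
    return math.dist(tuple(p), tuple(q))


def _angle_deg(a, v, b):
    ux, uy, uz = (a[0] - v[0], a[1] - v[1], a[2] - v[2])
    wx, wy, wz = (b[0] - v[0], b[1] - v[1], b[2] - v[2])
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nw = math.sqrt(wx * wx + wy * wy + wz * wz)
    c = (ux * wx + uy * wy + uz * wz) / (nu * nw)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _waters_of(frame, water_resname):
    groups = {}
    for atom in frame.atoms:
        if atom.residue_name == water_resname:
            key = (atom.residue_name, atom.residue_seq, atom.chain_id)
            groups.setdefault(key, []).append(atom)
    out = {}
    for key, atoms in groups.items():
        o = [a for a in atoms if a.element == "O"]
        h = [a for a in atoms if a.element == "H"]
        assert len(o) == 1
        out[key] = (o[0].position, [a.position for a in h])
    return out


def _carbonyl(frame, site):
    c = [a for a in frame.atoms
         if a.residue_name == site.ligand_resname and a.atom_name == site.carbonyl_c]
    o = [a for a in frame.atoms
         if a.residue_name == site.ligand_resname and a.atom_name == site.carbonyl_o]
    assert len(c) == 1 and len(o) == 1
    return c[0].position, o[0].position


def brute_force_scan(traj, site):
    """Per-frame (w1_set, pair_set) tuples by exhaustive enumeration."""
    ever_near = set()
    for frame in traj.frames:
        c_pos, _ = _carbonyl(frame, site)
        for key, (o_pos, _h) in _waters_of(frame, site.water_resname).items():
            if _dist(c_pos, o_pos) < site.w1_dist_cutoff:
                ever_near.add(key)

    results = []
    for frame in traj.frames:
        c_pos, co_pos = _carbonyl(frame, site)
        waters = _waters_of(frame, site.water_resname)
        w1_set = set()
        for key in ever_near:
            o_pos, h_pos = waters[key]
            d = _dist(c_pos, o_pos)
            if not d < site.w1_dist_cutoff:
                continue
            bd = _angle_deg(o_pos, c_pos, co_pos)
            lo, hi = site.bd_window.min_deg, site.bd_window.max_deg
            inside = lo <= bd <= hi if site.bd_window.inclusive else lo < bd < hi
            if not inside:
                continue
            if not all(d < _dist(c_pos, h) for h in h_pos):
                continue
            w1_set.add(key)
        pairs = set()
        for w1 in w1_set:
            o1, _ = waters[w1]
            for key, (o2, h2) in waters.items():
                if key == w1:
                    continue
                d = _dist(o1, o2)
                if d > site.w2_dist_cutoff:
                    continue
                if site.require_w2_orientation and not any(_dist(o1, h) < d for h in h2):
                    continue
                pairs.add((w1, key))
        results.append((w1_set, pairs))
    return results
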